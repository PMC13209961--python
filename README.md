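# tkscreen

A reusable, tested implementation of a kinase-inhibitor repurposing
workflow for computational medicinal chemists: given small molecules with
known activity, find plausible new tyrosine-kinase targets by 2D
similarity to approved drugs, derive statistically grounded acceptance
thresholds for docking scores from an approved-drug benchmark, triage
candidate docking results against those thresholds, validate the docking
protocol (symmetry-aware pose RMSD, enrichment factor, ROC-AUC), and
screen libraries with lightweight pharmacophore models plus drug-likeness
windows. Synthetic-data generators stand in for the docking engine, so the
whole statistical and decision layer is testable on one machine.

## The methods in brief

**Similarity gate.** Compounds are compared to approved drugs with the
Tanimoto coefficient *Tani = c/(a + b − c)* over two fingerprint views —
MACCS 166-bit substructure keys and Carhart-style atom pairs. A (compound,
drug) pair is eligible for target transfer when *Tani*<sub>AP</sub> ≥ 0.237
**and** *Tani*<sub>MACCS</sub> ≥ 0.528 simultaneously; the compound then
inherits the drug's annotated kinase targets as hypotheses.

**Score thresholds.** From a benchmark of approved kinase inhibitors
docked against their own targets (scores: binding affinity in kcal/mol,
CNN pose score in [0,1], CNN affinity), the package derives

* *soft thresholds* — one-sided 95% Student-*t* confidence bounds on the
  pooled mean: an upper bound for affinity, lower bounds for the two CNN
  metrics;
* *hard thresholds* — the benchmark extremes (worst value any approved
  drug produced).

On the shipped 48-pair benchmark these come out to soft (−9.00, 0.843,
7.702) and hard (−6.82, 0.526, 7.010). For targets where rigid-receptor
docking systematically underestimates affinity (e.g. wild-type EGFR), a
*category override* replaces the pooled affinity soft threshold by the
per-target benchmark mean (−7.95 for EGFR).

**Triage rule.** A candidate is accepted iff it meets at least two of the
three soft thresholds and no metric violates its hard bound.

**Validation.** Re-/cross-docking accuracy is the heavy-atom RMSD between
docked and crystal poses, minimized over graph automorphisms so symmetric
groups never inflate the error (< 2 Å consistent, 2–3 Å deviated, > 3 Å
inaccurate); screen discrimination is EF(x%) =
(actives<sub>x</sub>/dataset<sub>x</sub>)/(actives<sub>total</sub>/dataset<sub>total</sub>)
and the ROC-AUC.

**Pharmacophore screening.** Typed tolerance spheres (H-bond
acceptor/donor 0.5 Å, hydrophobic 1.0 Å, aromatic 1.1 Å, ± charges) are
matched to perceived ligand features by correspondence search with
least-squares alignment; hits are ranked by feature RMSD, pre-filtered by
drug-likeness windows spanned by approved TKIs, and post-filtered by a
receptor exclusion-sphere steric test.

## Worked example

Derive thresholds from the shipped benchmark and triage the compounds that
survived a VEGFR-2 pharmacophore screen:

```python
from tkscreen import derive_thresholds, triage_table
from tkscreen.datasets import load_fda_benchmark, load_vs_hits

thresholds = derive_thresholds(load_fda_benchmark())
print(thresholds.rounded())
# {'affinity_soft': -9.0, 'pose_soft': 0.843, 'cnn_affinity_soft': 7.702,
#  'affinity_hard': -6.82, 'pose_hard': 0.526, 'cnn_affinity_hard': 7.01}

report = triage_table(load_vs_hits("VEGFR-2"), thresholds)
print(report.n_accepted, "of", len(report.decisions))
# 14 of 14
```

Every VEGFR-2 screen survivor clears the rule: each record meets at least
two population-level (soft) bounds, and any metric that misses its soft
bound still stays inside the worst-approved-drug (hard) envelope.

The same flow is available from the shell:

```bash
tkscreen thresholds --benchmark benchmark.csv -o thresholds.json
tkscreen triage --scores candidates.csv --thresholds thresholds.json
tkscreen rmsd --ref crystal.sdf --pose docked.sdf
tkscreen enrich --scores screen.csv --top-pct 5
tkscreen run --config pipeline.yaml   # all stages + manifest
```

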