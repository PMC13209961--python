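# Methods

This note documents the models, conventions and design choices behind
`tkscreen`, in the order the pipeline runs them.

## Scope and data model

The pipeline operates on three record types: compounds (SMILES and/or an
explicit heavy-atom conformer with bond table and optional formal
charges), docking records (one ligand × target triple of binding affinity
in kcal/mol, CNN pose score in [0,1], CNN affinity > 0), and score tables
(unique ligand/target pairs). Hydrogens are dropped on every read: all
pose statistics in this package are heavy-atom statistics, which is the
convention for docking-pose validation. Coordinates are Å, right-handed;
atom indices are 0-based internally and 1-based only inside SDF V2000
bond blocks. CSV input normalizes the typeset Unicode minus (U+2212) to
ASCII so transcribed literature tables parse directly. SDF is restricted
to V2000; PDB reading extracts HETATM records of a single ligand only —
protein I/O is out of scope.

## Fingerprints and the similarity gate

Two complementary 2D views are used. MACCS substructure keys come from
RDKit's implementation of the public 166-key dictionary (keys reported on
a 0–165 range). Atom pairs are computed in-package with a fixed, documented
encoding so absolute values are reproducible: atom type = (atomic number,
heavy-neighbor count, aromatic flag) packed as `Z·100 + degree·10 + arom`;
a pair key is the order-normalized `(type_lo, type_hi, d)` with *d* the
topological shortest-path distance capped at 30 bonds, packed as
`type_lo·10⁶ + type_hi·10² + d`. Membership is binary (no counts).
Published pair similarities computed by third-party web services use
different key dictionaries, so absolute atom-pair Tanimoto values are
comparable only within this package; the dual-gate thresholds
(AP ≥ 0.237, MACCS ≥ 0.528, both inclusive) are configurable defaults
taken as given, not re-derived. The Tanimoto of two empty fingerprints is
defined as 0.0 (featureless molecules are not "similar") and warned
about. Hypotheses are ordered by descending AP Tanimoto, then MACCS
Tanimoto, then drug id, so output is deterministic.

## Threshold derivation

Soft thresholds are one-sided (1−α) Student-*t* confidence bounds on the
pooled benchmark mean (default α = 0.05): affinity gets the upper bound
`mean + t₁₋α,ₙ₋₁·s/√n`, the two maximize-metrics get the corresponding
lower bounds. The standard error uses the population SD (`ddof=0`) by
default — the convention of the reference workflow this package
reproduces; with the shipped 48-row benchmark the difference from the
sample-SD bound is < 0.005 on every metric, and `ThresholdConfig(ddof=1)`
selects the textbook estimator. Pooling is over all drug–target rows; no
per-target confidence intervals are produced. Hard thresholds are the
benchmark extremes: max affinity, min pose score, min CNN affinity.
Reporting rounds affinity to 2 decimals and the CNN metrics to 3;
triage always compares unrounded values.

Note an ordering consequence: because the affinity soft threshold is an
*upper* bound on the mean, the invariant on any non-degenerate benchmark
is mean < soft < hard for affinity, and hard < soft < mean for the two
maximize-metrics.

Category overrides handle targets where rigid-receptor docking is known
to understate affinities (large conformational changes, e.g. wild-type
EGFR): the per-target benchmark mean replaces the pooled affinity soft
threshold for that target only; pose and CNN-affinity thresholds are
never overridden.

## Triage

A record is accepted iff (i) it meets ≥ 2 of the 3 soft thresholds and
(ii) every soft-failing metric still satisfies its hard bound; any hard
violation rejects regardless of the other metrics. All comparisons are
inclusive, so a value exactly at a threshold passes. This rule is
monotone: improving any single metric can never turn an accepted record
into a rejected one (property-tested). Interaction inspection — hinge,
gatekeeper and DFG-motif contacts — is deliberately not automated; an
`interaction_note` free-text field carries curator annotations through
reports. On the shipped screening tables the rule accepts all 14 VEGFR-2
survivors and the single PDGFRα and HER2 survivors; two of the nine
listed EGFR compounds fail it even with the −7.95 override (one clears
only a single soft threshold), so the EGFR table is treated as
illustrative rather than as a consistency check of the strict rule.

## Pose RMSD

The RMSD between two conformers of the same molecule is minimized over
the automorphisms of the element-colored heavy-atom bond graph (VF2
enumeration, capped at 10,000 mappings; past the cap the best mapping
found so far is used and the result is flagged `capped`). Bond orders are
ignored in the matching so alternative Kekulé assignments of the same
aromatic system cannot block it. `IN_PLACE` mode — the default, and the
re-/cross-docking convention — compares coordinates in the shared
receptor frame; superposition would understate docking error.
`SUPERPOSED` mode first removes the optimal rigid motion
(Kabsch/least-squares via quaternion alignment, proper rotations only, so
reflections can never fake a match) and requires ≥ 3 atoms. Quality
bands: < 2.0 Å consistent, 2.0–3.0 Å deviated (inclusive on both edges),
> 3.0 Å inaccurate.

## Enrichment and ROC

EF(x%) ranks the labeled screen by the chosen metric (descending for the
CNN metrics, ascending for affinity), takes the top `floor(x·N/100)`
entries (ties broken stably by id) and computes
`(actives_x/dataset_x)/(actives_total/dataset_total)`. The floor rule
reproduces published tallies such as 16 inspected compounds from a
332-compound screen at 5%. An `enrichment_from_counts` entry point
computes EF directly from published count tallies. ROC-AUC is the
Mann–Whitney rank statistic (probability an active outranks an inactive,
ties half-credit), computed via scikit-learn and cross-checked in the
tests against a brute-force pair count; the curve is the standard
threshold sweep.

## Pharmacophore modeling and screening

Feature perception is SMARTS-driven from a versioned pattern file shipped
as package data (v1): acceptors are N/O with a free lone pair (amide
nitrogens, positive centers and pyrrole-type N–H excluded; pyridine-type
ring N included), donors are N–H/O–H, charges are formal charges at the
input protonation state (no pKa model). Aromatic features sit at
centroids of aromatic rings; hydrophobic features at centroids of
connected non-aromatic carbon fragments of ≥ 3 atoms with no heteroatom
contact — aromatic rings are represented by ARO alone, which keeps the
two channels disjoint. Perception is deterministic but intentionally
simpler than commercial implementations; the package's "performance
score" analogue is the consensus cluster support, which is not comparable
to scores printed by commercial tools.

Matching enumerates kind-compatible correspondences with
pairwise-distance pruning (model inter-feature distances must agree with
ligand distances within the sum of the two radii), capped at 10⁵
candidate assignments (`inconclusive` beyond the cap), applies
least-squares rigid alignment when enabled, accepts when every matched
ligand feature lies inside its model sphere, and returns the
correspondence with minimal feature RMSD. Default radii follow the
feature semantics: HAC/HDO 0.5 Å, HPB 1.0 Å, ARO 1.1 Å. Hits are ranked
by ascending feature RMSD with id tie-breaks. Consensus models cluster
same-kind features of co-aligned actives greedily within a 1.0 Å merge
radius and keep clusters supported by at least `min_support` of the
actives.

Drug-likeness windows (all inclusive, all overridable) default to the
ranges spanned by approved TKIs: MW [416.81, 461.47] Da, TPSA
[83.48, 95.83] Å², logP [2.62, 3.49], rotatable bonds [5, 7], H-bond
acceptors [4, 10], donors [0, 5], rings [4, 5]. Conventions are fixed:
average-mass MW, Ertl TPSA, Crippen logP, RDKit strict rotatable-bond
count, acceptor/donor counts from the same SMARTS as HAC/HDO, SSSR ring
count. The steric filter treats the receptor as exclusion spheres: a pose
is rejected iff any ligand heavy atom sits within
`max(vdW_radius − tolerance, 0)` of a receptor atom, with Bondi radii
shipped as data and tolerance defaulting to 1.5, interpreted as Å.

## Synthetic data

Generators are pure functions of spec + seed (one `numpy` Generator per
call, no global state). Benchmark tables draw each metric i.i.d. normal
per target, truncating pose scores to [0, 1] by clipping (at the shipped
SDs, clipping moves the pose mean by < 10⁻³, negligible against the
0.05-wide confidence margins). The default spec copies the per-target
means/SDs and group sizes of the shipped 48-pair reference table, so
simulated benchmarks land near the published thresholds — illustrative
structure, not ground truth. Screen sets are binormal — decoys N(μ, σ),
actives N(μ + d·σ, σ) — for which the theoretical AUC is Φ(d/√2); d = 1.19
gives AUC ≈ 0.80, in the range of published screens. Perturbed poses add
i.i.d. Gaussian coordinate noise (E[RMSD²] = 3σ²). Toy libraries are
drawn from a template grammar of diaryl ureas, aryl amides and
quinazolines — the scaffold families of ATP-competitive kinase
inhibitors — with halogen/alkoxy/amino substituents; all SMILES are valid
by construction. What these generators do **not** model: correlations
between the three docking metrics, heavy-tailed score distributions,
property-matched decoys, and conformational strain — so passing
simulation tests demonstrates the statistics are implemented correctly,
not that real docking scores satisfy the normality assumptions.

## Problem sizes and numerical choices

The shipped reference tables are small (48 benchmark rows, 25
cross-docking poses, 25 screen survivors) and all deterministic
quantities on them run in well under a second. Simulation checks use
2000 replicates for confidence-bound coverage (Monte-Carlo SE ≈ 0.5% at
95%), 5000 + 5000 scores for the binormal AUC check (SE ≈ 0.004), and
300 label permutations for the EF-expectation check; these sizes keep
each check's Monte-Carlo error well inside its assertion tolerance while
completing in seconds. Floating-point comparisons in triage and matching
are exact except for a 10⁻⁹ cushion on sphere-inclusion tests;
rigid-motion invariance holds to 10⁻⁶ Å.

## Known limitations

No docking is performed: affinity/pose/CNN-affinity numbers are inputs.
Fingerprint absolute values are implementation-specific across software
ecosystems (only the MACCS channel is portable). Pharmacophore perception
has no tautomer/protonation enumeration. The correspondence search is
exhaustive-with-pruning, adequate for models with ≤ ~8 features but not
for dense feature fields. Criterion-style interaction analysis (hinge,
DFG, gatekeeper contacts) remains a curator task.
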