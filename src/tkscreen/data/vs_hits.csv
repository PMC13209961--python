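ligand_id,target_id,affinity,cnn_pose_score,cnn_affinity
CHEMBL3661566,VEGFR-2,-10.99,0.537,7.802
CHEMBL4790167,VEGFR-2,-10.28,0.875,7.894
CHEMBL3661571,VEGFR-2,-10.44,0.804,7.759
CHEMBL4171108,VEGFR-2,-10.14,0.896,8.176
CHEMBL2354367,VEGFR-2,-10.14,0.809,8.386
CHEMBL4581299,VEGFR-2,-11.12,0.879,7.467
CHEMBL3661578,VEGFR-2,-10.52,0.8671,7.804
CHEMBL3641531,VEGFR-2,-10.85,0.905,8.133
CHEMBL4092441,VEGFR-2,-9.55,0.7488,7.734
CHEMBL2170947,VEGFR-2,-9.11,0.878,8.273
CHEMBL3661581,VEGFR-2,-10.03,0.763,8.067
CHEMBL1459733,VEGFR-2,-9.98,0.922,7.120
CHEMBL3661565,VEGFR-2,-10.82,0.800,7.989
CHEMBL3318995,VEGFR-2,-10.11,0.597,7.962
CHEMBL5019511,PDGFRa,-10.36,0.804,7.725
CHEMBL3903973,EGFR,-8.06,0.791,7.780
CHEMBL4865595,EGFR,-8.11,0.880,7.755
CHEMBL59202,EGFR,-8.69,0.587,7.696
CHEMBL3657549,EGFR,-8.62,0.843,7.286
CHEMBL3984043,EGFR,-8.49,0.890,7.441
CHEMBL2216869,EGFR,-9.00,0.966,8.171
CHEMBL165023,EGFR,-8.49,0.889,7.323
CHEMBL5091998,EGFR,-8.00,0.911,7.268
CHEMBL2041238,EGFR,-9.05,0.835,7.528
CHEMBL3355044,HER2,-10.39,0.869,7.564
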