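ligand_id,target_id,affinity,cnn_pose_score,cnn_affinity,rmsd
Axitinib,VEGFR-2,-8.53,0.842,7.634,5.500
Cabozatinib,VEGFR-2,-11.86,0.913,7.725,1.059
Fruquitinib,VEGFR-2,-8.74,0.906,7.672,1.499
Lenvatinib,VEGFR-2,-11.03,0.957,8.049,2.776
Pazopanib,VEGFR-2,-8.69,0.856,7.407,3.730
Regorafenib,VEGFR-2,-11.24,0.890,7.833,1.688
Sorafenib,VEGFR-2,-11.25,0.882,7.588,2.536
Sunitinib,VEGFR-2,-7.35,0.728,7.312,5.250
Vandetanib,VEGFR-2,-10.42,0.814,8.062,1.514
Cabozatinib,RET,-8.83,0.526,7.169,1.920
Lenvatinib,RET,-7.24,0.927,7.532,3.108
Selpercatinib,RET,-9.83,0.854,7.535,2.064
Avapritinib,PDGFRa,-6.82,0.904,8.235,5.095
Ripretinib,PDGFRa,-8.91,0.881,7.922,2.000
Afatinib,EGFR,-8.35,0.900,7.852,2.169
Dacomitinib,EGFR,-8.60,0.932,8.125,2.186
Gefitinib,EGFR,-7.93,0.983,7.986,1.862
Osimertinib,EGFR,-7.12,0.932,7.948,1.562
Afatinib,HER2,-7.61,0.925,7.381,2.906
Capivasertib,HER2,-9.71,0.898,7.450,2.537
Lapatinib,HER2,-9.98,0.858,7.609,2.022
Neratinib,HER2,-7.51,0.780,7.875,2.432
Tucatinib,HER2,-10.64,0.750,7.634,1.494
Capmatinib,c-MET,-11.41,0.901,7.976,2.534
Savolitinib,c-MET,-8.99,0.973,8.189,1.079
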