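ligand_id,target_id,affinity,cnn_pose_score,cnn_affinity
Axitinib,VEGFR-2,-8.53,0.842,7.634
Cabozatinib,VEGFR-2,-11.86,0.913,7.725
Fruquitinib,VEGFR-2,-8.74,0.906,7.672
Lenvatinib,VEGFR-2,-11.03,0.957,8.049
Pazopanib,VEGFR-2,-8.69,0.856,7.407
Regorafenib,VEGFR-2,-11.24,0.890,7.833
Sorafenib,VEGFR-2,-11.25,0.882,7.588
Sunitinib,VEGFR-2,-7.35,0.728,7.312
Tivozanib,VEGFR-2,-10.94,0.946,8.408
Vandetanib,VEGFR-2,-8.03,0.900,8.025
Avapritinib,PDGFRa,-6.82,0.904,8.235
Ripretinib,PDGFRa,-8.91,0.881,7.922
Capmatinib,c-MET,-11.41,0.901,7.976
Tepotinib,c-MET,-10.00,0.863,8.222
Savolitinib,c-MET,-8.99,0.973,8.189
Cabozatinib,RET,-8.83,0.526,7.169
Lenvatinib,RET,-7.24,0.927,7.532
Pralsetinib,RET,-10.09,0.974,8.053
Selpercatinib,RET,-9.83,0.854,7.535
Afatinib,EGFR,-8.35,0.900,7.852
Dacomitinib,EGFR,-8.60,0.932,8.125
Gefitinib,EGFR,-7.93,0.983,7.986
Mobocertinib,EGFR,-7.77,0.979,8.225
Osimertinib,EGFR,-7.12,0.932,7.948
Afatinib,HER2,-7.61,0.925,7.381
Capivasertib,HER2,-9.71,0.898,7.450
Lapatinib,HER2,-9.98,0.858,7.609
Neratinib,HER2,-7.51,0.780,7.875
Tucatinib,HER2,-10.64,0.750,7.634
Abrocitinib,JAK1,-9.10,0.974,7.630
Ruxolitinib,JAK1,-9.05,0.943,7.976
Filgotinib,JAK1,-8.12,0.586,7.010
Upadacitinib,JAK1,-9.85,0.886,7.826
Fedratinib,JAK2,-7.83,0.964,8.352
Momelotinib,JAK2,-8.71,0.967,7.799
Pacritinib,JAK2,-9.22,0.945,7.551
Ruxolitinib,JAK2,-8.02,0.910,7.796
Baricitinib,JAK2,-8.55,0.902,7.780
Acalabrutinib,BTK,-11.44,0.843,7.959
Ibrutinib,BTK,-9.80,0.858,7.688
Pirtobrutinib,BTK,-10.01,0.755,7.189
Zanubrutinib,BTK,-10.50,0.954,7.593
Asciminib,BCR-Abl,-10.69,0.797,7.737
Bosutinib,BCR-Abl,-8.80,0.748,7.687
Dasatinib,BCR-Abl,-9.84,0.803,7.527
Imatinib,BCR-Abl,-11.22,0.638,7.613
Nilotinib,BCR-Abl,-10.72,0.833,8.306
Ponatinib,BCR-Abl,-11.00,0.755,7.758
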