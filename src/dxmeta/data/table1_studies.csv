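author,year,ethnicity,gene,regulation,location,sample_type,reported_auc,cutoff,sen,spe,total,n_case,n_control,control_source,nos
Shao et al.,2014,Chinese,AA174084,Down,Unknown,Gastric juices,0.848,0.88,0.46,0.93,130,39,91,NMMG+AG+GU,7
Shao et al.,2014,Chinese,AA174084,Down,Unknown,Tissue,0.676,11.62,0.57,0.73,268,134,134,ANT,8
Lin et al.,2014,Chinese,ABHD11-AS1,Up,Intergenic,Tissue,0.613,11,0.67,0.64,150,75,75,ANT,7
Yang et al.,2016,Chinese,ABHD11-AS1,Up,Intergenic,Gastric juices,0.653,6.53,0.41,0.934,130,39,91,NMMG+AG+GU,7
Abdi et al.,2021,Iranian,AC064834.1,Up,Unknown,Tissue,0.7,Unclear,0.675,0.675,80,40,40,ANT,7
Sun et al.,2013,Chinese,AC096655.1-002,Down,Intergenic,Tissue,0.731,13.955,0.513,0.872,156,78,78,ANT,8
Chen et al.,2014,Chinese,AC138128.1,Down,Unknown,Tissue,0.688,Unclear,0.7,0.56,188,94,94,ANT,7
Zhou et al.,2020,Chinese,BC002811,Up,Unknown,Serum,0.723,1.41,0.58,0.943,170,100,70,Benign gastric diseases,6
Zhou et al.,2020,Chinese,C5orf66-AS1,Down,Intergenic,Serum,0.688,0.134,0.775,0.536,419,141,278,GS+GA+GD,7
Roghieh et al.,2021,Iranian,DLEU1,Up,Antisense,Tissue,0.7,0.3357,0.62,0.646,100,50,50,ANT,6
Liu et al.,2014,Chinese,FER1L4,Down,Unknown,Tissue,0.778,15.43,0.672,0.803,122,61,61,ANT,8
Tan et al.,2016,Chinese,GACAT2,Up,Antisense,Plasma,0.622,6.625,0.872,0.282,197,117,80,Healthy blood,6
Arita et al.,2013,Japanese,H19,Up,Intergenic,Plasma,0.64,Unclear,0.74,0.58,76,43,33,Healthy blood,7
Zhou et al.,2015,Chinese,H19,Up,Intergenic,Plasma,0.838,Unclear,0.829,0.729,140,70,70,Healthy blood,7
Zhou et al.,2015,Chinese,H19,Up,Intergenic,Plasma (early cancer),0.877,Unclear,0.855,0.801,52,26,26,Healthy blood,7
Chen et al.,2016,Chinese,H19,Up,Intergenic,Tissue,0.697,Unclear,0.62,0.74,256,128,128,ANT,7
Hashad et al.,2016,Egyptian,H19,Up,Intergenic,Plasma,0.724,0.5,0.6875,0.5667,62,32,30,Healthy blood,7
Yu et al.,2020,Chinese,H19,Up,Intergenic,Serum,0.943,Unclear,0.9007,0.9018,224,112,112,Healthy blood,7
Hui et al.,2021,Chinese,HEIH,Up,Intergenic,Tissue,0.784,Unclear,0.78,0.812,300,150,150,ANT,7
Sun et al.,2015,Chinese,HIF1A-AS2,Up,Antisense,Tissue,0.673,9.56,0.7229,0.6024,166,83,83,ANT,7
Xu et al.,2019,Chinese,HOTAIR,Up,Antisense,Tissue,0.8416,1.4,0.6667,0.8704,108,54,54,ANT,7
Zhao et al.,2014,Chinese,HULC,Up,Antisense,Tissue,0.769,10.88,0.707,0.724,116,58,58,ANT,7
Jin et al.,2016,Chinese,HULC,Up,Antisense,Serum,0.888,Unclear,0.82,0.836,210,100,110,Healthy blood,8
Ma et al.,2016,Chinese,KRT18P55,Up,Unknown,Tissue,0.733,Unclear,0.691,0.66,194,97,97,ANT,8
Samaneh et al.,2021,Iranian,KRT18P55,Up,Unknown,Tissue,0.6799,0.0023,0.5392,0.7745,204,102,102,ANT,7
Ji et al.,2019,Chinese,LINC00086,Down,Unknown,Plasma,0.86,0.3,0.726,0.838,242,168,74,Healthy blood,9
Pang et al.,2014,Chinese,LINC00152,Up,Intergenic,Tissue,0.645,4.385,0.625,0.681,142,71,71,ANT,6
Li et al.,2015,Chinese,LINC00152,Up,Intergenic,Plasma,0.657,Unclear,0.481,0.852,160,79,81,Healthy blood,7
Chen et al.,2016,Chinese,LINC00152,Up,Intergenic,Tissue,0.705,3.175,0.7629,0.567,194,97,97,ANT,7
Fei et al.,2016,Chinese,LINC00982,Up,Antisense,Tissue,0.742,Unclear,0.811,0.613,212,106,106,ANT,8
Liang et al.,2021,Chinese,LINC01061,Up,Intergenic,Serum,0.93,Unclear,0.717,0.965,82,53,29,Healthy blood,6
Yu et al.,2020,Chinese,linc-ROR,Down,Unknown,Tissue,0.6495,16.79,0.7524,0.5143,210,105,105,ANT,6
Liu et al.,2014,Chinese,ncRuPAR,Down,Intergenic,Tissue,0.84,4.97,0.8841,0.7391,276,138,138,ANT,7
Guo et al.,2016,Chinese,OR3A4,Up,Unknown,Plasma,0.852,Unclear,0.8694,0.9127,260,130,130,Healthy blood,7
Gao et al.,2016,Chinese,PVT1,Up,Intergenic,Plasma,0.797,Unclear,0.593,0.921,40,20,20,Healthy blood,6
Dastmalchi et al.,2021,Iranian,PVT1,Up,Intergenic,Tissue,0.71,Unclear,0.5588,0.7843,204,102,102,ANT,6
Yuan et al.,2016,Chinese,PVT1,Up,Intergenic,Tissue,0.728,Unclear,0.802,0.604,222,111,111,ANT,8
Shao et al.,2016,Chinese,RMRP,Up,Bidirectional,Plasma,0.639,Unclear,0.591,0.678,193,103,90,Healthy blood,6
Shao et al.,2016,Chinese,RMRP,Up,Bidirectional,Gastric juices,0.699,Unclear,0.564,0.754,84,39,45,Healthy juices,6
Sun et al.,2015,Chinese,RP11-119F7.4,Down,Unknown,Tissue,0.637,6.445,0.448,0.823,192,96,96,ANT,7
Mo et al.,2019,Chinese,RP11-555H23.1,Down,Unknown,Tissue,0.65,12.9,0.81,0.62,208,104,104,ANT,8
Jing et al.,2020,Chinese,RP11-731F5.2,Up,Unknown,Serum,0.78,Unclear,0.816,0.636,184,104,80,Healthy blood,6
Tang et al.,2020,Chinese,SGOL1-AS1,Up,Unknown,Tissue,0. 612,Unclear,0.877,0.4,130,65,65,ANT,6
Chen et al.,2016,Chinese,SNHG15,Up,Intronic,Tissue,0.722,4.43,0.642,0.745,212,106,106,ANT,8
Mei et al.,2013,Chinese,SUMO1P3,Up,Unknown,Tissue,0.666,2.31,0.659,0.636,192,96,96,ANT,7
Weiwei and Jianjun,2021,Chinese,TC0101441,Up,Unknown,Tissue,0.8082,8.45,0.817,0.923,318,159,159,ANT,6
Sun et al.,2015,Chinese,TINCR,Up,Intronic,Tissue,0.701,9.05,0.65,0.71,160,80,80,ANT,7
Li et al.,2021,Chinese,TUG1,Up,Intergenic,Serum,0.833,2.405,0.7419,0.8955,129,67,62,Healthy blood,9
Li et al.,2015,Chinese,UCA1,Up,Intergenic,Tissue,0.721,13.74,0.672,0.803,224,112,112,ANT,7
Gao et al.,2016,Chinese,UCA1,Up,Intergenic,Plasma,0.928,Unclear,0.892,0.803,40,20,20,Healthy blood,6
Ma et al.,2019,Chinese,ZEB1-AS1,Up,Antisense,Tissue,0.79,Unclear,0.821,0.792,143,84,59,ANT,7
Pan et al.,2017,Chinese,ZFAS1,Up,Antisense,Tissue,0.63,Unclear,0.5,0.787,188,94,94,ANT,8
Pan et al.,2017,Chinese,ZFAS1,Up,Antisense,Serum,0.792,Unclear,0.717,0.757,60,37,23,Healthy blood,6
Dastmalchi et al.,2021,Iranian,ZFAS1,Down,Antisense,Tissue,0.79,Unclear,0.6471,0.7941,204,102,102,ANT,6
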