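no,name,cas,sensitizer,molecular_weight_g_mol,llna_ec3_pct,noel_ug_cm2,gard_input_um,cdv0_interp_um,cdv0_ll_um,cdv0_ll_ci_low_um,cdv0_ll_ci_high_um,cdv0_interp_mg_l,p_no_effect
1,"2,4-Dinitrochlorobenzene",97-00-7,1,202.55,0.06,8.8,5,2.19,2.71,2.00,3.77,0.443,1.05e-5
2,Benzalkonium chloride,8001-54-5,1,423.7,0.1,ND,3,0.826,0.87,0.70,1.05,0.350,8.15e-9
3,Dimethyl fumarate,624-49-7,1,144.13,0.35,88,90,6.06,6.58,2.88,12.1,0.974,1.71e-7
4,Methylisothiazolinone,2682-20-4,1,115.15,0.4,15,10,7.85,7.12,2.23,13.5,0.904,5.32e-4
5,Iodopropynyl butylcarbamate,55406-53-6,1,281.09,0.9,ND,10,5.74,7.24,5.34,9.78,1.61,7.16e-7
6,Cinnamic aldehyde,104-55-2,1,132.16,1.1,559,160,3.97,3.64,2.05,6.64,0.524,2.21e-6
7,Isoeugenol,97-54-1,1,164.20,1.3,569,300,10.4,81.8,NA,NA,1.70,8.62e-4
8,2-Hydroxyethyl acrylate,818-61-1,1,116.12,1.56,ND,100,NA,NA,NA,NA,NA,1.50e-6
9,Diethyl maleate,141-05-9,1,172.18,2.1,1600,100,4.38,5.97,2.20,12.1,0.753,2.76e-7
10,3-Dimethylaminopropylamine,109-55-7,1,102.18,2.2,ND,500,251,257,107,NA,25.7,6.72e-3
11,trans-Anethole,4180-23-8,1,148.20,2.7,5510,500,NS,NS,NA,NA,NS,1.00
12,Benzyl salicylate,118-58-1,1,228.24,2.85,17717,200,164,130,97.9,NA,37.4,7.74e-2
13,Farnesol,4602-84-0,1,222.37,4.8,2755,500,54.4,55.0,26.4,92.9,12.1,1.09e-4
14,Eugenol,97-53-0,1,164.20,12.9,1938,500,56.6,64.6,57.8,72.6,9.29,1.96e-9
15,Pentachlorophenol,87-86-5,1,266.34,20,2155,150,75.4,83.3,52.8,137,20.1,7.11e-6
16,7-Hydroxycitronellal,107-75-5,1,172.26,22.2,2953,500,33.1,29.0,14.3,43.1,5.70,4.85e-5
17,Geraniol,106-24-1,1,154.25,23.2,3875,500,82.6,88.9,39.8,183,12.7,3.68e-5
18,Imidazolidinyl urea,39236-46-9,1,388.29,24,2000,50,38.5,33.4,25.6,46.0,14.9,3.22e-4
19,Linalool,78-70-6,1,154.25,30.4,13793,500,279,NS,71.6,NA,43.0,9.54e-3
20,Kanamycin sulfate,70560-51-9,1,582.58,NS,1874,125,NS,NS,NA,NA,NS,1.00
21,Benzocaine,94-09-7,1,165.19,NS,2000,500,NS,NS,406,NA,NS,5.76e-2
22,Benzyl alcohol,100-51-6,1,108.14,NS,5906,500,12.6,12.4,6.32,22.8,1.37,1.60e-3
23,Salicylic acid,69-72-7,0,138.12,12.2,NS,500,NS,NS,NA,NA,NS,1.00
24,Xylene,1330-20-7,0,106.17,95.8,NS,500,NS,NS,NA,NA,NS,0.810
25,1-Butanol,71-36-3,0,74.12,NS,NS,500,NS,NS,NA,NA,NS,1.00
26,Glycerol,56-81-5,0,92.09,NS,NS,500,NS,NS,181,NA,NS,1.00
27,Octanoic acid,124-07-2,0,144.21,NS,NS,500,NS,NS,224,NA,NS,0.555
28,Phenol,108-95-2,0,94.11,NS,NS,500,317,328,150,NA,29.9,2.44e-3
29,Vanillin,121-33-5,0,152.15,NS,1181,500,NS,NS,NA,NA,NS,1.00
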