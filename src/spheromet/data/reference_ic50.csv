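cell_line,compound,proliferative,metric,area
HCT116,Paclitaxel,0.284,0.33,0.2686
HCT116,5-FU,921,1762,1304
HCT116,Cytarabine,303,644,198.5
HCT116,Niraparib,3279,5300,1432
HCT116,Etoposide,>2000,>2000,>2000
HCT116,Oxaliplatin,>10000,>2000,>2000
LoVo,Paclitaxel,n/a,>8,12.9
LoVo,5-FU,n/a,0.0014,688
LoVo,Cytarabine,14.2,15.2,14.3
LoVo,Niraparib,270,>400,693
LoVo,Etoposide,n/a,>80,283
LoVo,Oxaliplatin,n/a,>80,>400
PANC-1,Paclitaxel,1.24,1.28,1.31
PANC-1,5-FU,1361,>400,738
PANC-1,Cytarabine,254,498,325
PANC-1,Niraparib,563,478,451
PANC-1,Etoposide,1982,1904,2041
PANC-1,Oxaliplatin,1705,457,1717
CFPAC-1,Paclitaxel,0.01,0.012,0.011
CFPAC-1,5-FU,328,71.8,286
CFPAC-1,Cytarabine,71.0,66.0,43.3
CFPAC-1,Niraparib,>3.2,>80,>80
CFPAC-1,Etoposide,>2000,>2000,>400
CFPAC-1,Oxaliplatin,>10000,527,>400
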