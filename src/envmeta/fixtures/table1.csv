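accession,clade,contributor,country_of_origin,type,row_type,dtf,avg_ws
06OR-20,1,OSU-OR,United States,Breeding line,6,73,58
MW09S4086-001,1,UMN,United States,Breeding line,6,69,59
MW09S4076-002,1,UMN,United States,Breeding line,6,58,65
2011-F5-110-1,2,OSU-OR,United States,Breeding line,6,139,59
2011-F5-123-1,2,OSU-OR,United States,Breeding line,6,146,59
2011-F5-97-1,2,OSU-OR,United States,Breeding line,6,130,57
2011-F5-141-5,2,OSU-OR,United States,Breeding line,6,127,62
2011-F5-36-3,2,OSU-OR,United States,Breeding line,6,154,69
2011-F5-37-3,2,OSU-OR,United States,Breeding line,6,126,55
OBADV11-2,2,OSU-OR,United States,Breeding line,6,89,58
07OR-55,2,OSU-OR,United States,Breeding line,6,82,56
29648/2329,3,Lfl,Germany,Breeding line,2,146,56
Scala,3,OSU-OR,Germany,Cultivar,2,152,58
85849_NH,3,OSU-OR,France,Breeding line,2,118,58
Diadem,3,JHI,France,Cultivar,6,141,64
JET,3,JHI,United Kingdom,Cultivar,2,131,55
Ayana,3,JHI,United Kingdom,Cultivar,6,116,58
Admire-1,4,OSU-OH,United States,Germplasm,6,102,65
Admire-2,4,OSU-OH,United States,Germplasm,6,152,56
MO_B475,4,OSU-OH,United States,Cultivar,6,116,73
CIho6486,4,OSU-OR,Germany,Cultivar,6,NA,56
Friedrichswerther_Berg,4,OSU-OH,Germany,Landrace,6,138,56
PI327603,4,OSU-OR,Czech Republic,Landrace,6,NA,56
Grete,4,JHI,Germany,Cultivar,6,60,55
Herefordia,4,JHI,?,Cultivar,6,144,57
Cetin,4,JHI,Italy,Cultivar,6,118,62
NB09432,5,UNL,United States,Breeding line,6,133,65
NB09433,5,UNL,United States,Breeding line,6,135,63
NB07411,5,UNL,United States,Breeding line,6,139,56
NB99875,5,UNL,United States,Breeding line,6,112,65
Leninakanskij,6,OSU-OH,Armenia,Cultivar,6,143,60
PI327764,6,OSU-OR,Russia,Landrace,6,NA,68
PI327702,6,OSU-OR,Russia,Landrace,?,NA,67
PI340977,6,OSU-OR,Russia,Cultivar,6,NA,67
PI327709,6,OSU-OR,Russia,Landrace,6,NA,61
PI87835,7,OSU-OR,North Korea,Landrace,?,NA,74
P-721,7,UNL,United States,Breeding line,6,103,55
NB10403,7,UNL,United States,Breeding line,6,137,56
NB10444,7,UNL,United States,Breeding line,6,123,59
NB09441,7,UNL,United States,Breeding line,6,126,56
VA08B-85,7,VPI-SU,United States,Breeding line,6,124,55
NB10406,7,UNL,United States,Breeding line,6,132,56
NB10417,7,UNL,United States,Breeding line,6,128,57
NB10419,7,UNL,United States,Breeding line,6,114,62
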