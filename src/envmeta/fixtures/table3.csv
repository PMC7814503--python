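accession,ws,dtf,ppd_h2,ppd_h1,vrn_h1,vrn_h2
GRETE,55,60,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Deletion ZCCT_Ha ZCCT_Hb ZCCT_Hc
MW09S4076-002,65,58,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Deletion ZCCT_Ha ZCCT_Hb
06OR-20,58,73,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Deletion ZCCT_Ha ZCCT_Hb ZCCT_Hc
07OR-55,56,82,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Deletion ZCCT_Ha ZCCT_Hb ZCCT_Hc
OBADV11-2,58,89,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Deletion ZCCT_Ha ZCCT_Hb ZCCT_Hc
MW09S4086-001,59,69,intact_HvFT3,dominant_PPD-H1,intact_intron1,Deletion ZCCT_Ha ZCCT_Hb
NB09433,63,135,intact_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
NB10403,56,137,intact_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
NB10417,57,128,intact_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
CETIN,62,118,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Partial deletion
DIADEM,64,141,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Deletion ZCCT_Hc
JET,55,131,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Partial deletion
NB09432,65,133,intact_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
LENINAKANSKIJ,60,143,NA,recessive_ppd-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
NB09441,57,126,intact_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
NB10419,62,114,intact_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
P-721,55,103,intact_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
2011-F5-141-5,62,127,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
2011-F5-36-3,69,154,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
NB07411,56,139,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
NB10444,59,123,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
NB99875,65,112,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc
MO_B475,72,116,truncated_HvFT3,dominant_PPD-H1,intact_intron1,Partial deletion
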