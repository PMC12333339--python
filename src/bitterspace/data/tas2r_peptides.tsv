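# Amino acids / peptides with cell-assay evidence of activating human bitter taste receptors
receptor	peptides
TAS2R1	F,GF,GL,IF,LW,FI,FL,WW,GLL,IQW,LKP,FFF,WWW,YPFPGPIHNS,LVYPFPGPIHN,(D)-F
TAS2R4	F,W,GF,GL,IF,LW,FW,WL,WF,WP,WW,LLL,WWW,(D)-W
TAS2R8	FFPR
TAS2R14	GF,WWW,CL1,CL2,CL3,CL4,CL6
TAS2R16	GF
TAS2R20	F
TAS2R39	F,W,IF,LW,PR,WW,WWW,FFPR,YPFPGPIHNS,LVYPFPGPIHN,(D)-F,(D)-W
TAS2R43	W,CL6
TAS2R46	WWW
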