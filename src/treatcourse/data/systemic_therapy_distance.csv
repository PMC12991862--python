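,CH,HO,IM,TS,CI,CT,CIT,IT,SC,AS,WS,WW,OT,MI
CH,0,0.8,0.8,0.8,0.4,0.4,0.4,0.8,0.5,0.9,1,1,1,1
HO,0.8,0,0.2,0.2,0.8,0.8,0.8,0.2,1,0.8,0.8,0.8,1,1
IM,0.8,0.2,0,0.2,0.7,0.8,0.7,0.2,1,0.8,0.8,0.8,1,1
TS,0.8,0.2,0.2,0,0.8,0.7,0.7,0.2,1,0.8,0.8,0.8,1,1
CI,0.4,0.8,0.7,0.8,0,0.2,0.1,0.8,0.5,0.9,1,1,1,1
CT,0.4,0.8,0.8,0.7,0.2,0,0.1,0.8,0.5,0.9,1,1,1,1
CIT,0.4,0.8,0.7,0.7,0.1,0.1,0,0.7,0.5,0.9,1,1,1,1
IT,0.8,0.2,0.2,0.2,0.8,0.8,0.7,0,1,0.8,0.8,0.8,1,1
SC,0.5,1,1,1,0.5,0.5,0.5,1,0,1,1,1,1,1
AS,0.9,0.8,0.8,0.8,0.9,0.9,0.9,0.8,1,0,0.2,0.4,1,1
WS,1,0.8,0.8,0.8,1,1,1,0.8,1,0.2,0,0.2,1,1
WW,1,0.8,0.8,0.8,1,1,1,0.8,1,0.4,0.2,0,1,1
OT,1,1,1,1,1,1,1,1,1,1,1,1,0,1
MI,1,1,1,1,1,1,1,1,1,1,1,1,1,1
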