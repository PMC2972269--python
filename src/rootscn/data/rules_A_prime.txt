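# Reference rule set, root SCN model A'
PLT = ARF
Auxin = 1
ARF = NOT Aux/IAA
Aux/IAA = NOT Auxin
SHR = SHR
SCR[SHR,SCR,JKD,MGP] = SHR AND SCR
JKD = SHR AND SCR
MGP = SHR AND SCR AND NOT WOX5
WOX5 = ARF AND SHR AND SCR AND (NOT MGP OR WOX5)
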