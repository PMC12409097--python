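analyte,ion_label,exact_mz,ion_formula,backbone_positions,ionization,status,notes
aspartic acid 3TMS,350,350.1639,C13H32NO4Si3,1;2;3;4,APCI,verified,[M+H]+ adduct; MID overlapped by [M]+ at m/z 349 - prefer m/z 349 or correct externally
aspartic acid 3TMS,349,349.1561,C13H31NO4Si3,1;2;3;4,APCI,verified,[M]+ radical cation
aspartic acid 3TMS,232,232.1189,C9H22NO2Si2,2;3;4,APCI,verified,loss of the 1-C carboxy-TMS group; near base peak - acquire with split injection
aspartic acid 3TMS,234,,,1;2,APCI,requires-user-input,supply certified m/z and ion formula for the {1;2} fragment
aspartic acid 3TMS,216,,,2;3,APCI,requires-user-input,supply certified m/z and ion formula for the {2;3} fragment
aspartic acid 3TMS,203,,,3;4,APCI,requires-user-input,supply certified m/z and ion formula for the {3;4} fragment
aspartic acid 2TMS,262,,,1;2;3;4,APCI,requires-user-input,alternative whole-backbone fragment; supply certified formula
aspartic acid 2TMS,245,,,1;2;3;4,APCI,requires-user-input,alternative whole-backbone fragment; supply certified formula
aspartic acid 2TMS,160,,,2;3;4,APCI,requires-user-input,alternative {2;3;4} fragment; supply certified formula
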