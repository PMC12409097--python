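analyte,ion_label,exact_mz,ion_formula,backbone_positions,ionization,status,notes
aspartic acid 3TMS,234,234.0982,C8H20NO3Si2,1;2,APCI,synthetic-standin,synthetic stand-in formula for the {1;2} fragment (plausible composition; replace with certified values)
aspartic acid 3TMS,216,216.0876,C8H18NO2Si2,2;3,APCI,synthetic-standin,synthetic stand-in formula for the {2;3} fragment (plausible composition; replace with certified values)
aspartic acid 3TMS,203,203.0560,C7H15O3Si2,3;4,APCI,synthetic-standin,synthetic stand-in formula for the {3;4} fragment (plausible composition; replace with certified values)
aspartic acid 2TMS,262,262.0931,C9H20NO4Si2,1;2;3;4,APCI,synthetic-standin,synthetic stand-in formula (M-CH3 composition; replace with certified values)
aspartic acid 2TMS,245,245.0903,C9H19NO3Si2,1;2;3;4,APCI,synthetic-standin,synthetic stand-in formula (replace with certified values)
aspartic acid 2TMS,160,160.0794,C6H14NO2Si,2;3;4,APCI,synthetic-standin,synthetic stand-in formula (replace with certified values)
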