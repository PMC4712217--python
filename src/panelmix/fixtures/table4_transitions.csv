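subgroup,from_type,to_type,prob
early_to_middle,GAD,GAD,0.58
early_to_middle,GAD,DA,0.20
early_to_middle,GAD,C-DA,0.03
early_to_middle,GAD,Np,0.19
early_to_middle,DA,GAD,0.05
early_to_middle,DA,DA,0.51
early_to_middle,DA,C-DA,0.10
early_to_middle,DA,Np,0.34
early_to_middle,C-DA,GAD,0.10
early_to_middle,C-DA,DA,0.53
early_to_middle,C-DA,C-DA,0.17
early_to_middle,C-DA,Np,0.20
early_to_middle,Np,GAD,0.08
early_to_middle,Np,DA,0.15
early_to_middle,Np,C-DA,0.02
early_to_middle,Np,Np,0.75
middle_to_late,GAD,GAD,0.88
middle_to_late,GAD,DA,0.01
middle_to_late,GAD,C-DA,0.00
middle_to_late,GAD,Np,0.11
middle_to_late,DA,GAD,0.03
middle_to_late,DA,DA,0.45
middle_to_late,DA,C-DA,0.06
middle_to_late,DA,Np,0.46
middle_to_late,C-DA,GAD,0.19
middle_to_late,C-DA,DA,0.38
middle_to_late,C-DA,C-DA,0.00
middle_to_late,C-DA,Np,0.43
middle_to_late,Np,GAD,0.04
middle_to_late,Np,DA,0.03
middle_to_late,Np,C-DA,0.00
middle_to_late,Np,Np,0.93
males,GAD,GAD,0.41
males,GAD,DA,0.41
males,GAD,C-DA,0.02
males,GAD,Np,0.16
males,DA,GAD,0.04
males,DA,DA,0.54
males,DA,C-DA,0.12
males,DA,Np,0.30
males,C-DA,GAD,0.10
males,C-DA,DA,0.52
males,C-DA,C-DA,0.13
males,C-DA,Np,0.25
males,Np,GAD,0.04
males,Np,DA,0.19
males,Np,C-DA,0.03
males,Np,Np,0.74
females,GAD,GAD,0.80
females,GAD,DA,0.03
females,GAD,C-DA,0.01
females,GAD,Np,0.16
females,DA,GAD,0.08
females,DA,DA,0.37
females,DA,C-DA,0.03
females,DA,Np,0.52
females,C-DA,GAD,0.19
females,C-DA,DA,0.43
females,C-DA,C-DA,0.14
females,C-DA,Np,0.25
females,Np,GAD,0.09
females,Np,DA,0.05
females,Np,C-DA,0.01
females,Np,Np,0.85
higher_quality,GAD,GAD,0.73
higher_quality,GAD,DA,0.06
higher_quality,GAD,C-DA,0.02
higher_quality,GAD,Np,0.19
higher_quality,DA,GAD,0.03
higher_quality,DA,DA,0.48
higher_quality,DA,C-DA,0.06
higher_quality,DA,Np,0.43
higher_quality,C-DA,GAD,0.09
higher_quality,C-DA,DA,0.52
higher_quality,C-DA,C-DA,0.07
higher_quality,C-DA,Np,0.32
higher_quality,Np,GAD,0.07
higher_quality,Np,DA,0.09
higher_quality,Np,C-DA,0.01
higher_quality,Np,Np,0.83
poorer_quality,GAD,GAD,0.64
poorer_quality,GAD,DA,0.25
poorer_quality,GAD,C-DA,0.02
poorer_quality,GAD,Np,0.09
poorer_quality,DA,GAD,0.11
poorer_quality,DA,DA,0.51
poorer_quality,DA,C-DA,0.19
poorer_quality,DA,Np,0.19
poorer_quality,C-DA,GAD,0.16
poorer_quality,C-DA,DA,0.47
poorer_quality,C-DA,C-DA,0.23
poorer_quality,C-DA,Np,0.14
poorer_quality,Np,GAD,0.11
poorer_quality,Np,DA,0.27
poorer_quality,Np,C-DA,0.05
poorer_quality,Np,Np,0.57
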