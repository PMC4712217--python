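subgroup,wave,type,count,percent
early_to_middle,1,GAD,107,11.6
early_to_middle,1,DA,255,27.6
early_to_middle,1,C-DA,81,8.8
early_to_middle,1,Np,480,52.0
early_to_middle,2,GAD,105,11.4
early_to_middle,2,DA,278,30.1
early_to_middle,2,C-DA,78,8.5
early_to_middle,2,Np,462,50.1
early_to_middle,3,GAD,120,13.0
early_to_middle,3,DA,286,31.0
early_to_middle,3,C-DA,69,7.5
early_to_middle,3,Np,448,48.5
early_to_middle,4,GAD,133,14.4
early_to_middle,4,DA,265,28.7
early_to_middle,4,C-DA,57,6.2
early_to_middle,4,Np,468,50.7
early_to_middle,5,GAD,125,13.5
early_to_middle,5,DA,263,28.5
early_to_middle,5,C-DA,54,5.9
early_to_middle,5,Np,481,52.1
middle_to_late,1,GAD,75,19.2
middle_to_late,1,DA,67,17.2
middle_to_late,1,C-DA,21,5.4
middle_to_late,1,Np,227,58.2
middle_to_late,2,GAD,83,21.3
middle_to_late,2,DA,64,16.4
middle_to_late,2,C-DA,8,2.1
middle_to_late,2,Np,235,60.3
middle_to_late,3,GAD,79,20.3
middle_to_late,3,DA,53,13.6
middle_to_late,3,C-DA,6,1.5
middle_to_late,3,Np,252,64.6
middle_to_late,4,GAD,76,19.5
middle_to_late,4,DA,43,11.0
middle_to_late,4,C-DA,7,1.8
middle_to_late,4,Np,264,67.7
middle_to_late,5,GAD,82,21.0
middle_to_late,5,DA,45,11.5
middle_to_late,5,C-DA,4,1.0
middle_to_late,5,Np,259,66.4
males,1,GAD,44,6.9
males,1,DA,231,36.3
males,1,C-DA,81,12.7
males,1,Np,281,44.1
males,2,GAD,44,6.9
males,2,DA,253,39.7
males,2,C-DA,62,9.7
males,2,Np,278,43.6
males,3,GAD,46,7.2
males,3,DA,260,40.8
males,3,C-DA,54,8.5
males,3,Np,277,43.5
males,4,GAD,47,7.4
males,4,DA,233,36.6
males,4,C-DA,52,8.2
males,4,Np,305,47.9
males,5,GAD,46,7.2
males,5,DA,239,37.5
males,5,C-DA,47,7.4
males,5,Np,305,47.9
females,1,GAD,138,20.4
females,1,DA,91,13.5
females,1,C-DA,21,3.1
females,1,Np,426,63.0
females,2,GAD,144,21.3
females,2,DA,89,13.2
females,2,C-DA,24,3.6
females,2,Np,419,62.0
females,3,GAD,153,22.6
females,3,DA,79,11.7
females,3,C-DA,21,3.1
females,3,Np,423,62.6
females,4,GAD,162,24.0
females,4,DA,75,11.1
females,4,C-DA,12,1.8
females,4,Np,427,63.2
females,5,GAD,161,23.8
females,5,DA,69,10.2
females,5,C-DA,11,1.6
females,5,Np,435,64.3
higher_quality,1,GAD,127,12.2
higher_quality,1,DA,231,22.1
higher_quality,1,C-DA,59,5.6
higher_quality,1,Np,628,60.1
higher_quality,2,GAD,136,13.0
higher_quality,2,DA,228,21.8
higher_quality,2,C-DA,55,5.3
higher_quality,2,Np,626,59.9
higher_quality,3,GAD,135,12.9
higher_quality,3,DA,225,21.5
higher_quality,3,C-DA,42,4.0
higher_quality,3,Np,643,61.5
higher_quality,4,GAD,148,14.2
higher_quality,4,DA,206,19.7
higher_quality,4,C-DA,29,2.8
higher_quality,4,Np,662,63.3
higher_quality,5,GAD,146,14.0
higher_quality,5,DA,206,19.7
higher_quality,5,C-DA,26,2.5
higher_quality,5,Np,667,63.8
poorer_quality,1,GAD,55,20.5
poorer_quality,1,DA,91,34.0
poorer_quality,1,C-DA,43,16.0
poorer_quality,1,Np,79,29.5
poorer_quality,2,GAD,52,19.4
poorer_quality,2,DA,114,42.5
poorer_quality,2,C-DA,31,11.6
poorer_quality,2,Np,71,26.5
poorer_quality,3,GAD,64,23.9
poorer_quality,3,DA,114,42.5
poorer_quality,3,C-DA,33,12.3
poorer_quality,3,Np,57,21.3
poorer_quality,4,GAD,61,22.8
poorer_quality,4,DA,102,38.1
poorer_quality,4,C-DA,35,13.1
poorer_quality,4,Np,70,26.1
poorer_quality,5,GAD,61,22.8
poorer_quality,5,DA,102,38.1
poorer_quality,5,C-DA,32,11.9
poorer_quality,5,Np,73,27.2
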