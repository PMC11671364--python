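pathway_id	metabolite_id
path01	gc_001
path01	gc_002
path01	gc_030
path01	gc_031
path01	polar_030
path02	gc_033
path02	polar_031
path02	gc_034
path02	polar_057
path02	gc_058
path03	polar_001
path03	polar_002
path03	polar_003
path03	polar_032
path03	polar_033
path04	polar_010
path04	polar_036
path04	polar_037
path04	gc_036
path04	gc_037
path05	polar_011
path05	polar_038
path05	polar_039
path05	gc_038
path06	gc_010
path06	polar_040
path06	polar_041
path06	gc_039
path06	gc_040
path07	gc_011
path07	polar_042
path07	gc_041
path07	polar_040
path08	polar_020
path08	gc_042
path08	gc_043
path08	polar_043
path08	gc_044
path09	gc_020
path09	polar_044
path09	polar_045
path09	gc_045
path09	gc_046
path09	polar_046
path10	gc_021
path10	gc_047
path10	polar_047
path10	gc_048
path10	polar_048
path11	gc_022
path11	gc_049
path11	gc_050
path11	polar_049
path12	polar_050
path12	polar_051
path12	gc_051
path12	gc_052
path12	polar_052
path13	polar_053
path13	polar_054
path13	gc_053
path13	gc_054
path14	lipid_001
path14	lipid_002
path14	lipid_003
path14	gc_055
path15	lipid_004
path15	lipid_005
path15	lipid_006
path15	polar_055
path15	gc_056
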