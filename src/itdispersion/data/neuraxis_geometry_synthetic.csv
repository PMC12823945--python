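label,position_cm,major_radius_cm,minor_radius_cm,tissue_fraction
CM,0.0,2.399,0.650,0.15
C3,7.0,1.600,0.450,0.45
C5,11.0,1.450,0.420,0.45
C7,15.0,1.350,0.380,0.42
T2,20.0,1.300,0.350,0.40
T4,26.0,1.250,0.340,0.40
T5,29.0,1.220,0.340,0.38
T7,35.0,1.200,0.350,0.36
T9,41.0,1.250,0.380,0.34
T11,47.0,1.400,0.450,0.30
L1,50.0,1.598,0.500,0.25
L2,53.0,1.550,0.480,0.20
L5,61.0,1.300,0.420,0.10
S3,65.0,1.200,0.390,0.05
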