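label,quantity,reference_value,measured_value
CM,diameter,1.30,1.32
T2,diameter,0.70,0.71
L1,diameter,1.00,1.02
S3,diameter,0.78,0.80
CM,area,4.90,5.01
T2,area,1.43,1.49
L1,area,2.51,2.63
S3,area,1.47,1.53
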