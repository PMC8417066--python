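,p1,p2,p3,p4,p5,n1,n2,n3,n4,n5
p1,1.0,0.66,0.48,0.53,0.38,0.24,0.51,0.34,0.51,0.41
p2,0.66,1.0,0.72,0.59,0.51,0.32,0.6,0.43,0.61,0.45
p3,0.48,0.72,1.0,0.53,0.44,0.3,0.51,0.37,0.57,0.29
p4,0.53,0.59,0.53,1.0,0.71,0.4,0.6,0.5,0.66,0.5
p5,0.38,0.51,0.44,0.71,1.0,0.37,0.48,0.38,0.54,0.36
n1,0.24,0.32,0.3,0.4,0.37,1.0,0.57,0.44,0.48,0.38
n2,0.51,0.6,0.51,0.6,0.48,0.57,1.0,0.47,0.75,0.49
n3,0.34,0.43,0.37,0.5,0.38,0.44,0.47,1.0,0.52,0.48
n4,0.51,0.61,0.57,0.66,0.54,0.48,0.75,0.52,1.0,0.51
n5,0.41,0.45,0.29,0.5,0.36,0.38,0.49,0.48,0.51,1.0
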