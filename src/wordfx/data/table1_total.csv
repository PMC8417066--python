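,p1,p2,p3,p4,p5,n1,n2,n3,n4,n5
p1,1.0,0.67,0.44,0.51,0.36,0.26,0.43,0.32,0.49,0.41
p2,0.67,1.0,0.7,0.57,0.46,0.3,0.49,0.41,0.54,0.41
p3,0.44,0.7,1.0,0.52,0.42,0.26,0.41,0.36,0.5,0.22
p4,0.51,0.57,0.52,1.0,0.7,0.36,0.46,0.47,0.57,0.43
p5,0.36,0.46,0.42,0.7,1.0,0.34,0.41,0.35,0.49,0.32
n1,0.26,0.3,0.26,0.36,0.34,1.0,0.62,0.45,0.53,0.41
n2,0.43,0.49,0.41,0.46,0.41,0.62,1.0,0.49,0.74,0.48
n3,0.32,0.41,0.36,0.47,0.35,0.45,0.49,1.0,0.5,0.47
n4,0.49,0.54,0.5,0.57,0.49,0.53,0.74,0.5,1.0,0.55
n5,0.41,0.41,0.22,0.43,0.32,0.41,0.48,0.47,0.55,1.0
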