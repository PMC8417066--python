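,p1,p2,p3,p4,p5,n1,n2,n3,n4,n5
p1,1.0,0.66,0.41,0.54,0.38,0.37,0.55,0.39,0.57,0.5
p2,0.66,1.0,0.67,0.57,0.47,0.44,0.65,0.51,0.67,0.53
p3,0.41,0.67,1.0,0.52,0.42,0.38,0.57,0.45,0.61,0.33
p4,0.54,0.57,0.52,1.0,0.72,0.45,0.6,0.52,0.67,0.51
p5,0.38,0.47,0.42,0.72,1.0,0.43,0.53,0.4,0.56,0.38
n1,0.37,0.44,0.38,0.45,0.43,1.0,0.59,0.41,0.52,0.36
n2,0.55,0.65,0.57,0.6,0.53,0.59,1.0,0.47,0.72,0.43
n3,0.39,0.51,0.45,0.52,0.4,0.41,0.47,1.0,0.51,0.46
n4,0.57,0.67,0.61,0.67,0.56,0.52,0.72,0.51,1.0,0.51
n5,0.5,0.53,0.33,0.51,0.38,0.36,0.43,0.46,0.51,1.0
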