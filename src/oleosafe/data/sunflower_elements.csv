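symbol,concentration,sd,lod,loq
Al,1.0401,0.0199,0.0114,0.0380
As,,,0.0048,0.0159
Cd,,,0.0007,0.0024
Co,,,0.0016,0.0054
Cr,0.0242,0.0049,0.0015,0.0049
Cu,0.2791,0.0094,0.0014,0.0048
Fe,1.6637,0.0393,0.0193,0.0644
Mg,,,0.0675,0.2251
Mn,0.2372,0.0051,0.0004,0.0012
Ni,,,0.0023,0.0077
Pb,,,0.0070,0.0233
Se,,,0.0080,0.0267
Zn,6.6228,0.0788,0.0018,0.0060
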