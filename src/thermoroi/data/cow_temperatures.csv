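cow_id,RT,LU,AA
Cow 1,38.9,36.5,37.6
Cow 2,38.8,36.7,37.4
Cow 3,39.0,37.2,38.1
Cow 4,38.2,36.4,37.1
Cow 5,38.6,35.2,37.2
Cow 6,38.6,35.7,37.3
Cow 7,38.8,36.5,37.2
Cow 8,38.4,36.2,37.4
Cow 9,38.4,36.4,36.9
Cow 10,39.7,37.5,38.5
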