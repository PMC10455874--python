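GEIC01017550
GEIC01017551
GEIC01017552
GEIC01017553
GEIC01017554
GEIC01017555
GEIC01017556
GEIC01017557
GEIC01017558
GEIC01017559
GEIC01017560
GEIC01019170
GEIC01019171
GEIC01019172
GEIC01019173
GEIC01019174
GEIC01019175
GEIC01019176
GEIC01019177
GEIC01019178
GEIC01019179
GEIC01019180
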