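STROMAL_SIGNATURE	synthetic fixture	G000304	G000305	G000306	G000307	G000308	G000309	G000310	G000311	G000312	G000313
IMMUNE_SIGNATURE	synthetic fixture	G000314	G000315	G000316	G000317	G000318	G000319	G000320	G000321	G000322	G000323
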