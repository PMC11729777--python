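gender,n_artists
male,32
female,6
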