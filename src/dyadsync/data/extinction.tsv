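wavelength_nm	ext_hbo	ext_hbr
760	0.5860	1.5485
850	1.0580	0.6913
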