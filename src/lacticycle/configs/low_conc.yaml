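# Low-titer scenario: 1 g/L lactic acid in spent media (all else baseline).
spent_media:
  lactic_acid_conc: 1.0
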