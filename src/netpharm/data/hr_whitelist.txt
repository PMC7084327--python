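# Components added back after the strict ADME filter: five retained for
# reported hepatoprotective activity, anthraquinone as a principal
# constituent of the herb despite its low drug-likeness score.
HR02
HR03
HR04
HR05
HR09
HR11
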