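# alias	canonical
GRIN2	GRIN2B
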