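IMMUNE_CHECKPOINT_PANEL	na	PDCD1	CTLA4	HAVCR2	LAG3
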