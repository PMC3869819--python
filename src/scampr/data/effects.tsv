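group	count
nonsense	18
missense	181
silent	233
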