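gene	intron_type	donor_pre	acceptor_pre	edited_side	edited_index
NRK	U2-like	GT	AA	acceptor	1
ADARB1	U2-like	GT	AA	acceptor	1
HOOK3	U2-like	GT	AA	acceptor	1
COG8	U2-like	GT	AA	acceptor	1
C14orf37	U2-like	AT	AG	donor	0
NUP210	U12-like	AT	AG	donor	0
CRYZL1	U12-like	AT	AG	donor	0
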