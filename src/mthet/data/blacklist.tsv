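pos	ref	alt
11467	A	G
12684	G	A
12705	C	T
13052	A	G
13095	T	C
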