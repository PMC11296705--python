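pdb_id,chain_pair,kind
6VAU,BA,F-actin
8A2S,ED,F-actin
8A2T,AB,F-actin
3MFP,AB,F-actin
6UC4,EF,boundary
6VAO,CA,C-actin
5YU8,ED,C-actin
3J0S,KL,C-actin
6VAO,CAJF,cofilactin
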