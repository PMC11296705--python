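pdb_id,chains,method,nucleotide,protein_bound,structural_class
1ATN,A,X-RAY,ATP,DNASE I,G
1J6Z,A,X-RAY,ADP-RHO,,G
2BTF,A,X-RAY,ATP,PROFILIN,G
2ZWH,A,X-RAY,ADP,,G
3DAW,A,X-RAY,ATP,TWINFILIN-1,G
3HBT,A,X-RAY,ATP,,G
3J0S,A|B|C|D|E|F|G|H|I|J|K|L,EM,,COFILIN-2,C
3J8I,D|E|F|G|H,EM,ADP,,F
3J8J,A|B|C|D|E|F|G|H|I|J|K,EM,,,tilted
3J8K,A|B|C|D|E|F|G|H|I|J,EM,,,tilted
3MFP,A,EM,ADP,,F
4A7N,A|B|C|D|E,EM,ADP,,F
5ONV,A|B|C|D|E,EM,ADP,,F
5OOC,A|B|C|D|E,EM,ADP JASP,,F
5OOD,A|B|C|D|E,EM,ADP-Pi JASP,,F
5OOE,A|B|C|D|E,EM,ANP,,F
5OOF,A|B|C|D|E,EM,ADP-BeFx,,F
5YU8,A|B|C|D|E,EM,ADP,COFILIN-2,C
6BNO,A|B|C|D|E|F|G|H,EM,ADP,,F
6BNU,A|B|C|D|E|F|G|H,EM,,,F
6DJM,A|B|C|D,EM,AMPPNP,,F
6DJN,A|B|C|D,EM,ADP-Pi,,F
6DJO,A|B|C|D,EM,ADP,,F
6FHL,A|B|C|D|E,EM,ADP-Pi,,F
6KLL,A|B|C|D,EM,ADP,,F
6KLN,A|B|C|D,EM,ADP,,F
6UBY,A|B|C|D|E|F|G,EM,ADP,COFILIN-1,single-cofilin
6UC0,A|B|C|D|E|F|G,EM,ADP,COFILIN-1,C
6UC4,A|B|C|D|E|F|J|K|L,EM,ADP,COFILIN-1,C
6VAO,D|A|B|C|E,EM,ADP,COFILIN-1,C
6VAU,B|A|C|D|E,EM,ADP,,F
7Q8B,A|B|C|D|E,EM,ADP-Pi,,F
7Q8C,A|B|C|D|E,EM,ADP,,F
7Q8S,A|C|D|E|F,EM,ADP,ADF/COFILIN,C
8A2R,C|A|B|D|E,EM,ADP-BeF3,,F
8A2S,C|A|B|D|E,EM,ADP-Pi,,F
8A2T,C|A|B|D|E,EM,ADP,,F
8A2U,C|A|B|D|E,EM,ADP-BeF3,,F
8A2Y,C|A|B|D|E,EM,ADP-Pi,,F
8A2Z,C|A|B|D|E,EM,ADP,,F
8D13,A|B|C,EM,ADP,,F
8D14,A|B|C,EM,ADP-Pi,,F
8D15,A|B|C|D|E|F|G,EM,ADP,,F
8D16,A|B|C|D|E|F|G,EM,ADP-Pi,,F
8D17,A|B|C|D|E|F|G,EM,ADP,,F
8D18,A|B|C|D|E|F|G,EM,ADP,,F
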