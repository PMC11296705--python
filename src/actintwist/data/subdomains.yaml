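# Actin subdomain residue ranges, in mature-sequence ("gene") numbering.
#
# These boundaries follow the conventional four-subdomain partition of the
# actin fold (SD1/SD2 form the outer domain, SD3/SD4 the inner domain; the
# nucleotide cleft lies between SD2 and SD4).  The exact boundary residues
# are a configurable assumption: different authors shift them by a few
# residues, and downstream alignment/PCA accepts any user-supplied table
# with the same schema.
version: 1
numbering: gene
subdomains:
  SD1:
    - [1, 32]
    - [70, 144]
    - [338, 375]
  SD2:
    - [33, 69]
  SD3:
    - [145, 180]
    - [270, 337]
  SD4:
    - [181, 269]
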