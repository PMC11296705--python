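# Declarative chain-merge table for ensemble loading.
#
# Some deposited cofilactin structures split what is biologically one
# protomer position across two chain ids; those segments are concatenated
# and re-labelled before analysis.
version: 1
merges:
  6UC4:
    E: [E, H]
    F: [F, G]
  6UBY:
    G: [G, H]
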