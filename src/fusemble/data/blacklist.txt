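# Genes whose fusions are discarded as likely artifacts: repeat-region,
# paralog-family and pseudogene loci.  One symbol per line; user-extensible.
HLA-DRB5
GOLGA8A
GOLGA8B
PABPC1P2
NBPF10
POTEE
LINC00969
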