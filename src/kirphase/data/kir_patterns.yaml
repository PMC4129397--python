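# Gene-content constraints observed across KIR haplotype studies, expressed
# as 1-based column positions of the bundled 14-locus panel:
#   - three framework (anchor) genes present on every haplotype;
#   - one pair of genes always present or absent together (complete
#     positive LD);
#   - two gene pairs behaving as allelic variants of a single ancestral
#     locus (complete negative LD: exactly one member present).
anchors: [1, 7, 14]
together: [[2, 3]]
exclusive: [[3, 4], [8, 9]]
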