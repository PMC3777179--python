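# Self-designed LINE1 bisulfite-pyrosequencing assays (converted-reference
# coordinates, 1-based inclusive; reverse primers annotated 5'->3' as printed).
# dispensation_order "auto" derives a fully identifiable order from the
# sequence-to-analyze at load time.
assays:
  - name: LINE1_CpG1-6
    reference: X58075_bisulfite_converted
    amplicon_bp: 109
    primers:
      forward: {name: F1, sequence: GGGAGGAGTTAAGATGGT, start: 3, end: 20}
      reverse: {name: R1, sequence: ATAAACCCCATACCTCAAA, start: 111, end: 93}
      sequencing: {name: S1, sequence: GGGAGGAGTTAAGATGGT, start: 3, end: 20}
    sequence_to_analyze: YGAATAGGAATAGTTTYGGTTTATAGTTTTTAGYGTGAGYGAYGTAGAAGAYGGGTGATTTTTGTATTTTTATTTGA
    dispensation_order: auto
  - name: LINE1_CpG7-14
    reference: X58075_bisulfite_converted
    amplicon_bp: 127
    primers:
      forward: {name: F1, sequence: GGTTTATTTTATTAGGGAGTGTTA, start: 105, end: 128}
      reverse: {name: R1, sequence: AAAAAAAAACTCCCTAACC, start: 231, end: 213}
      sequencing: {name: S1, sequence: AGGGAGTGTTAGATAGTGG, start: 118, end: 136}
    sequence_to_analyze: GYGTAGGTTATTGTGTGYGYGTATYGTGYGYGAGTYGAAGTAGGGYGAGGTATTGTTTTATTTGGGAAG
    dispensation_order: auto
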