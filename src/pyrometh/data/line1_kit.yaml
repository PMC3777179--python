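# Commercial LINE1 global-methylation kit: three-CpG read-out and the
# vendor-printed dispensation order (controls interleaved by the vendor in
# an unpublished pattern; honored verbatim, never regenerated).
sequence_to_analyze: TTYGTGGTGYGTYGTTT
dispensation_order: GCTCGTGTAGTCAGTCG
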