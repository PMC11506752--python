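# SYNTHETIC placeholder conserved-sequence-block motifs for the vertebrate
# mitochondrial control region.
#
# The published CSB consensus sequences for Selene control regions are shown
# only graphically in the source study and are not machine-readable, so this
# file ships stand-in IUPAC patterns with the reported domain lengths
# (CSB-D 18 bp, CSB-1 22 bp, CSB-2 17 bp, CSB-3 19 bp). They exercise the
# search machinery and the packaged simulator; REPLACE them with real
# consensus motifs (same key -> pattern layout) for analyses of real data.
motifs:
  CSB-D: "TACATRTATGTAATTACA"
  CSB-1: "TTAATGTAGTAAGARCCGACCA"
  CSB-2: "CAAACCCCCYTACCCCC"
  CSB-3: "TGTCAARCCCCGAAAGCCA"
max_mismatch:
  CSB-D: 2
  CSB-1: 2
  CSB-2: 2
  CSB-3: 2
order: [CSB-D, CSB-1, CSB-2, CSB-3]
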