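# Gene model for junction classification, RPS24-style architecture:
# a constitutive anchor exon (ex4), three microexons (3, 18, 22 bp), and the
# next constitutive exon (ex6).  Coordinates below are synthetic toy values
# on an artificial locus; to analyse real data, replace chrom/strand and the
# exon coordinates with the hg38 values for your transcript annotation
# (e.g. take exon boundaries for RPS24 from a GENCODE GTF; coordinates are
# 1-based inclusive, as in the GTF and in STAR's SJ.out.tab).
gene_id: RPS24_toy
chrom: chr10
strand: "+"
anchor: ex4
terminal: ex6
exons:
  - {name: ex4, start: 901, end: 1000, kind: constitutive}
  - {name: me3, start: 2001, end: 2003, kind: microexon}
  - {name: me18, start: 3001, end: 3018, kind: microexon}
  - {name: me22, start: 4001, end: 4022, kind: microexon}
  - {name: ex6, start: 5001, end: 5200, kind: constitutive}
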