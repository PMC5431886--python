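# Demo pipeline configuration: three species sharing four contigs, one
# dinucleotide diagnostic for the reference species and one single-nucleotide
# diagnostic for the second target species, plus an F1 hybrid sample.
simulate:
  n_contigs: 4
  contig_length: 600
  fragment_bp: 360
  gc_fraction: 0.45
  species: [A_ruthenus, H_huso, A_baerii]
  reference_species: A_ruthenus
  diagnostics:
    - {locus: 0, offset: 20, target: A_ruthenus, target_allele: AG, other_allele: CT}
    - {locus: 1, offset: 20, target: H_huso, target_allele: C, other_allele: G}
  samples:
    - {sample_id: ar1, species: A_ruthenus}
    - {sample_id: hh1, species: H_huso}
    - {sample_id: ab1, species: A_baerii}
    - {sample_id: be1, cross: [H_huso, A_ruthenus]}
  coverage: 20
  error_rate: 0.0
  read_len: 125
preprocess:
  barcode_max_mismatch: 1
  clip_length: 110
map:
  mismatch_cost: 2
  max_gap_length: 3
  max_gaps: 1
  min_fraction_aligned: 0.9
callvars:
  min_coverage: 32
  targets:
    - {target: A_ruthenus, contrasts: [H_huso, A_baerii]}
    - {target: H_huso, contrasts: [A_ruthenus, A_baerii]}
design:
  amplicon_min: 100
  amplicon_max: 300
identify:
  panel: designed
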