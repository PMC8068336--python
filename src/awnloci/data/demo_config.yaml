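# Demo run configuration: a small mixed accession panel exercising the
# whole pipeline (read simulation -> TE call -> haplotype -> groups ->
# CSSL locus mapping).
seed: 7
reads:
  read_length: 100
  depth: 20.0
  error_rate: 0.01
thresholds:
  present_th: 0.80
  absent_th: 0.20
  min_support: 2
  min_years: 2
  min_awn_mm: 3.0
cssl:
  n_lines: 35
  n_years: 3
accessions:
  - {id: jap1, species: japonica, te_present: true, rae2_edit: del1}
  - {id: jap2, species: japonica, te_present: true}
  - {id: ind1, species: indica, rae1_exon2_del: true, rae2_edit: del2b}
  - {id: ind2, species: indica}
  - {id: ruf1, species: rufipogon}
  - {id: ruf2, species: rufipogon, rae2_edit: del2b}
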