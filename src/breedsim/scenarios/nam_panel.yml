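# Nested association mapping panel: 26 founders, one common parent
# crossed to the other 25, each F1 selfed into 200 F2 seeds, and every
# seed advanced by single-seed descent (4 selfing generations, keeping
# the top-phenotype offspring per line) into recombinant inbred lines.
case_study: nam_panel
seed: 42
params:
  n_chr: 1
  n_loci: 300
  n_qtl: 30
  n_founders: 26
  n_rils_per_family: 200
  ssd_gens: 4
  ssd_per_mate: 10
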