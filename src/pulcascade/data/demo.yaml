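# Demo run: a small noise-free synthetic assembly with two planted
# beta-mannan loci, plus proteomics and array stages.
seed: 0
stages: [simulate, annotate, mine, compare, proteomics, arrays]
genome:
  n_contigs: 2
  n_genes_per_contig: 60
  n_puls: 2
  n_decoys: 3
  fp_rate: 0.0
  fn_rate: 0.0
  near_threshold_fraction: 0.0
proteome:
  n_proteins: 300
  conditions: [galactomannan, pectin, mannose]
  n_reps: 3
  effect_proteins: 22
  effect_fold: 8.0
  cv: 0.2
  missing_rate: 0.0
arrays_sim:
  n_extracts: 4
  n_probes: 2
  treatments: [GH26C, buffer]
  deletion_depth: 1.0
  n_spots: 2
  noise_cv: 0.0
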