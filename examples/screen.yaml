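# One 100-female pedigree with a fully penetrant recessive suppressor
# planted at its first mutation. Run:
#   amm report --config examples/screen.yaml --seed 11 --out out/
seed: 11
simulate:
  pedigrees:
    - {n_mutations: 42, n_g2: 10, g3_per_g2: 9}
  baseline_incidence: 0.80
  baseline_median_onset: 22.0
  effects:
    - {pedigree: 1, index: 0, model: recessive, direction: suppress, hazard_multiplier: 0.0}
analysis:
  models: [recessive, additive, dominant]
  mixed: false
criteria:
  min_g3_per_pedigree: 20
  min_hom_var_screened: 2
  min_hom_ref_screened: 2
  alpha: 0.05
saturation:
  total_autosomal_genes: 20000
plots: false
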