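# Desk-scale end-to-end run: simulate -> gwas -> pgi -> impute -> fit ->
# hetero -> correct.  Completes in well under five minutes on one CPU.
#   pgifam run --config examples/demo.yaml --out scratch/demo --seed 17
seed: 17
simulate:
  n_snps: 300
  n_gwas: 5000        # unrelated individuals for weight estimation
  n_families: 1000    # trio families for the within-family stage
  h2_direct: 0.3      # Var(x gamma) / Var(y)
  theta_scale: 0.3    # parental effects: 0.3*gamma plus an orthogonal part
  theta_mode: mixed
  spousal_corr: 0.0
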