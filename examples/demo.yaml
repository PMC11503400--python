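# Demo pipeline: synthetic cohort -> cross-validated fits -> interpretation.
# Run with:  netpoisson all --config examples/demo.yaml --seed 1 --out runs/demo
seed: 1
n_subjects: 2000
terms:
  - sex
  - drugs
  - income
  - DLA_DT     # default-mode / dorsal-attention connectivity
  - AD_CA
  - AD_CGC
  - AD_DT
effects:
  sex: {Male: 1.17, Female: 0.85}
  drugs: {None: 0.76, Father Only: 0.93, Mother Only: 1.12, Both Parents: 1.27}
  DLA_DT: {type: tanh, scale: 0.9, center: -0.5, width: 0.25}
families: [lasso, mcp, scad]
alpha_grid: [1.0]
gamma_grid: [4.0]
k: 10
rule: 1se
n_lambda: 50
lambda_min_ratio: 0.05
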