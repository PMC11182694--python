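# Example four-step study configuration: three protein-lowering drug
# targets plus the two lipase controls.  theta is the simulated outcome
# log-OR per s.d. *higher* protein, so lowering a positive-theta target is
# protective.  Run with:  dtmr run --config examples/config.yml --out results/
steps: [1, 2, 3, 4]
seed: 7
selection:
  p_threshold: 5.0e-8
  clump_r2: 0.10
coloc_priors: [1.0e-4, 1.0e-4, 1.0e-5]
genes:
  - name: ANGPTL3
    sim: {theta: 0.02}          # common variants: no detectable CAD effect
  - name: ANGPTL4
    sim: {theta: 0.56}          # strong protection from lowering
  - name: APOC3
    sim: {theta: 0.11}
  - name: LPL
    sim: {theta: 0.37}          # positive control
  - name: LIPG
    sim: {theta: -0.32}         # opposite-direction control
phewas:
  n_phenotypes: 40
  n_true_effects: 3
  scheme: phenome_wide
step3:
  n_traits: 167
  concordance_rho: 0.91
step4:
  tg_shift: -0.81
  or_per_allele: 0.71
  studies:
    - {study: DiscoveryExomes, n_carriers: 1200, n_noncarriers: 120000}
    - {study: Biobank, n_carriers: 900, n_noncarriers: 180000}
    - {study: CaseControl, n_carriers: 300, n_noncarriers: 40000}
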