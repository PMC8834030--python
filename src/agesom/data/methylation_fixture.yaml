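# Default methylation cohort: five co-methylation modules planted directly
# on the promoter-methylation layer under the seven-group scheme (fetal
# group included): monotone demethylation, three age-swept
# hyper-methylation peaks, monotone methylation gain. Expression follows
# antagonistically.
scheme: methylation
n_per_group: 6
n_background_genes: 2000
noise_sd: 0.3
baseline_beta: 0.3
baseline_expression: 7.0
modes:
  - {shape: monotone_down, amplitude: 2.0, n_genes: 200, coupling: antagonistic, layer: methylation}
  - {shape: peak, peak_center: 0.25, peak_sigma: 0.1, amplitude: 2.0, n_genes: 200, coupling: antagonistic, layer: methylation}
  - {shape: peak, peak_center: 0.5, peak_sigma: 0.1, amplitude: 2.0, n_genes: 200, coupling: antagonistic, layer: methylation}
  - {shape: peak, peak_center: 0.75, peak_sigma: 0.1, amplitude: 2.0, n_genes: 200, coupling: antagonistic, layer: methylation}
  - {shape: monotone_up, amplitude: 2.0, n_genes: 200, coupling: antagonistic, layer: methylation}
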