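# Default expression cohort: seven co-expression modules whose age courses
# sweep from a newborn maximum to a late-adult maximum (monotone decay,
# four age-swept activation peaks, monotone rise) plus a U-shaped
# developmental-reversal module. Six samples per postnatal age group.
# Peak widths (sigma 0.10 on the normalized age axis) keep the module
# profiles mutually distinguishable (|r| <= ~0.5).
scheme: expression
n_per_group: 6
n_background_genes: 2000
noise_sd: 0.3
baseline_beta: 0.3
baseline_expression: 7.0
modes:
  - {shape: monotone_down, amplitude: 2.0, n_genes: 200, coupling: antagonistic}
  - {shape: peak, peak_center: 0.2, peak_sigma: 0.1, amplitude: 2.0, n_genes: 200, coupling: antagonistic}
  - {shape: peak, peak_center: 0.4, peak_sigma: 0.1, amplitude: 2.0, n_genes: 200, coupling: antagonistic}
  - {shape: peak, peak_center: 0.6, peak_sigma: 0.1, amplitude: 2.0, n_genes: 200, coupling: antagonistic}
  - {shape: peak, peak_center: 0.8, peak_sigma: 0.1, amplitude: 2.0, n_genes: 200, coupling: antagonistic}
  - {shape: monotone_up, amplitude: 2.0, n_genes: 200, coupling: antagonistic}
  - {shape: U, amplitude: 2.0, n_genes: 200, coupling: decoupled}
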