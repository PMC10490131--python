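# Reference Rolie-Poly molecular parameters for completely monodisperse
# entangled linear lambda-DNA solutions at four entangled concentrations,
# as extracted from linear-viscoelastic characterization of those solutions.
# These parameter sets generate the steady-shear validation curves for the
# inverse solver.  eta_p in Pa s, tau_D and tau_R in s, concentration in
# mg/mL; chi_max and beta dimensionless.
concentrations:
  - {concentration: 0.82, eta_p: 12.4, tau_D: 87.0, tau_R: 11.0, chi_max: 18.0, beta: 20.0}
  - {concentration: 1.01, eta_p: 22.6, tau_D: 109.0, tau_R: 14.0, chi_max: 18.0, beta: 13.0}
  - {concentration: 1.55, eta_p: 474.4, tau_D: 1006.0, tau_R: 21.0, chi_max: 18.0, beta: 5.0}
  - {concentration: 2.06, eta_p: 4811.7, tau_D: 4092.0, tau_R: 29.0, chi_max: 18.0, beta: 1.0}
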