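# Admissible ranges of the Rolie-Poly molecular parameters for entangled
# aqueous polymer (e.g. lambda-DNA) solutions, with the sampling scale used
# for surrogate training and inverse-solver restarts.  SI units.
eta_p: {min: 1.0, max: 6000.0, scale: log, units: "Pa s"}
tau_D: {min: 1.0, max: 5000.0, scale: log, units: "s"}
tau_R: {min: 1.0, max: 50.0, scale: log, units: "s"}
chi_max: {min: 15.0, max: 20.0, scale: linear, units: ""}
beta: {min: 1.0, max: 25.0, scale: linear, units: ""}
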