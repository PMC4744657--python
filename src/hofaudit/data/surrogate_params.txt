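# Surrogate force-field defaults.
# Scalars: key value.  Per-element: sigma/epsilon ELEM value.
# Bond reference lengths: b0 ELEM ELEM value (Å); unlisted pairs use
# the covalent-radius sum.
k_bond 300.0          # kcal/mol/A^2
k_angle 50.0          # kcal/mol/rad^2
theta0_deg 109.47
epsilon_default 0.1   # kcal/mol
aqueous_factor 0.6    # scales well depths in aqueous phase
# ideal X-H bond lengths
b0 C H 1.09
b0 N H 1.01
b0 O H 0.96
b0 S H 1.34
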