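# Default parameter set for the CO2-based batch fermentation model.
# Sugar and ethanol are algebraic in cumulative CO2: S = S0 - kS*CO2,
# E = E0 + kE*CO2. Temperature laws take T in degC:
#   mu_max(T) = a*ln(T) + b        [1/h]
#   r_vdk(T)  = c*T^2 + d*T + e    [1/h]
kS: 0.372       # gS / L CO2
kE: 0.162       # gE / L CO2
KS: 12.0        # g/L, Monod half-saturation
Cp_max: 2.18    # L CO2 / g sugar, carrying-capacity factor
kV: 1.74e-2     # ppm VDK / L CO2
a: 1.41         # 1/h
b: -3.89        # 1/h
c: -3.0e-4      # 1/(degC^2 h)
d: 1.6e-2       # 1/(degC h)
e: -0.175       # 1/h
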