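# Default parameter set for the biomass-based batch fermentation model.
# Yields are per gram of biomass produced; temperature laws take T in degC:
#   mu_max(T) = a*ln(T) + b        [1/h]
#   r_vdk(T)  = c*ln(T) + d        [1/h]
kS: 15.3        # gS/gX
kE: 6.31        # gE/gX
S_min: 13.1     # g/L, growth threshold of the Droop-type rate
delta_X: 1.67e-2  # 1/h, biomass settling rate
kV: 0.651       # ppm VDK / gX
kCO2: 37.1      # L CO2 / gX
a: 0.400        # 1/h
b: -1.1         # 1/h
c: 2.50e-2      # 1/h
d: -5.60e-2     # 1/h
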