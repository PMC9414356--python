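"""Physical constants used throughout the package (SI)."""

#: Gas constant, J/(mol K)
R_GAS = 8.314

#: Vacuum permittivity, F/m
EPS0 = 8.8541878128e-12

#: Relaxation time defining the dielectric glass transition, s
TAU_AT_TG = 100.0
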