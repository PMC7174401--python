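"""Physical constants and unit helpers.

All public APIs carry explicit units in their argument names
(``_um``, ``_s``, ``_hz``, ``_k``, ``_pa_s``).  Internally, viscosity and
modulus computations convert to SI.
"""

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN_J_PER_K: float = 1.380649e-23

#: FWHM of a Gaussian = FWHM_SIGMA_FACTOR * sigma.
FWHM_SIGMA_FACTOR: float = 2.3548200450309493  # 2*sqrt(2*ln 2)

UM_PER_M: float = 1e6
M_PER_UM: float = 1e-6
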