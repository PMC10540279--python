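"""Physical constants and numerical tolerances used across the package."""

#: Gas constant in kcal mol^-1 K^-1 (CODATA, converted from J).
GAS_CONSTANT_KCAL = 1.98720425e-3

#: Default temperature (K) for er <-> free-energy conversions.
DEFAULT_TEMPERATURE_K = 298.15

#: Geometric degeneracy tolerance in Angstrom: below this, points are treated
#: as coincident/collinear/coplanar and descriptor operations raise.
DEGENERACY_TOL = 1e-6
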