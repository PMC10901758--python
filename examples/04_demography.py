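"""Demography scalings: generation time and per-generation mutation rate.

Converts age at maturity and adult survival into a generation time, then a
per-year mutation rate into per-generation units — the scalings applied to
the axes of coalescent demography output.
"""

import phyloconv as pc

p = pc.demography_params(a=1.0, s=0.5, mu_year=3e-9)
print(f"maturation age a        = {p.a} years")
print(f"adult survival s        = {p.s}")
print(f"generation time g       = {p.g} years   (g = a + s/(1-s))")
print(f"mutation rate per year  = {p.mu_year:.1e}")
print(f"mutation rate per gen.  = {p.mu_gen:.1e}  (mu_year * g)")
print(
    "Coalescent methods report time in generations scaled by mu; these two\n"
    "numbers convert their output to calendar years and census-style sizes."
)
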