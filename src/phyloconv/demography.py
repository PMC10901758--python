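"""Closed-form demography scalings used when rescaling coalescent output.

Generation time follows the age-at-maturity / adult-survival relation
g = a + s / (1 - s), and a per-year mutation rate is converted to the
per-generation rate mu_gen = mu_year * g.  (The coalescent inference itself
is out of scope here; these are the scalings applied to its axes.)
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class DemographyParams:
    a: float  # sexual maturation age, years
    s: float  # expected adult survival rate
    g: float  # generation time, years
    mu_year: float  # mutation rate per site per year
    mu_gen: float  # mutation rate per site per generation


def generation_time(a: float, s: float) -> float:
    """g = a + s / (1 - s); a > 0 years, 0 <= s < 1."""
    if a <= 0:
        raise ValueError("maturation age must be positive")
    if not 0.0 <= s < 1.0:
        raise ValueError("survival rate must lie in [0, 1)")
    return a + s / (1.0 - s)


def per_generation_rate(mu_year: float, g: float) -> float:
    """mu_gen = mu_year * g; both inputs positive."""
    if mu_year <= 0 or g <= 0:
        raise ValueError("mutation rate and generation time must be positive")
    return mu_year * g


def demography_params(a: float, s: float, mu_year: float) -> DemographyParams:
    g = generation_time(a, s)
    return DemographyParams(
        a=a, s=s, g=g, mu_year=mu_year, mu_gen=per_generation_rate(mu_year, g)
    )
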