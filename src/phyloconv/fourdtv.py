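"""4DTv divergence between homologous coding-sequence pairs.

The raw 4DTv is the fraction of strictly four-fold degenerate third
positions at which the two sequences differ by a transversion (one purine,
one pyrimidine).  The corrected distance applies the transversion component
of the HKY substitution model,

    d = -2 pi_R pi_Y ln(1 - Q / (2 pi_R pi_Y)),

with Q the raw proportion and pi_R/pi_Y the purine/pyrimidine frequencies
pooled over both sequences' retained third positions.  In the equal-
frequency limit (pi_R = pi_Y = 1/2) this reduces to the classic
two-parameter transversion correction -0.5 ln(1 - 2Q).  The correction is
undefined (flagged) once Q >= 2 pi_R pi_Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import Alignment, extract_4d_sites

_PURINES = frozenset("AG")


@dataclass
class FourDTvRecord:
    pair_id: tuple[str, str]
    n_4d_sites: int
    raw_4dtv: float
    corrected_4dtv: float  # nan when undefined
    pi_R: float
    pi_Y: float

    @property
    def corrected_defined(self) -> bool:
        return np.isfinite(self.corrected_4dtv)


def hky_transversion_correction(
    raw: float, pi_R: float, pi_Y: float
) -> float:
    """HKY transversion-component distance; nan outside the log domain."""
    c = 2.0 * pi_R * pi_Y
    if c <= 0.0 or raw >= c:
        return float("nan")
    return -c * np.log(1.0 - raw / c)


def pairwise_4dtv(
    codon_pair_aln: Alignment,
    frequencies: str | tuple[float, float] = "empirical",
) -> FourDTvRecord:
    """4DTv record for a two-taxon codon alignment.

    ``frequencies`` is ``"empirical"`` (purine/pyrimidine composition pooled
    over both sequences' retained third positions, the default), ``"equal"``
    (pi_R = pi_Y = 1/2), or an explicit ``(pi_R, pi_Y)`` pair.
    """
    if codon_pair_aln.n_taxa != 2:
        raise ValueError("pairwise_4dtv requires exactly two taxa")
    sites = extract_4d_sites(codon_pair_aln)
    pair = (codon_pair_aln.taxon_ids[0], codon_pair_aln.taxon_ids[1])
    if sites.n_sites == 0:
        return FourDTvRecord(pair, 0, float("nan"), float("nan"), 0.5, 0.5)
    thirds = sites.third_position_matrix  # (2, n)
    a, b = thirds[0], thirds[1]
    is_tv = np.array(
        [(x in _PURINES) != (y in _PURINES) for x, y in zip(a, b)]
    )
    raw = float(is_tv.mean())
    if frequencies == "empirical":
        pooled = np.concatenate([a, b])
        pi_R = float(np.mean([ch in _PURINES for ch in pooled]))
        pi_Y = 1.0 - pi_R
    elif frequencies == "equal":
        pi_R = pi_Y = 0.5
    else:
        pi_R, pi_Y = float(frequencies[0]), float(frequencies[1])
    corrected = hky_transversion_correction(raw, pi_R, pi_Y)
    return FourDTvRecord(pair, sites.n_sites, raw, corrected, pi_R, pi_Y)


def summarize_4dtv(
    records: list[FourDTvRecord],
    bin_width: float = 0.01,
    use_corrected: bool = True,
) -> dict:
    """Histogram of 4DTv values with local maxima ("peaks").

    A bin is a mode when its count strictly exceeds both neighbors (the
    first/last bins compare against a single neighbor).  Returns a dict with
    ``edges``, ``counts``, and ``modes`` (bin-center positions).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not records:
        raise ValueError("no 4DTv records to summarize")
    vals = np.array(
        [
            (r.corrected_4dtv if use_corrected else r.raw_4dtv)
            for r in records
        ]
    )
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite 4DTv values to summarize")
    lo = 0.0
    hi = max(vals.max() + bin_width, bin_width)
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    padded = np.concatenate([[-1], counts, [-1]])
    modes = [
        float(centers[i])
        for i in range(len(counts))
        if padded[i + 1] > padded[i] and padded[i + 1] > padded[i + 2]
    ]
    return {"edges": edges, "counts": counts, "centers": centers, "modes": modes}
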