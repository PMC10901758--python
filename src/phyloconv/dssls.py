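"""The dSSLS convergence test.

For each gene, per-site log-likelihood support (SSLS) is computed under the
species tree H0 and two alternatives: H1 (targets forced monophyletic) and
H1' (an equally distorted control).  The per-site differences
dL = lnL(H0) - lnL(H1) shift negative when the data favor H1.  A gene is
called in favor of H1 only when the dL(H0-H1) distribution separates from
the dL(H0-H1') control distribution (two-sample Kolmogorov-Smirnov test),
the mean dL(H0-H1) is negative, and the shift is stronger toward H1 than
toward the control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .likelihood import FittedGeneModel

FAVORS_H1 = "favors_H1"
NO_SUPPORT = "no_support"


@dataclass
class DeltaSSLSResult:
    gene_id: str
    delta_H0_H1: np.ndarray
    delta_H0_H1prime: np.ndarray
    mean_delta_H0_H1: float
    mean_delta_H0_H1prime: float
    ks_statistic: float = np.nan
    ks_p: float = np.nan
    verdict: str | None = None

    @property
    def n_sites(self) -> int:
        return len(self.delta_H0_H1)


def compute_delta(
    fit_h0: FittedGeneModel,
    fit_h1: FittedGeneModel,
    fit_h1p: FittedGeneModel,
) -> DeltaSSLSResult:
    """Per-site dL vectors; sign convention dL = lnL(H0) - lnL(H1), so
    negative values favor the alternative."""
    n = len(fit_h0.site_logliks)
    if len(fit_h1.site_logliks) != n or len(fit_h1p.site_logliks) != n:
        raise ValueError(
            f"column-count mismatch among fits for gene {fit_h0.gene_id!r}: "
            f"{n}, {len(fit_h1.site_logliks)}, {len(fit_h1p.site_logliks)}"
        )
    d1 = fit_h0.site_logliks - fit_h1.site_logliks
    d2 = fit_h0.site_logliks - fit_h1p.site_logliks
    return DeltaSSLSResult(
        gene_id=fit_h0.gene_id,
        delta_H0_H1=d1,
        delta_H0_H1prime=d2,
        mean_delta_H0_H1=float(d1.mean()),
        mean_delta_H0_H1prime=float(d2.mean()),
    )


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_x - ECDF_y|; the P value is exact (enumeration) when both
    samples have at most 25 observations, asymptotic (Smirnov) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    method = "exact" if (x.size <= 25 and y.size <= 25) else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def classify_gene(
    result: DeltaSSLSResult, alpha: float = 0.05
) -> DeltaSSLSResult:
    """Set the verdict: favors_H1 iff the KS test separates the two dL
    distributions (P < alpha), the mean dL(H0-H1) is negative, and the shift
    toward H1 exceeds the shift toward the control."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    d, p = ks_two_sample(result.delta_H0_H1, result.delta_H0_H1prime)
    result.ks_statistic = d
    result.ks_p = p
    if (
        p < alpha
        and result.mean_delta_H0_H1 < 0.0
        and result.mean_delta_H0_H1 < result.mean_delta_H0_H1prime
    ):
        result.verdict = FAVORS_H1
    else:
        result.verdict = NO_SUPPORT
    return result


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted q values (optional multiple-testing correction; raw P
    values are used by default)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
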