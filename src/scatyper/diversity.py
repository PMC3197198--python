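"""Richness and diversity estimators over cluster-size distributions.

Given the bin sizes from clustering (an abundance vector of positive
integers), this module computes the nonparametric Chao1 richness estimate,
the Shannon-Wiener index (natural log, as in DOTUR; base-2 optional) and the
analytic rarefaction curve E[S_n] via log-binomial coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from scatyper.errors import InvalidParameterError


@dataclass
class AbundanceVector:
    """Bin sizes; derives N, S_obs, singleton (F1) and doubleton (F2) counts."""

    counts: list[int]

    def __post_init__(self):
        self.counts = [int(c) for c in self.counts]
        if not self.counts:
            raise InvalidParameterError("empty abundance vector")
        if any(c < 1 for c in self.counts):
            raise InvalidParameterError("all counts must be >= 1")

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def f1(self) -> int:
        return sum(1 for c in self.counts if c == 1)

    @property
    def f2(self) -> int:
        return sum(1 for c in self.counts if c == 2)


def _as_vector(v) -> AbundanceVector:
    return v if isinstance(v, AbundanceVector) else AbundanceVector(list(v))


def chao1(v, bias_corrected: bool = False) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), falling back to the
    bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) when F2 = 0 (or always,
    when ``bias_corrected`` is set)."""
    v = _as_vector(v)
    if bias_corrected or v.f2 == 0:
        return v.s_obs + v.f1 * (v.f1 - 1) / (2.0 * (v.f2 + 1))
    return v.s_obs + v.f1**2 / (2.0 * v.f2)


def shannon(v, base: float | None = None) -> float:
    """Shannon-Wiener index H' = -sum p_i log p_i (natural log by default)."""
    v = _as_vector(v)
    p = np.asarray(v.counts, dtype=float) / v.n
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(0.0, h)


def rarefaction_curve(v, depths) -> np.ndarray:
    """Analytic rarefaction: expected richness at each subsampling depth.

    E[S_n] = sum_i [1 - C(N - n_i, n) / C(N, n)], evaluated with log-binomial
    coefficients for numerical stability.  Depths must not exceed N.
    """
    v = _as_vector(v)
    depths = np.atleast_1d(np.asarray(depths, dtype=int))
    if (depths < 0).any() or (depths > v.n).any():
        raise InvalidParameterError(f"depths must lie in [0, N={v.n}]")
    counts = np.asarray(v.counts, dtype=int)
    N = v.n

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(depths), dtype=float)
    for j, n in enumerate(depths):
        keep = (N - counts) >= n
        p_absent = np.zeros(len(counts))
        if keep.any():
            p_absent[keep] = np.exp(
                log_choose(N - counts[keep], n) - log_choose(N, n)
            )
        out[j] = float((1.0 - p_absent).sum())
    return out
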