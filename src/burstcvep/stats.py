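"""Paired model comparisons: Wilcoxon signed-rank, Stouffer combination,
standardized mean difference, and Bonferroni correction over a family."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

__all__ = ["stouffer_combine", "smd", "wilcoxon_stouffer", "WilcoxonStoufferResult", "bonferroni"]


def stouffer_combine(pvalues) -> tuple[float, float]:
    """Stouffer's method on one-sided p-values.

    z = sum_i Phi^-1(1 - p_i) / sqrt(k); the combined one-sided p is
    1 - Phi(z).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    z = sps.norm.isf(p).sum() / np.sqrt(p.size)
    return float(z), float(sps.norm.sf(z))


def smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference of paired scores: mean(d) / SD(d).

    Identical samples (all differences zero) give 0 by convention; a
    constant non-zero difference has no finite SMD and raises.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    s = d.std(ddof=1)
    if s == 0:
        if np.allclose(d, 0):
            return 0.0
        raise ValueError("constant non-zero paired difference: SMD undefined")
    return float(d.mean() / s)


@dataclasses.dataclass
class WilcoxonStoufferResult:
    wilcoxon_p: np.ndarray  # two-sided p per metric row
    stouffer_z: float
    stouffer_p: float       # two-sided, from |z|
    smd: float


def wilcoxon_stouffer(metric_a, metric_b) -> WilcoxonStoufferResult:
    """Compare two models over participants, combining across metrics.

    ``metric_a`` / ``metric_b``: per-participant scores, either 1-D
    (single metric) or 2-D (k metrics x n participants).  Per row, a
    Wilcoxon signed-rank test gives a two-sided p (reported) and a
    one-sided p (a > b) that enters the Stouffer combination; the combined
    p is two-sided in |z|.  SMD is computed on the row-mean scores.
    """
    a = np.atleast_2d(np.asarray(metric_a, dtype=float))
    b = np.atleast_2d(np.asarray(metric_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.shape[1] < 5:
        raise ValueError("need at least 5 paired samples")
    two, one = [], []
    for ra, rb in zip(a, b):
        if np.allclose(ra, rb):  # identical models: no evidence either way
            two.append(1.0)
            one.append(0.5)
            continue
        two.append(sps.wilcoxon(ra, rb).pvalue)
        one.append(sps.wilcoxon(ra, rb, alternative="greater").pvalue)
    z, _ = stouffer_combine(np.clip(one, 1e-15, 1.0))
    p_two = float(2.0 * sps.norm.sf(abs(z)))
    return WilcoxonStoufferResult(
        wilcoxon_p=np.asarray(two) if len(two) > 1 else float(two[0]),
        stouffer_z=z,
        stouffer_p=min(p_two, 1.0),
        smd=smd(a.mean(axis=0), b.mean(axis=0)),
    )


def bonferroni(pvalues, n_family: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    k = p.size if n_family is None else n_family
    return np.minimum(p * k, 1.0)
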