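"""Within-sample (alpha) diversity at ASV level.

Observed richness, Shannon entropy (natural log by default), the Simpson
index as 1 - sum(p^2), and Fisher's alpha — the positive root of
S = alpha * ln(1 + N / alpha) for S observed taxa among N reads. Group
comparisons use the unpaired two-sided rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort_stats import mann_whitney
from .preprocess import DegenerateSampleError


class UndefinedEstimateError(ValueError):
    """Fisher's alpha is undefined (every read its own taxon)."""


def _row(counts_row) -> np.ndarray:
    r = np.asarray(counts_row, dtype=float)
    if (r < 0).any():
        raise ValueError("counts must be nonnegative")
    return r


def observed_richness(counts_row) -> int:
    """Number of taxa with count > 0."""
    return int((_row(counts_row) > 0).sum())


def shannon(counts_row, base: float | None = None) -> float:
    """Shannon entropy H = -sum p ln p (nats unless *base* given)."""
    r = _row(counts_row)
    total = r.sum()
    if total <= 0:
        raise DegenerateSampleError("zero-total sample")
    p = r[r > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def simpson(counts_row, variant: str = "one_minus") -> float:
    """Simpson diversity.

    ``one_minus`` (default): 1 - sum(p^2), the probability two random reads
    differ. ``dominance``: sum(p^2). ``inverse``: 1 / sum(p^2).
    """
    r = _row(counts_row)
    total = r.sum()
    if total <= 0:
        raise DegenerateSampleError("zero-total sample")
    d = float(((r / total) ** 2).sum())
    if variant == "one_minus":
        return 1.0 - d
    if variant == "dominance":
        return d
    if variant == "inverse":
        return 1.0 / d
    raise ValueError(f"unknown Simpson variant: {variant!r}")


def fisher_alpha(counts_row, tol: float = 1e-10) -> float:
    """Fisher's log-series alpha: the root of S = alpha ln(1 + N/alpha).

    Solved by bracketing + Brent to |S - alpha ln(1 + N/alpha)| < tol.
    Undefined when S == N (all singletons: the root diverges).
    """
    r = _row(counts_row)
    s = int((r > 0).sum())
    n = float(r.sum())
    if s == 0:
        raise DegenerateSampleError("no observed taxa")
    if s >= n:
        raise UndefinedEstimateError("S == N: Fisher's alpha diverges")

    def f(alpha: float) -> float:
        return alpha * np.log1p(n / alpha) - s

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for S < N
            raise UndefinedEstimateError("failed to bracket Fisher's alpha")
    return float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample table of all four metrics (fisher_alpha NaN where undefined)."""
    rows = {}
    for sample, row in counts.iterrows():
        r = row.to_numpy()
        try:
            fa = fisher_alpha(r)
        except (UndefinedEstimateError, DegenerateSampleError):
            fa = np.nan
        rows[sample] = {
            "observed_richness": observed_richness(r),
            "shannon": shannon(r),
            "simpson": simpson(r),
            "fisher_alpha": fa,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_alpha(values_a, values_b) -> tuple[float, float]:
    """Two-sided rank-sum comparison of a metric between two groups.

    The study names the Wilcoxon signed-rank test but compares independent
    groups of unequal size; the unpaired rank-sum (Mann-Whitney) test is the
    applicable variant and is what runs here.
    """
    return mann_whitney(values_a, values_b)
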