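"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — direct formula evaluation, exhaustive
enumeration, dense grid scans — and shares no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.abs(x - y).sum() / (x + y).sum())


def _branches(tree) -> list[tuple[frozenset, float]]:
    """Every branch as (set of descendant tip names, length)."""
    out = []
    for node in tree.postorder(include_self=False):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        out.append((tips, node.length or 0.0))
    return out


def unweighted_unifrac_pair(tree, taxa: list[str], x: np.ndarray,
                            y: np.ndarray) -> float:
    """Classify every branch shared/unique by walking its descendant tips."""
    present_x = {t for t, v in zip(taxa, x) if v > 0}
    present_y = {t for t, v in zip(taxa, y) if v > 0}
    unique = total = 0.0
    for tips, length in _branches(tree):
        in_x = bool(tips & present_x)
        in_y = bool(tips & present_y)
        if in_x or in_y:
            total += length
            if in_x != in_y:
                unique += length
    return unique / total if total else 0.0


def weighted_unifrac_pair(tree, taxa: list[str], x: np.ndarray, y: np.ndarray,
                          normalized: bool) -> float:
    px = dict(zip(taxa, x / x.sum()))
    py = dict(zip(taxa, y / y.sum()))
    raw = 0.0
    for tips, length in _branches(tree):
        mass_x = sum(px.get(t, 0.0) for t in tips)
        mass_y = sum(py.get(t, 0.0) for t in tips)
        raw += length * abs(mass_x - mass_y)
    if not normalized:
        return raw
    root = tree.root()
    denom = 0.0
    for tip in tree.tips():
        depth = tip.accumulate_to_ancestor(root)
        denom += depth * (px.get(tip.name, 0.0) + py.get(tip.name, 0.0))
    return raw / denom if denom else 0.0


def permanova_stats(d: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """(pseudo_F, R2) straight from the definitional sums of squares."""
    n = d.shape[0]
    groups = np.unique(codes)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(codes == g)
        ss_within += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_among = ss_total - ss_within
    df_a, df_w = len(groups) - 1, n - len(groups)
    return (ss_among / df_a) / (ss_within / df_w), ss_among / ss_total


def permanova_exact_p(d: np.ndarray, codes: np.ndarray) -> float:
    """Exact permutation p over every label assignment (small n only)."""
    f_obs, _ = permanova_stats(d, codes)
    n = len(codes)
    hits = total = 0
    for perm in set(itertools.permutations(codes)):
        f, _ = permanova_stats(d, np.array(perm))
        total += 1
        if f >= f_obs - 1e-12:
            hits += 1
    return hits / total


def mannwhitney_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating every split of the pooled sample."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * len(y) / 2
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        u = ranks[list(combo)].sum() - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def envfit_r2(axes: np.ndarray, v: np.ndarray) -> float:
    """Squared multiple correlation via the normal equations."""
    a = np.column_stack([np.ones(len(v)), axes])
    beta = np.linalg.solve(a.T @ a, a.T @ v)
    fitted = a @ beta
    ssr = ((fitted - v.mean()) ** 2).sum()
    sst = ((v - v.mean()) ** 2).sum()
    return float(ssr / sst)


def soft_threshold(z: float, t: float) -> float:
    return float(np.sign(z) * max(abs(z) - t, 0.0))


def auc_pairs(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by direct enumeration of positive/negative pairs."""
    pos = scores[labels == labels.max()]
    neg = scores[labels != labels.max()]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def fisher_alpha_grid(s: int, n: float, lo: float = 1e-6, hi: float = 1e6,
                      points: int = 2_000_001) -> float:
    """Dense log-grid scan for the root of S = a ln(1 + N/a)."""
    grid = np.logspace(np.log10(lo), np.log10(hi), points)
    vals = grid * np.log1p(n / grid) - s
    i = int(np.argmin(np.abs(vals)))
    return float(grid[i])
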