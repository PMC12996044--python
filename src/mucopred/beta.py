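"""Between-sample dissimilarity, ordination and related inference.

Bray-Curtis and (un)weighted UniFrac distance matrices, classical principal
coordinate analysis (Gower double-centering + eigendecomposition), PERMANOVA
with seeded label permutations, envfit-style projection of external
variables onto the first two ordination axes, and Euclidean distances
between group centroids.

Distances are delegated to scikit-bio; PCoA / PERMANOVA / envfit are
implemented here because the conventions this package pins down (positive-
eigenvalue proportions, the (1+r)/(1+n) permutation p, vector fitting of
0/1 covariates) need to hold exactly.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .preprocess import DegenerateSampleError


class MissingLeafError(KeyError):
    """A counted ASV is absent from the phylogeny."""


@dataclasses.dataclass
class OrdinationResult:
    eigenvalues: np.ndarray          # all eigenvalues, descending (may be < 0)
    coordinates: pd.DataFrame        # samples x axes, positive-eigenvalue axes only
    proportion_explained: np.ndarray  # relative to the sum of positive eigenvalues


@dataclasses.dataclass
class PermanovaResult:
    ss_among: float
    ss_within: float
    ss_total: float
    df_among: int
    df_within: int
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int
    seed: int | None


@dataclasses.dataclass
class EnvfitResult:
    """Per-variable fitted vectors on PCoA axes 1-2."""

    arrows: pd.DataFrame   # variables x (axis1, axis2); length = sqrt(R2)
    r2: pd.Series
    p: pd.Series
    n_permutations: int
    seed: int | None


def _as_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    m = np.asarray(table, dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (m.sum(axis=1) <= 0).any():
        bad = table.index[m.sum(axis=1) <= 0]
        raise DegenerateSampleError(f"zero-total sample(s): {list(bad[:5])}")
    return m, list(map(str, table.index))


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y)."""
    m, ids = _as_matrix(table)
    return beta_diversity("braycurtis", m, ids=ids, validate=False)


def _check_leaves(table: pd.DataFrame, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    counted = set(table.columns[(np.asarray(table) > 0).any(axis=0)])
    missing = sorted(counted - tips)
    if missing:
        raise MissingLeafError(f"ASVs not in tree: {missing[:5]}")


def unweighted_unifrac(table: pd.DataFrame, tree: TreeNode) -> DistanceMatrix:
    """Presence/absence UniFrac: unique branch length / total branch length."""
    m, ids = _as_matrix(table)
    _check_leaves(table, tree)
    return beta_diversity("unweighted_unifrac", (m > 0).astype(int), ids=ids,
                          taxa=list(table.columns), tree=tree, validate=False)


def weighted_unifrac(table: pd.DataFrame, tree: TreeNode,
                     normalized: bool = True) -> DistanceMatrix:
    """Abundance-weighted UniFrac on row proportions.

    Raw form: sum over branches of length x |P_x - P_y| where P_s is the
    fraction of sample s's reads descending from the branch. The normalized
    form (default) divides by the pair's maximum attainable value — branch
    lengths weighted by tip-to-root distances times (P_x + P_y), scikit-bio's
    convention — making values comparable across pairs.
    """
    m, ids = _as_matrix(table)
    _check_leaves(table, tree)
    props = m / m.sum(axis=1, keepdims=True)
    col = {name: j for j, name in enumerate(table.columns)}
    n = len(ids)
    raw = np.zeros((n, n))
    node_mass: dict[int, np.ndarray] = {}
    depths: dict[str, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            j = col.get(node.name)
            mass = props[:, j].copy() if j is not None else np.zeros(n)
        else:
            mass = np.zeros(n)
            for child in node.children:
                mass += node_mass.pop(id(child))
        node_mass[id(node)] = mass
        if node.parent is not None and node.length:
            raw += node.length * np.abs(mass[:, None] - mass[None, :])
    if not normalized:
        return DistanceMatrix(raw, ids=ids)
    for tip in tree.tips():
        if tip.name in col:
            depths[tip.name] = tip.accumulate_to_ancestor(tree.root())
    d = np.zeros(n)
    for name, j in col.items():
        if name in depths:
            d += depths[name] * props[:, j]
    denom = d[:, None] + d[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, raw / denom, 0.0)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(out, ids=ids)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Gower-centers -d^2/2, eigendecomposes, and keeps up to *n_axes* axes with
    positive eigenvalues; coordinates are eigenvectors scaled by sqrt of the
    eigenvalue (negative eigenvalues are reported but receive no axis and no
    share of proportion_explained; no Cailliez/Lingoes correction). Axis
    signs are fixed so each column's largest-magnitude entry is positive.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    a = -0.5 * dm ** 2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigvals, eigvecs = np.linalg.eigh(centered)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(f"requested {n_axes} axes but only {n_pos} positive "
                      "eigenvalues; truncating", stacklevel=2)
    k = min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for j in range(k):  # deterministic sign convention
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigvals[:n_pos].sum()
    proportion = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    frame = pd.DataFrame(coords, index=list(d.ids),
                         columns=[f"PCo{j + 1}" for j in range(k)])
    return OrdinationResult(eigenvalues=eigvals, coordinates=frame,
                            proportion_explained=proportion)


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss


def permanova(d: DistanceMatrix, labels, n_permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA (adonis-style) with seeded permutations.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous per-group
    terms; pseudo-F = (SS_among/df_among) / (SS_within/df_within); the p-value
    uses the (1 + #{F_perm >= F_obs}) / (1 + n_permutations) convention.
    """
    labels = pd.Series(list(labels))
    codes, uniques = pd.factorize(labels)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if (np.bincount(codes) < 1).any():  # pragma: no cover - factorize guards
        raise ValueError("every group needs at least one sample")
    d2 = np.asarray(d.data, dtype=float) ** 2
    n = d2.shape[0]
    if len(labels) != n:
        raise ValueError("labels must align with the distance matrix")
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = _ss_within(d2, codes, n_groups)
    ss_among = ss_total - ss_within
    df_among, df_within = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore"):  # ss_within = 0 gives F = inf
        f_obs = (ss_among / df_among) / (ss_within / df_within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        ss_w = _ss_within(d2, perm, n_groups)
        ss_a = ss_total - ss_w
        with np.errstate(divide="ignore"):
            f_perm = (ss_a / df_among) / (ss_w / df_within)
        if f_perm >= f_obs:
            hits += 1
    return PermanovaResult(
        ss_among=float(ss_among), ss_within=float(ss_within),
        ss_total=float(ss_total), df_among=df_among, df_within=df_within,
        pseudo_f=float(f_obs), r2=float(ss_among / ss_total),
        p=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations, seed=seed)


def _fit_one(axes: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit of one centered variable on two centered axes."""
    coef, *_ = np.linalg.lstsq(axes, v, rcond=None)
    fitted = axes @ coef
    sst = float((v ** 2).sum())
    r2 = float((fitted ** 2).sum() / sst) if sst > 0 else 0.0
    return coef, r2


def envfit_vectors(ordination: OrdinationResult, variables: pd.DataFrame,
                   n_permutations: int = 999,
                   seed: int | None = None) -> EnvfitResult:
    """Project per-sample variables onto PCoA axes 1-2 as fitted vectors.

    Each variable (numeric; 0/1 for binary exposure flags) is regressed on
    the first two axes; the arrow is the coefficient direction scaled to
    length sqrt(R2); p comes from permuting the variable's values:
    (1 + #{R2_perm >= R2}) / (1 + n_permutations).
    """
    if ordination.coordinates.shape[1] < 2:
        raise ValueError("ordination must carry at least 2 axes")
    variables = variables.loc[ordination.coordinates.index]
    axes = ordination.coordinates.iloc[:, :2].to_numpy()
    axes = axes - axes.mean(axis=0)
    rng = np.random.default_rng(seed)
    arrows, r2s, ps = {}, {}, {}
    for name in variables.columns:
        v = variables[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"constant variable {name!r}: fit undefined")
        v = v - v.mean()
        coef, r2 = _fit_one(axes, v)
        norm = np.linalg.norm(coef)
        arrows[name] = (coef / norm) * np.sqrt(r2) if norm > 0 else coef * 0.0
        hits = 0
        for _ in range(n_permutations):
            _, r2p = _fit_one(axes, rng.permutation(v))
            if r2p >= r2:
                hits += 1
        r2s[name] = r2
        ps[name] = (1 + hits) / (1 + n_permutations)
    arrow_frame = pd.DataFrame(arrows, index=["axis1", "axis2"]).T
    return EnvfitResult(arrows=arrow_frame, r2=pd.Series(r2s), p=pd.Series(ps),
                        n_permutations=n_permutations, seed=seed)


def centroid_distances(ordination: OrdinationResult, groups) -> pd.DataFrame:
    """Euclidean distances between group centroids on the first two axes."""
    groups = pd.Series(list(groups), index=ordination.coordinates.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group")
    coords = ordination.coordinates.iloc[:, :2]
    centroids = coords.groupby(groups).mean()
    if (coords.groupby(groups).size() < 1).any():  # pragma: no cover
        raise ValueError("empty group")
    names = list(centroids.index)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            dist = float(np.linalg.norm(centroids.loc[a] - centroids.loc[b]))
            out.loc[a, b] = out.loc[b, a] = dist
    return out
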