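"""Seeded synthetic cohorts of mucosa-adherent 16S ASV profiles.

Generates everything the downstream stages consume — an ASV count table, a
rank-labelled taxonomy, a rooted phylogeny, per-sample clinical metadata with
responder / non-responder labels — plus the ground truth of which ASVs carry
planted signal and in which direction.

The generative model: a shared log-normal baseline composition (steep
abundance rank curve, so a top-N abundance filter is meaningfully selective);
group-specific expected compositions obtained by multiplying the expected
relative abundance of each planted signal ASV by ``effect_fold_change`` in
its enriched group and renormalising; counts drawn Dirichlet-multinomial with
concentration ``overdispersion`` x composition; a designated block of
non-bacterial (Eukaryota / unassigned) contaminant ASVs holding an expected
``contaminant_fraction`` of every sample's reads; sequencing depth uniform
over ``depth_range``.

One master seed deterministically spawns independent sub-streams per
generator, so whole-cohort generation is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

TAXONOMY_RANKS = ["Domain", "Phylum", "Class", "Order", "Family", "Genus", "Species"]

# Genus pool for bacterial taxonomy labels; the first two genera are reserved
# for the planted signal ASVs (non-response-like and response-like).
_SIGNAL_GENUS_NONRESPONSE = ("Mediterraneibacter", "gnavus")
_SIGNAL_GENUS_RESPONSE = ("Blautia", "")
_BACKGROUND_GENERA = [
    "Bacteroides", "Faecalibacterium", "Agathobacter", "Subdoligranulum",
    "Anaerostipes", "Roseburia", "Lachnoclostridium", "Escherichia",
    "Prevotella", "Alistipes", "Ruminococcus", "Dorea", "Coprococcus",
    "Akkermansia", "Parabacteroides", "Clostridium",
]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-group cohort.

    ``effect_fold_change`` multiplies the expected relative abundance of each
    non-response signal ASV in non-responders (and of each response signal ASV
    in responders); 1.0 means no planted signal. ``overdispersion`` is the
    Dirichlet concentration scale: smaller values give noisier compositions.
    """

    n_responders: int = 22
    n_nonresponders: int = 16
    n_asvs: int = 300
    n_signal_asvs_nonresponse: int = 4
    n_signal_asvs_response: int = 4
    effect_fold_change: float = 4.0
    contaminant_fraction: float = 0.093
    n_contaminant_asvs: int | None = None  # default: 5.6% of n_asvs
    depth_range: tuple[int, int] = (20_000, 60_000)
    overdispersion: float = 200.0
    baseline_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("both groups need at least one sample")
        if self.n_asvs < 2:
            raise ValueError("n_asvs must be >= 2")
        n_cont = self.resolved_n_contaminants()
        n_signal = self.n_signal_asvs_nonresponse + self.n_signal_asvs_response
        if n_signal + n_cont > self.n_asvs:
            raise ValueError("signal + contaminant ASVs exceed n_asvs")
        if self.effect_fold_change < 1:
            raise ValueError("effect_fold_change must be >= 1")
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant_fraction must lie in [0, 1]")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range must satisfy 1 <= min <= max")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")

    def resolved_n_contaminants(self) -> int:
        if self.n_contaminant_asvs is not None:
            return self.n_contaminant_asvs
        if self.contaminant_fraction == 0:
            return 0
        return max(1, round(0.056 * self.n_asvs))


@dataclasses.dataclass
class CohortDataset:
    """One fully generated cohort: counts + taxonomy + tree + metadata + truth."""

    counts: pd.DataFrame          # samples x ASVs, integer
    taxonomy: pd.DataFrame        # ASV id -> Domain..Species
    tree: TreeNode
    metadata: pd.DataFrame        # sample id -> clinical covariates + response
    truth: pd.DataFrame           # planted signal ASVs with direction

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "tree": outdir / "tree.nwk",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.counts.to_csv(paths["counts"], sep="\t", index_label="sample_id")
        self.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="asv_id")
        self.tree.write(str(paths["tree"]))
        self.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _subseeds(seed: int, n: int) -> list[int]:
    """Deterministic per-generator sub-seeds (< 2**31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def generate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Random rooted binary tree with leaves ASV_1..ASV_n.

    Built by random agglomeration: repeatedly join two uniformly chosen
    subtrees under a fresh parent, with exponential branch lengths. All branch
    lengths are strictly positive and the result is reproducible from *seed*.
    """
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    # work on newick fragments; branch lengths drawn at leaf/join creation
    frags = [f"ASV_{i + 1}:{rng.exponential(0.1) + 1e-3:.6f}" for i in range(n_taxa)]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        right = frags.pop(j)
        left = frags.pop(i)
        if len(frags) == 0:  # final join is the root (no branch above it)
            frags.append(f"({left},{right});")
        else:
            bl = rng.exponential(0.1) + 1e-3
            frags.append(f"({left},{right}):{bl:.6f}")
    return TreeNode.read(io.StringIO(frags[0]), convert_underscores=False)


def _baseline_composition(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal relative-abundance profile, sorted steepest-first."""
    x = np.sort(rng.lognormal(mean=0.0, sigma=sigma, size=n))[::-1]
    return x / x.sum()


def _signal_indices(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic mid-abundance ranks for the planted signal ASVs.

    Placed around rank n/4 of the bacterial block: abundant enough to survive
    a top-250 filter on a few-hundred-ASV table, but not dominating it.
    """
    n_bact = config.n_asvs - config.resolved_n_contaminants()
    k = config.n_signal_asvs_nonresponse + config.n_signal_asvs_response
    start = max(0, min(n_bact - k, n_bact // 4))
    idx = np.arange(start, start + k)
    return (idx[: config.n_signal_asvs_nonresponse],
            idx[config.n_signal_asvs_nonresponse:])


def generate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial counts with planted group signal.

    Returns ``(counts, truth)``: counts is samples x ASVs (responders first,
    ``S1..``), truth lists each planted signal ASV with its direction
    (``non_response`` = enriched in non-responders, ``response`` = enriched
    in responders).
    """
    rng = np.random.default_rng(_subseeds(config.seed, 4)[1])
    n_cont = config.resolved_n_contaminants()
    n_bact = config.n_asvs - n_cont

    bact = _baseline_composition(n_bact, config.baseline_sigma, rng)
    bact *= 1.0 - config.contaminant_fraction
    if n_cont:
        cont = _baseline_composition(n_cont, config.baseline_sigma, rng)
        cont *= config.contaminant_fraction
        base = np.concatenate([bact, cont])
    else:
        base = bact
    if config.contaminant_fraction < 1:
        base = base / base.sum()

    nr_idx, r_idx = _signal_indices(config)
    comp_resp = base.copy()
    comp_resp[r_idx] *= config.effect_fold_change
    comp_resp /= comp_resp.sum()
    comp_nonresp = base.copy()
    comp_nonresp[nr_idx] *= config.effect_fold_change
    comp_nonresp /= comp_nonresp.sum()

    n_total = config.n_responders + config.n_nonresponders
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1,
                          size=n_total)
    rows = np.empty((n_total, config.n_asvs), dtype=np.int64)
    for s in range(n_total):
        comp = comp_resp if s < config.n_responders else comp_nonresp
        p = rng.dirichlet(config.overdispersion * comp)
        rows[s] = rng.multinomial(depths[s], p)

    asv_ids = [f"ASV_{i + 1}" for i in range(config.n_asvs)]
    sample_ids = [f"S{i + 1}" for i in range(n_total)]
    counts = pd.DataFrame(rows, index=sample_ids, columns=asv_ids)
    truth = pd.DataFrame({
        "asv_id": [asv_ids[i] for i in nr_idx] + [asv_ids[i] for i in r_idx],
        "direction": (["non_response"] * len(nr_idx) + ["response"] * len(r_idx)),
    })
    return counts, truth


def generate_taxonomy(config: SimulationConfig) -> pd.DataFrame:
    """Rank table (Domain..Species) for every ASV.

    Bacterial ASVs get Domain=Bacteria with genera from a fixed pool; the
    planted signal ASVs are labelled Mediterraneibacter gnavus-like
    (non-response) and Blautia-like (response). The trailing contaminant block
    gets Domain=Eukaryota or an unassigned Domain so the exclusion step has
    something to remove.
    """
    rng = np.random.default_rng(_subseeds(config.seed, 4)[2])
    n_cont = config.resolved_n_contaminants()
    n_bact = config.n_asvs - n_cont
    nr_idx, r_idx = _signal_indices(config)

    rows = []
    for i in range(config.n_asvs):
        asv = f"ASV_{i + 1}"
        if i >= n_bact:  # contaminant block
            if rng.random() < 0.5:
                rows.append([asv, "Eukaryota", "Chordata", "Mammalia",
                             "Primates", "Hominidae", "Homo", "sapiens"])
            else:
                rows.append([asv, "", "", "", "", "", "", ""])
        elif i in nr_idx:
            g, s = _SIGNAL_GENUS_NONRESPONSE
            rows.append([asv, "Bacteria", "Firmicutes", "Clostridia",
                         "Lachnospirales", "Lachnospiraceae", g, s])
        elif i in r_idx:
            g, s = _SIGNAL_GENUS_RESPONSE
            rows.append([asv, "Bacteria", "Firmicutes", "Clostridia",
                         "Lachnospirales", "Lachnospiraceae", g, s])
        else:
            g = _BACKGROUND_GENERA[int(rng.integers(len(_BACKGROUND_GENERA)))]
            species = "" if rng.random() < 0.4 else f"sp{int(rng.integers(1, 40))}"
            rows.append([asv, "Bacteria", "Firmicutes", "Clostridia",
                         "Oscillospirales", "Ruminococcaceae", g, species])
    df = pd.DataFrame(rows, columns=["asv_id"] + TAXONOMY_RANKS)
    return df.set_index("asv_id")


# Clinical covariate distributions loosely matching a baseline CD biologics
# cohort: categorical probabilities and log-normal medians/spreads.
CATEGORICAL_COVARIATES: dict[str, float] = {
    "sex_female": 0.60,
    "agent_infliximab": 0.40,
    "smoking_active": 0.20,
    "immunomodulators": 0.47,
    "prior_anti_tnfa": 0.50,
    "prior_vdz": 0.14,
    "prior_uste": 0.09,
    "family_history_ibd": 0.08,
}
CONTINUOUS_COVARIATES: dict[str, tuple[float, float]] = {
    # name -> (median, sigma of log)
    "age_years": (30.0, 0.35),
    "crp_mg_l": (5.0, 1.2),
    "fcal_ug_g": (600.0, 1.3),
    "hbi": (5.0, 0.55),
    "ses_cd": (8.0, 0.55),
}


def generate_clinical(n_samples: int, seed: int) -> pd.DataFrame:
    """Per-sample clinical covariates from documented distributions.

    Categoricals are Bernoulli with the probabilities in
    ``CATEGORICAL_COVARIATES``; continuous covariates are log-normal with the
    (median, log-sigma) pairs in ``CONTINUOUS_COVARIATES``, with HBI and
    SES-CD rounded to integer scores.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for name, p in CATEGORICAL_COVARIATES.items():
        data[name] = (rng.random(n_samples) < p).astype(int)
    for name, (median, sigma) in CONTINUOUS_COVARIATES.items():
        vals = rng.lognormal(mean=np.log(median), sigma=sigma, size=n_samples)
        if name in ("hbi", "ses_cd"):
            vals = np.round(vals)
        else:
            vals = np.round(vals, 1)
        data[name] = vals
    idx = [f"S{i + 1}" for i in range(n_samples)]
    return pd.DataFrame(data, index=idx)


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Full cohort: counts, taxonomy, tree, metadata (with labels), truth."""
    seeds = _subseeds(config.seed, 4)
    counts, truth = generate_counts(config)
    taxonomy = generate_taxonomy(config)
    tree = generate_tree(config.n_asvs, seeds[0])
    n_total = config.n_responders + config.n_nonresponders
    metadata = generate_clinical(n_total, seeds[3])
    metadata["response"] = (["responder"] * config.n_responders
                            + ["non_responder"] * config.n_nonresponders)
    metadata["location"] = "colon"
    return CohortDataset(counts=counts, taxonomy=taxonomy, tree=tree,
                         metadata=metadata, truth=truth)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int64)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
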