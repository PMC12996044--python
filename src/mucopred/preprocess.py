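"""Filtering and normalisation of ASV count tables.

Raw counts (samples x ASVs) are reduced to the relative-abundance matrices
the diversity, ordination and modelling stages consume: a minimum-read
presence filter, exclusion of non-bacterial (Eukaryota / Domain-unassigned)
ASVs with an accounting report, total-sum scaling to relative abundance, and
a deterministic top-N-by-mean-abundance feature filter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd


class MissingAnnotationError(KeyError):
    """An ASV in the count table has no taxonomy row."""


class DegenerateSampleError(ValueError):
    """A sample has zero total reads where a positive total is required."""


@dataclasses.dataclass
class FilterReport:
    """Accounting of the non-bacterial exclusion step."""

    n_asvs_before: int
    n_asvs_removed_minreads: int
    n_asvs_removed_taxonomy: int
    per_sample_excluded_fraction: pd.Series
    mean_excluded_fraction: float
    sd_excluded_fraction: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_asvs_before": self.n_asvs_before,
            "n_asvs_removed_minreads": self.n_asvs_removed_minreads,
            "n_asvs_removed_taxonomy": self.n_asvs_removed_taxonomy,
            "per_sample_excluded_fraction":
                self.per_sample_excluded_fraction.round(6).to_dict(),
            "mean_excluded_fraction": round(self.mean_excluded_fraction, 6),
            "sd_excluded_fraction": round(self.sd_excluded_fraction, 6),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _check_table(table: pd.DataFrame) -> None:
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("count table is empty")
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValueError("duplicate sample or ASV identifiers")


def filter_min_reads(table: pd.DataFrame, min_reads: int = 4,
                     per_sample: bool = False) -> pd.DataFrame:
    """Drop ASVs that never reach *min_reads* in any sample.

    The default mode is a per-ASV presence threshold: an ASV is retained iff
    its count is >= min_reads in at least one sample; retained counts are
    untouched. With ``per_sample=True`` the alternative reading is applied
    instead: cells below the threshold are zeroed sample-wise, then ASVs with
    no remaining reads are dropped.
    """
    _check_table(table)
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if per_sample:
        zeroed = table.where(table >= min_reads, 0)
        return zeroed.loc[:, zeroed.sum(axis=0) > 0]
    keep = (table >= min_reads).any(axis=0)
    return table.loc[:, keep]


def exclude_nonbacterial(table: pd.DataFrame,
                         taxonomy: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Remove ASVs whose Domain is not Bacteria; report the read share lost.

    Eukaryota and Domain-unassigned (empty-string) ASVs are excluded together.
    The report records, per sample, the fraction of total reads the excluded
    ASVs carried, plus the mean and sd across samples.
    """
    _check_table(table)
    missing = table.columns.difference(taxonomy.index)
    if len(missing):
        raise MissingAnnotationError(
            f"ASVs missing from taxonomy: {', '.join(map(str, missing[:5]))}")
    domain = taxonomy.loc[table.columns, "Domain"].fillna("").astype(str)
    bacterial = domain == "Bacteria"
    removed = table.loc[:, ~bacterial.values]
    totals = table.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = (removed.sum(axis=1) / totals).fillna(0.0)
    report = FilterReport(
        n_asvs_before=table.shape[1],
        n_asvs_removed_minreads=0,
        n_asvs_removed_taxonomy=int((~bacterial).sum()),
        per_sample_excluded_fraction=frac,
        mean_excluded_fraction=float(frac.mean()),
        sd_excluded_fraction=float(frac.std(ddof=1)) if len(frac) > 1 else 0.0,
    )
    return table.loc[:, bacterial.values], report


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scaling: each row divided by its total."""
    _check_table(table)
    totals = table.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateSampleError(
            f"zero-total sample(s): {', '.join(map(str, zero.index[:5]))}")
    return table.div(totals, axis=0)


def top_n_by_mean_abundance(table: pd.DataFrame, n: int = 250) -> pd.DataFrame:
    """Keep the n ASVs with highest mean relative abundance.

    Ties broken by ascending ASV id; output columns ordered by descending
    mean abundance (then ascending id), so downstream feature indices are
    stable. If fewer than n ASVs exist, all are kept (reordered).
    """
    _check_table(table)
    if n < 1:
        raise ValueError("n must be >= 1")
    means = table.mean(axis=0)
    order = sorted(table.columns, key=lambda a: (-means[a], a))
    return table.loc[:, order[:n]]
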