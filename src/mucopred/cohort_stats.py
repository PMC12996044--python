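"""Clinical-covariate statistics and the composite therapy-response rule.

Responders and non-responders are compared with the uncorrected Pearson
chi-square test for categorical covariates and the two-sided Mann-Whitney
U-test for continuous ones, and summarised as a baseline-characteristics
table (n (%) or median (IQR), missing counts bracketed). The response label
itself combines an endoscopic gate (>=50% SES-CD reduction) with either a
corticosteroid-free clinical response or a biochemical response.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass(frozen=True)
class ResponseInputs:
    """Baseline and follow-up disease-activity measurements for one patient.

    SES-CD: simple endoscopic score for Crohn's disease. HBI: Harvey-Bradshaw
    index. CRP in mg/L, faecal calprotectin in ug/g.
    """

    ses_cd_baseline: float
    ses_cd_followup: float
    hbi_baseline: float
    hbi_followup: float
    on_systemic_steroids: bool
    crp_baseline: float
    crp_followup: float
    fcal_baseline: float
    fcal_followup: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name != "on_systemic_steroids" and v < 0:
                raise ValueError(f"{f.name} must be nonnegative")


def chisq_test(observed) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square test of independence.

    Returns (statistic, degrees of freedom, upper-tail p). No Yates
    continuity correction — on 2x2 tables this matches the score z-test for
    two proportions. Raises on degenerate margins (an all-zero row/column).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any() or obs.sum() <= 0:
        raise ValueError("cells must be nonnegative with positive total")
    expected = stats.contingency.expected_freq(obs)
    if (expected == 0).any():
        raise ValueError("degenerate margin: an expected cell is zero")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test; returns (U of x, p).

    Exact null distribution when both samples have n <= 8 and the pooled data
    are tie-free; otherwise the normal approximation with tie-corrected
    variance (no continuity correction, so identical samples give p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if np.ptp(pooled) == 0:  # all observations identical: no evidence either way
        return x.size * y.size / 2.0, 1.0
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def classify_response(r: ResponseInputs) -> bool:
    """Composite responder rule at 26-52 week follow-up.

    responder iff [SES-CD reduction >= 50%] AND (
        [clinical: (HBI drop >= 3 or follow-up HBI <= 4) and not on steroids]
        OR
        [biochemical: (CRP drop >= 50% or follow-up CRP <= 5 mg/L)
                      and (fcal drop >= 50% or follow-up fcal <= 250 ug/g)] )
    Reductions from a zero baseline count as achieved only via the absolute
    thresholds (a 0 -> 0 course has a 100% reduction by convention here).
    """
    def reduced_half(baseline: float, followup: float) -> bool:
        if baseline == 0:
            return followup == 0
        return (baseline - followup) / baseline >= 0.5

    endoscopic = reduced_half(r.ses_cd_baseline, r.ses_cd_followup)
    clinical = ((r.hbi_baseline - r.hbi_followup >= 3 or r.hbi_followup <= 4)
                and not r.on_systemic_steroids)
    biochemical = ((reduced_half(r.crp_baseline, r.crp_followup)
                    or r.crp_followup <= 5.0)
                   and (reduced_half(r.fcal_baseline, r.fcal_followup)
                        or r.fcal_followup <= 250.0))
    return endoscopic and (clinical or biochemical)


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation between order statistics."""
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def summarize_cohort(metadata: pd.DataFrame, group_col: str = "response",
                     categorical: list[str] | None = None,
                     continuous: list[str] | None = None) -> pd.DataFrame:
    """Baseline-characteristics table comparing the two label groups.

    Categoricals (0/1 or two-level) are shown as "n (%)" per group with the
    uncorrected chi-square p; continuous covariates as "median (q1-q3)" with
    the Mann-Whitney p. Missing values are dropped per covariate and shown in
    square brackets. Covariates whose test cannot be computed (all missing,
    degenerate margins) are reported with p = NaN rather than raising.
    """
    groups = metadata[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError("group label must be binary")
    g1, g2 = sorted(map(str, groups))
    sub1 = metadata[metadata[group_col].astype(str) == g1]
    sub2 = metadata[metadata[group_col].astype(str) == g2]

    if categorical is None or continuous is None:
        categorical, continuous = [], []
        for col in metadata.columns:
            if col == group_col:
                continue
            vals = metadata[col].dropna()
            if vals.nunique() <= 2 or not pd.api.types.is_numeric_dtype(vals):
                categorical.append(col)
            else:
                continuous.append(col)

    def fmt_missing(col: str, sub: pd.DataFrame) -> str:
        n_miss = int(sub[col].isna().sum())
        return f" [{n_miss}]" if n_miss else ""

    rows = []
    for col in categorical:
        a, b = sub1[col].dropna(), sub2[col].dropna()
        if len(a) == 0 and len(b) == 0:
            rows.append([col, "categorical", "NA", "NA", np.nan])
            continue
        level = sorted(pd.concat([a, b]).unique())[-1]  # report the "positive" level
        ka, kb = int((a == level).sum()), int((b == level).sum())
        try:
            table = np.array([[ka, len(a) - ka], [kb, len(b) - kb]])
            _, _, p = chisq_test(table)
        except ValueError:
            p = np.nan
        cell1 = f"{ka} ({100 * ka / len(a):.1f})" + fmt_missing(col, sub1) if len(a) else "NA"
        cell2 = f"{kb} ({100 * kb / len(b):.1f})" + fmt_missing(col, sub2) if len(b) else "NA"
        rows.append([col, "categorical", cell1, cell2, p])
    for col in continuous:
        a, b = sub1[col].dropna().to_numpy(), sub2[col].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            rows.append([col, "continuous", "NA", "NA", np.nan])
            continue
        m1, q11, q31 = _median_iqr(a)
        m2, q12, q32 = _median_iqr(b)
        try:
            _, p = mann_whitney(a, b)
        except ValueError:
            p = np.nan
        cell1 = f"{m1:g} ({q11:g}-{q31:g})" + fmt_missing(col, sub1)
        cell2 = f"{m2:g} ({q12:g}-{q32:g})" + fmt_missing(col, sub2)
        rows.append([col, "continuous", cell1, cell2, p])

    return pd.DataFrame(rows, columns=["covariate", "kind", g1, g2, "p"])
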