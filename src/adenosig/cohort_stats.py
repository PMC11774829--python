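"""Group summaries and pairwise comparisons over per-sample features.

The comparison report mirrors the structure of clinical WES feature
tables: for each genomic feature (SBS18+SBS36 proportion, SBS30
proportion, TMB, indel count, SNV count) and each configured pair of
groups it gives group summaries (mean, sample SD, range), a two-sided
Welch t-test with Satterthwaite degrees of freedom, a Bonferroni-adjusted
p-value (default m = 35 hypotheses), and a pooled-SD Cohen's d.

Welch's unequal-variance t is the default flavour because p-values
recomputed from the published summary statistics match the published
magnitudes only under Welch; a pooled-variance Student's t is available
via ``equal_var=True``. Summary-based and raw-value-based calls share the
same formulas, so they coincide exactly when the summaries are computed
from the same values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

DEFAULT_FEATURES: tuple[str, ...] = ("sbs18_36", "sbs30", "tmb", "indel_count", "snv_count")

#: Number of hypotheses for the default Bonferroni correction.
DEFAULT_M = 35


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD (n-1 denominator) and range of one group's feature."""

    label: str
    n: int
    mean: float
    sd: float | None  # None when n < 2
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.minimum <= self.mean <= self.maximum:
            raise ValueError("min <= mean <= max violated")


@dataclass(frozen=True)
class ComparisonResult:
    """One feature, one pair of groups: t / df / p / adjusted p / Cohen's d."""

    feature: str
    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    p_adjusted: float
    cohens_d: float | None
    summary_a: GroupSummary | None = None
    summary_b: GroupSummary | None = None


def summarize(values: Sequence[float], label: str) -> GroupSummary:
    """Summarise one group's values; SD is undefined (None) for n = 1."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty group")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return GroupSummary(
        label=label,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )


def _as_stats(x) -> tuple[float, float, int]:
    """Coerce a GroupSummary or raw values to (mean, sd, n)."""
    if isinstance(x, GroupSummary):
        if x.sd is None:
            raise ValueError(f"group {x.label!r} has undefined SD (n < 2)")
        return x.mean, x.sd, x.n
    arr = np.asarray(list(x), dtype=float)
    if arr.size < 2:
        raise ValueError("need n >= 2 in each group")
    return float(arr.mean()), float(np.std(arr, ddof=1)), int(arr.size)


def welch_from_stats(m1, s1, n1, m2, s2, n2):
    """Welch t, Satterthwaite df and two-sided p from summary statistics.

    Accepts scalars or numpy arrays (broadcast elementwise).
    """
    m1, s1, m2, s2 = (np.asarray(v, dtype=float) for v in (m1, s1, m2, s2))
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    v1 = s1**2 / n1
    v2 = s2**2 / n2
    se2 = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        # zero variance in both groups: t is 0 (equal means) or +/- inf
        t = np.where(se2 == 0, np.where(m1 == m2, 0.0, np.inf * np.sign(m1 - m2)), t)
        df = np.where(se2 == 0, n1 + n2 - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if np.ndim(t) == 0:
        return float(t), float(df), float(p)
    return t, df, p


def welch_t_test(a, b, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided t-test from raw values or (mean, sd, n) summaries.

    Default is Welch (unequal variances, Satterthwaite df); set
    ``equal_var=True`` for the pooled-variance Student's variant.
    """
    m1, s1, n1 = _as_stats(a)
    m2, s2, n2 = _as_stats(b)
    if equal_var:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        if se == 0:
            t = 0.0 if m1 == m2 else math.inf * math.copysign(1, m1 - m2)
        else:
            t = (m1 - m2) / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
        return t, float(df), p
    return welch_from_stats(m1, s1, n1, m2, s2, n2)


def cohens_d_pooled(a, b) -> float | None:
    """Cohen's d with the pooled-SD denominator; first minus second mean.

    Returns None (undefined) when the pooled SD is zero.
    """
    m1, s1, n1 = _as_stats(a)
    m2, s2, n2 = _as_stats(b)
    if n1 + n2 < 3:
        raise ValueError("need n_a + n_b >= 3")
    sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if sp == 0:
        return None
    return (m1 - m2) / sp


def bonferroni_adjust(p: float, m: int = DEFAULT_M) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p outside [0, 1]: {p}")
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    return min(1.0, m * p)


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F with (k-1, N-k) df and its p-value.

    Degenerate inputs: when both between- and within-group variance are
    zero, F = 0 and p = 1; zero within-variance with real separation gives
    F = inf, p = 0.
    """
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
    df_b = len(arrs) - 1
    df_w = all_vals.size - len(arrs)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def comparison_table(
    features: pd.DataFrame,
    plan: Sequence[tuple[str, str]],
    feature_cols: Sequence[str] = DEFAULT_FEATURES,
    m: int = DEFAULT_M,
    exclude_mmr_deficient_from: Iterable[str] = (),
    group_col: str = "group",
) -> tuple[list[ComparisonResult], dict[tuple[str, str], GroupSummary]]:
    """Comparisons for each feature and each planned pair of groups.

    ``features`` must carry one row per sample with a ``group`` column and
    the feature columns. Samples with ``mmr_status == "deficient"`` are
    dropped from groups named in ``exclude_mmr_deficient_from`` (the
    biallelic-MUTYH CRC group in the default plan): MMR-deficiency adds
    its own mutational process and would dilute the base-excision-repair
    comparison. Groups of one sample are summarised but never tested.
    """
    for col in (group_col, *feature_cols):
        if col not in features.columns:
            raise KeyError(f"features table is missing column {col!r}")
    known = set(features[group_col].unique())
    for a, b in plan:
        for g in (a, b):
            if g not in known:
                raise KeyError(f"unknown group label {g!r}")

    def group_values(label: str, feature: str) -> np.ndarray:
        sub = features[features[group_col] == label]
        if label in set(exclude_mmr_deficient_from) and "mmr_status" in sub.columns:
            sub = sub[sub["mmr_status"] != "deficient"]
        return sub[feature].dropna().to_numpy(dtype=float)

    summaries: dict[tuple[str, str], GroupSummary] = {}
    results: list[ComparisonResult] = []
    labels = {g for pair in plan for g in pair}
    for label in sorted(labels):
        for feature in feature_cols:
            vals = group_values(label, feature)
            if vals.size:
                summaries[(label, feature)] = summarize(vals, label)
    for feature in feature_cols:
        for a, b in plan:
            va = group_values(a, feature)
            vb = group_values(b, feature)
            if va.size < 2 or vb.size < 2:
                continue  # singletons are summarised only
            t, df, p = welch_t_test(va, vb)
            results.append(
                ComparisonResult(
                    feature=feature,
                    group_a=a,
                    group_b=b,
                    t=t,
                    df=df,
                    p=p,
                    p_adjusted=bonferroni_adjust(p, m),
                    cohens_d=cohens_d_pooled(va, vb),
                    summary_a=summaries.get((a, feature)),
                    summary_b=summaries.get((b, feature)),
                )
            )
    return results, summaries


def comparisons_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten ComparisonResults to a tidy table."""
    rows = []
    for r in results:
        rows.append(
            {
                "feature": r.feature,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "n_a": r.summary_a.n if r.summary_a else None,
                "n_b": r.summary_b.n if r.summary_b else None,
                "mean_a": r.summary_a.mean if r.summary_a else None,
                "mean_b": r.summary_b.mean if r.summary_b else None,
                "sd_a": r.summary_a.sd if r.summary_a else None,
                "sd_b": r.summary_b.sd if r.summary_b else None,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "cohens_d": r.cohens_d,
            }
        )
    return pd.DataFrame(rows)
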