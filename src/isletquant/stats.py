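"""Donor-level aggregation and group statistics.

The test choice is gated on per-group normality (Shapiro–Wilk at
alpha = 0.05): one-way ANOVA with Tukey HSD post-hoc when every group
passes, Kruskal–Wallis with Dunn post-hoc (Holm-adjusted) otherwise.
Paired within-donor contrasts use a random-intercept-per-donor
mixed-effects model, cross-checked against a paired t-test on donor-level
means.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupResult",
    "aggregate_donor",
    "compare_groups",
    "mixed_effects_paired",
    "phenotype_trajectory",
    "dunn_posthoc",
    "GROUP_ORDER",
]

GROUP_ORDER = ["ND", "AAb+", "T1D_recent", "T1D_long", "T2D"]
SHAPIRO_ALPHA = 0.05


@dataclass
class GroupResult:
    metric: str
    groups: list[str]
    test_used: str               # "anova" | "kruskal" | "mixed-effects"
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None
    normality: dict[str, bool] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# aggregation


def aggregate_donor(
    table: pd.DataFrame,
    metric: str,
    statistic: str = "mean",
    donor_col: str = "donor_id",
    group_col: str = "group",
) -> pd.DataFrame:
    """One value per donor per metric (the donor is the statistical unit).

    ``statistic`` is 'mean' or 'median' over that donor's rows.  Donors
    with no finite values yield a missing value with ``n = 0``.
    """
    if metric not in table.columns:
        numeric = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
        raise KeyError(f"unknown metric {metric!r}; available: {numeric}")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    rows = []
    for donor, sub in table.groupby(donor_col, sort=True):
        vals = sub[metric].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        value = float(getattr(np, statistic)(vals)) if vals.size else np.nan
        row = {
            donor_col: donor,
            "metric": metric,
            "statistic": statistic,
            "value": value,
            "dispersion": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
            "n": int(vals.size),
        }
        if group_col in sub.columns:
            row[group_col] = sub[group_col].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# omnibus group comparison with normality gate


def dunn_posthoc(samples: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal–Wallis, with tie
    correction and multiplicity adjustment."""
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    rank_means = {}
    start = 0
    for g in names:
        n = samples[g].size
        rank_means[g] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    pvals = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / samples[a].size + 1.0 / samples[b].size))
        z = (rank_means[a] - rank_means[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "statistic": float(z)})
        pvals.append(p)
    adj = multipletests(pvals, method=adjust)[1] if pvals else []
    for row, p, pa in zip(rows, pvals, adj):
        row["p_value"] = float(p)
        row["p_adjusted"] = float(pa)
    return pd.DataFrame(rows)


def compare_groups(
    summaries: pd.DataFrame,
    metric: str | None = None,
    value_col: str = "value",
    group_col: str = "group",
    min_donors: int = 3,
) -> GroupResult:
    """Gated omnibus comparison of donor-level values across groups.

    Shapiro–Wilk at alpha = 0.05 per group decides between one-way ANOVA
    (all normal; Tukey HSD post-hoc) and Kruskal–Wallis (Dunn post-hoc
    with Holm adjustment).  Groups with fewer than ``min_donors`` donors
    are excluded with a warning.
    """
    df = summaries
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    df = df[np.isfinite(df[value_col].astype(float))]
    samples: dict[str, np.ndarray] = {}
    notes: list[str] = []
    for g, sub in df.groupby(group_col, sort=True):
        vals = sub[value_col].to_numpy(dtype=float)
        if vals.size < min_donors:
            notes.append(f"group {g!r} excluded (n={vals.size} < {min_donors})")
            warnings.warn(notes[-1], stacklevel=2)
            continue
        samples[g] = vals
    if len(samples) < 2:
        raise ValueError("need >= 2 groups with enough donors to compare")
    normality: dict[str, bool] = {}
    for g, vals in samples.items():
        if np.ptp(vals) == 0:
            normality[g] = False  # constant sample: Shapiro undefined
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality[g] = bool(sps.shapiro(vals).pvalue >= SHAPIRO_ALPHA)
    names = list(samples)
    arrays = [samples[g] for g in names]
    if all(np.ptp(v) == 0 for v in arrays) and len({v[0] for v in arrays}) == 1:
        # identical constant groups: nothing to reject
        return GroupResult(
            metric=metric or value_col, groups=names, test_used="kruskal",
            statistic=0.0, p_value=1.0, normality=normality, notes=notes,
        )
    if all(normality.values()):
        stat, p = sps.f_oneway(*arrays)
        flat = np.concatenate(arrays)
        labels = np.concatenate([[g] * samples[g].size for g in names])
        tuk = pairwise_tukeyhsd(flat, labels, alpha=0.05)
        posthoc = pd.DataFrame(
            tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
        )
        posthoc = posthoc.rename(
            columns={"p-adj": "p_adjusted", "group1": "group1", "group2": "group2"}
        )
        test = "anova"
    else:
        stat, p = sps.kruskal(*arrays)
        posthoc = dunn_posthoc(samples)
        test = "kruskal"
    return GroupResult(
        metric=metric or value_col,
        groups=names,
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        posthoc=posthoc,
        normality=normality,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# paired mixed-effects contrast


def mixed_effects_paired(
    cell_table: pd.DataFrame,
    value_col: str,
    condition_col: str,
    donor_col: str = "donor_id",
    min_donors: int = 3,
) -> GroupResult:
    """Random-intercept-per-donor model of ``value ~ condition``.

    The fixed-effect contrast (second condition level minus first) and
    its Wald p-value are reported; a paired t-test on donor-level means
    is attached as a cross-check.
    """
    df = cell_table[[donor_col, condition_col, value_col]].dropna()
    levels = sorted(df[condition_col].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 condition levels, got {levels}")
    both = (
        df.groupby(donor_col)[condition_col].nunique().pipe(lambda s: s[s == 2]).index
    )
    if len(both) < min_donors:
        raise ValueError(
            f"condition present in both levels for only {len(both)} donors "
            f"(need >= {min_donors})"
        )
    df = df[df[donor_col].isin(both)].copy()
    df["_x"] = (df[condition_col] == levels[1]).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(
            df[value_col].to_numpy(dtype=float),
            np.column_stack([np.ones(len(df)), df["_x"].to_numpy()]),
            groups=df[donor_col].to_numpy(),
        )
        fit = model.fit(reml=True)
    effect = float(fit.params[1])
    p = float(fit.pvalues[1])
    donor_means = df.pivot_table(
        index=donor_col, columns=condition_col, values=value_col, aggfunc="mean"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_stat, t_p = sps.ttest_rel(donor_means[levels[1]], donor_means[levels[0]])
    posthoc = pd.DataFrame(
        [
            {
                "contrast": f"{levels[1]} - {levels[0]}",
                "effect": effect,
                "p_value": p,
                "paired_t_statistic": float(t_stat),
                "paired_t_p_value": float(t_p),
            }
        ]
    )
    return GroupResult(
        metric=value_col,
        groups=levels,
        test_used="mixed-effects",
        statistic=effect,
        p_value=p,
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# phenotype trajectory


def phenotype_trajectory(
    counts: pd.DataFrame,
    group_order: list[str] | None = None,
    donor_col: str = "donor_id",
    group_col: str = "group",
    phenotype_col: str = "phenotype",
    count_col: str = "n_cells",
) -> pd.DataFrame:
    """Mean per-donor phenotype fractions per group, ordered by disease
    stage.  Fractions sum to 1 per group (donors with zero cells are
    skipped)."""
    order = group_order or GROUP_ORDER
    rows = []
    for group, gsub in counts.groupby(group_col):
        donor_fracs = []
        for _, dsub in gsub.groupby(donor_col):
            total = dsub[count_col].sum()
            if total == 0:
                continue
            donor_fracs.append(
                dsub.set_index(phenotype_col)[count_col] / total
            )
        if not donor_fracs:
            continue
        mean_frac = pd.concat(donor_fracs, axis=1).fillna(0.0).mean(axis=1)
        mean_frac = mean_frac / mean_frac.sum()
        for phen, frac in mean_frac.items():
            rows.append({group_col: group, phenotype_col: phen, "fraction": float(frac)})
    out = pd.DataFrame(rows)
    if len(out):
        rank = {g: i for i, g in enumerate(order)}
        out["_rank"] = out[group_col].map(lambda g: rank.get(g, len(rank)))
        out = out.sort_values(["_rank", phenotype_col]).drop(columns="_rank")
        out = out.reset_index(drop=True)
    return out
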