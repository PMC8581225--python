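"""Nonparametric group-comparison battery for arousal outcomes.

Rank-based tests as used for clinical case-control arousal comparisons:
Mann-Whitney U with the rank-based effect size r = |Z|/sqrt(n),
Kruskal-Wallis with eta^2 = (H - k + 1)/(n - k), Spearman correlation
tables, a Pearson chi-square on binned stability distributions, a pooled
two-sample t with Cohen's d, and tolerance-based randomized case-control
age matching.  No multiple-testing correction is applied anywhere — the
battery mirrors an explicitly explorative analysis strategy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stages import STAGE_ORDER


@dataclass
class GroupComparison:
    """One contrast: test statistic, p-value, effect size, sample sizes."""

    test: str
    statistic: float
    p: float
    effect: float
    effect_name: str
    n_per_group: tuple
    z: float | None = None
    df: float | None = None
    k: int | None = None


@dataclass
class MatchSpec:
    """Randomized case-control matching specification."""

    tolerance: float = 2.0   # months
    seed: int = 0
    match_gender: bool = False

    def validate(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-based effect size r = |Z| / sqrt(n).

    Reported as a magnitude; reproduces published effect-size cells from
    their printed Z statistics and sample sizes.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return abs(z) / np.sqrt(n_total)


def _mw_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U1, Z) with mid-rank ties, tie-corrected variance, no continuity
    correction."""
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = 0.0 if var == 0 else (u1 - mu) / np.sqrt(var)
    return u1, z


def mann_whitney(x, y) -> GroupComparison:
    """Mann-Whitney U test with rank-based effect size.

    The p-value is exact for small tie-free samples and otherwise uses the
    tie-corrected normal approximation without continuity correction; the
    effect size is always r = |Z|/sqrt(n1 + n2) from the approximation Z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u1, z = _mw_z(x, y)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if not has_ties and x.size + y.size <= 20:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue)
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return GroupComparison(
        test="mann-whitney", statistic=float(u1), p=p,
        effect=effect_size_r(z, x.size + y.size), effect_name="r",
        n_per_group=(x.size, y.size), z=float(z))


def kruskal_wallis(groups) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with eta^2 = (H - k + 1)/(n - k).

    eta^2 is reported unclamped (slightly negative values arise for H < k-1
    and round to the small magnitudes seen in published tables).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    combined = np.concatenate(groups)
    if np.all(combined == combined[0]):  # degenerate: every value tied
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    eta2 = (h - k + 1) / (n - k)
    return GroupComparison(
        test="kruskal-wallis", statistic=float(h), p=float(p),
        effect=float(eta2), effect_name="eta2",
        n_per_group=tuple(g.size for g in groups), df=k - 1, k=k)


def spearman_table(scores: pd.DataFrame, arousal: pd.DataFrame
                   ) -> pd.DataFrame:
    """Spearman rho/p for every (clinical score, arousal measure) pair.

    Rows are score columns, columns a MultiIndex (measure, {rho, p}).
    Cells with fewer than 4 complete pairs are NaN.
    """
    out = {}
    for measure in arousal.columns:
        rhos, ps = [], []
        for score in scores.columns:
            pair = pd.concat([scores[score], arousal[measure]], axis=1).dropna()
            if len(pair) < 4:
                rhos.append(np.nan)
                ps.append(np.nan)
                continue
            rho, p = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rhos.append(float(rho))
            ps.append(float(p))
        out[(measure, "rho")] = rhos
        out[(measure, "p")] = ps
    return pd.DataFrame(out, index=list(scores.columns))


def age_match(cases: pd.DataFrame, controls: pd.DataFrame,
              spec: MatchSpec | None = None, age_col: str = "age_months"
              ) -> pd.DataFrame:
    """Randomized greedy case-control matching within an age tolerance.

    Cases are visited in seeded-random order; each is paired with a random
    not-yet-used control whose age differs by at most ``tolerance`` months.
    Unmatched cases are dropped (their count is the difference between
    ``len(cases)`` and ``len(result)``).  Deterministic under the seed.
    """
    spec = spec or MatchSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.match_gender and "gender" not in cases.columns:
        raise ValueError("match_gender requires a 'gender' column")
    case_order = rng.permutation(len(cases))
    used = np.zeros(len(controls), dtype=bool)
    ctrl_ages = controls[age_col].to_numpy(dtype=float)
    pairs = []
    for ci in case_order:
        case = cases.iloc[ci]
        ok = (~used) & (np.abs(ctrl_ages - float(case[age_col]))
                        <= spec.tolerance)
        if spec.match_gender:
            ok &= (controls["gender"].to_numpy() == case["gender"])
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            continue
        pick = int(rng.choice(cand))
        used[pick] = True
        pairs.append({
            "case_index": cases.index[ci],
            "control_index": controls.index[pick],
            "case_age": float(case[age_col]),
            "control_age": float(ctrl_ages[pick]),
            "age_diff": abs(float(case[age_col]) - float(ctrl_ages[pick])),
        })
    return pd.DataFrame(pairs)


DEFAULT_STABILITY_BINS: tuple = ((1, 3), (4, 5), (6, 7), (8, 8))


def stability_chi2(scores_a, scores_b,
                   bins: tuple = DEFAULT_STABILITY_BINS) -> GroupComparison:
    """Pearson chi-square of group x binned-stability contingency.

    The default 4-bin partition {1-3, 4-5, 6-7, 8} gives df = 3.  Bins with
    zero expected count are merged into their neighbor with a warning.
    """
    def binned(scores):
        scores = np.asarray(scores)
        return np.array([np.sum((scores >= lo) & (scores <= hi))
                         for lo, hi in bins])

    table = np.vstack([binned(scores_a), binned(scores_b)])
    keep = table.sum(axis=0) > 0
    if not keep.all():
        warnings.warn("empty stability bins merged out of the contingency "
                      "table", stacklevel=2)
        table = table[:, keep]
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    n = int(table.sum())
    return GroupComparison(
        test="chi2", statistic=float(chi2), p=float(p),
        effect=float(np.sqrt(chi2 / n)), effect_name="phi",
        n_per_group=(int(table[0].sum()), int(table[1].sum())),
        df=float(df))


def two_sample_t(x, y) -> GroupComparison:
    """Pooled-variance two-sample t with Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    s_pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                       / (n1 + n2 - 2))
    if s_pooled == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    d = (x.mean() - y.mean()) / s_pooled
    return GroupComparison(
        test="t", statistic=float(t), p=float(p), effect=float(d),
        effect_name="d", n_per_group=(n1, n2), df=float(n1 + n2 - 2))


#: arousal outcome columns compared between diagnostic groups
AROUSAL_MEASURES: tuple = ("stability", "mean_vigilance") + tuple(
    f"occ_{s}" for s in STAGE_ORDER)


def vigilance_comparison_table(table: pd.DataFrame, group_col: str = "group",
                               measures: tuple = AROUSAL_MEASURES
                               ) -> pd.DataFrame:
    """Mann-Whitney battery over arousal measures between two groups.

    Output rows mirror published vigilance-comparison tables: per measure the
    group means/SDs, Z, p, and r.
    """
    names = sorted(table[group_col].unique())
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    a = table[table[group_col] == names[0]]
    b = table[table[group_col] == names[1]]
    rows = []
    for m in measures:
        cmp_ = mann_whitney(a[m].to_numpy(), b[m].to_numpy())
        rows.append({
            "measure": m,
            f"mean_{names[0]}": a[m].mean(), f"sd_{names[0]}": a[m].std(ddof=1),
            f"mean_{names[1]}": b[m].mean(), f"sd_{names[1]}": b[m].std(ddof=1),
            "U": cmp_.statistic, "Z": cmp_.z, "p": cmp_.p, "r": cmp_.effect,
            f"n_{names[0]}": len(a), f"n_{names[1]}": len(b),
        })
    return pd.DataFrame(rows)
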