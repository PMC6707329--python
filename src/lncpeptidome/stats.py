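"""Differential-abundance statistics.

The central tool is a two-group moderated t-test in the empirical-Bayes
style of limma: per-feature sample variances s2_g (d_g residual df) are
shrunk toward a prior (d0, s0^2) estimated across features by moment
matching on log variances, giving the posterior variance

    s~2_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated statistic t_g = fc_g / (s~_g * sqrt(1/n1 + 1/n2)),
referred to a t distribution with d_g + d0 degrees of freedom.  At d0 = 0
this is the ordinary pooled t; at d0 = inf all features share s0^2.

All matrices entering this module hold log2 intensities with NaN for
missing; each feature is tested on its available samples and the per-group
n is recorded.  Features below the minimum n per group are flagged
excluded, never silently dropped.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

STAGES = ("I", "II", "III", "IV")


# ---------------------------------------------------------------------------
# empirical Bayes variance shrinkage (Smyth 2004 moment matching)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate (d0, s0^2) from per-feature variances by moment matching.

    Matches mean and variance of log s2_g to a scaled-F distribution; if the
    observed spread of log variances is no larger than expected from chi^2
    sampling alone, the prior df is infinite (all features share s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        warnings.warn("too few variances to fit a prior; using d0=inf", stacklevel=2)
        return math.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # spread of log variances no larger than chi^2 sampling alone:
        # infinite prior df, pooled variance is the plain mean
        d0 = math.inf
        s0_2 = float(np.mean(s2))
    return d0, s0_2


def moderated_t_test(
    matrix: pd.DataFrame,
    labels: pd.Series | dict,
    group1: str,
    group2: str,
    min_n: int = 2,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Per-row moderated t-test of ``group2`` vs ``group1`` log2 intensities.

    Returns a DataFrame with log2fc (mean group2 - mean group1), t_mod, p,
    adj_p (BH over tested rows), n1, n2 and an ``excluded`` reason column.
    ``d0_override`` forces the prior df (0 -> ordinary pooled t,
    inf -> fully shared variance); by default the prior is estimated.
    """
    labels = pd.Series(labels)
    cols1 = [c for c in matrix.columns if labels.get(c) == group1]
    cols2 = [c for c in matrix.columns if labels.get(c) == group2]
    if not cols1 or not cols2:
        raise ValueError(f"need samples in both groups {group1!r} and {group2!r}")
    x1 = matrix[cols1].to_numpy(dtype=float)
    x2 = matrix[cols2].to_numpy(dtype=float)
    n1 = (~np.isnan(x1)).sum(axis=1)
    n2 = (~np.isnan(x2)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        v1 = np.nanvar(x1, axis=1, ddof=1)
        v2 = np.nanvar(x2, axis=1, ddof=1)
    fc = m2 - m1
    dg = (n1 + n2 - 2).astype(float)
    tested = (n1 >= min_n) & (n2 >= min_n)
    # pooled per-row variance
    s2 = np.where(
        tested, ((n1 - 1) * np.nan_to_num(v1) + (n2 - 1) * np.nan_to_num(v2)) / np.maximum(dg, 1), np.nan
    )
    if d0_override is None:
        d0, s0_2 = fit_variance_prior(s2[tested], dg[tested])
    else:
        d0 = float(d0_override)
        _, s0_2 = fit_variance_prior(s2[tested], dg[tested])
    if np.isinf(d0):
        post_var = np.full_like(s2, s0_2)
        df_total = dg + d0
    else:
        post_var = (d0 * s0_2 + dg * s2) / (d0 + dg) if d0 > 0 else s2
        df_total = dg + d0
    # total df cannot exceed the pooled residual df over all tested features
    df_total = np.minimum(df_total, float(np.sum(dg[tested])))
    se = np.sqrt(post_var * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / se
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "log2fc": fc,
            "t_mod": np.where(tested, t, np.nan),
            "p": np.where(tested, p, np.nan),
            "n1": n1,
            "n2": n2,
            "excluded": np.where(tested, "", f"fewer than {min_n} values per group"),
        },
        index=matrix.index,
    )
    out["adj_p"] = np.nan
    if tested.any():
        out.loc[tested, "adj_p"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    return out


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1,
    monotone in the p-value ordering, order-preserving in the input)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# stage analysis


def stage_filter(
    matrix: pd.DataFrame,
    stage_labels: pd.Series | dict,
    min_per_stage: int = 2,
    stages: tuple[str, ...] = STAGES,
) -> pd.Series:
    """Presence filter: a row passes iff every stage has at least
    ``min_per_stage`` non-missing values.  Errors if a stage is absent
    from the cohort altogether."""
    stage_labels = pd.Series(stage_labels)
    cols_by_stage = {
        s: [c for c in matrix.columns if stage_labels.get(c) == s] for s in stages
    }
    for s, cols in cols_by_stage.items():
        if not cols:
            raise ValueError(f"stage {s} has no samples in the cohort")
    included = pd.Series(True, index=matrix.index)
    for s, cols in cols_by_stage.items():
        included &= matrix[cols].notna().sum(axis=1) >= min_per_stage
    return included


def one_way_anova(values_by_group: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA (F, p) over log2 value groups.

    Zero total variance returns (0, 1) with a warning.
    """
    arrays = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    arrays = [a[~np.isnan(a)] for a in arrays]
    arrays = [a for a in arrays if len(a) > 0]
    if len(arrays) < 2:
        return math.nan, math.nan
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        warnings.warn("zero total variance; p set to 1", stacklevel=2)
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def stage_anova(
    matrix: pd.DataFrame,
    stage_labels: pd.Series | dict,
    min_per_stage: int = 2,
    stages: tuple[str, ...] = STAGES,
) -> pd.DataFrame:
    """Stage-wise pipeline: 2-of-4 presence filter, then one-way ANOVA of
    log2 abundance across stages; BH across the included rows."""
    stage_labels = pd.Series(stage_labels)
    included = stage_filter(matrix, stage_labels, min_per_stage, stages)
    rows = []
    for gid in matrix.index:
        if not included[gid]:
            rows.append({"group_id": gid, "F": math.nan, "p": math.nan, "included": False})
            continue
        groups = {
            s: matrix.loc[gid, [c for c in matrix.columns if stage_labels.get(c) == s]]
            .to_numpy(dtype=float)
            for s in stages
        }
        f, p = one_way_anova(groups)
        rows.append({"group_id": gid, "F": f, "p": p, "included": True})
    out = pd.DataFrame(rows).set_index("group_id")
    out["adj_p"] = np.nan
    mask = out["included"] & out["p"].notna()
    if mask.any():
        out.loc[mask, "adj_p"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def early_late_test(
    matrix: pd.DataFrame,
    stage_labels: pd.Series | dict,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Unpaired t-test of late (III+IV) vs early (I+II) log2 abundance.

    Welch by default; ``equal_var=True`` gives the pooled-variance test.
    log2fc is mean(late) - mean(early).
    """
    stage_labels = pd.Series(stage_labels)
    early_cols = [c for c in matrix.columns if stage_labels.get(c) in ("I", "II")]
    late_cols = [c for c in matrix.columns if stage_labels.get(c) in ("III", "IV")]
    if len(early_cols) < 2 or len(late_cols) < 2:
        raise ValueError("need at least two samples in each of early and late")
    rows = []
    for gid in matrix.index:
        e = matrix.loc[gid, early_cols].dropna().to_numpy(dtype=float)
        l = matrix.loc[gid, late_cols].dropna().to_numpy(dtype=float)
        if len(e) < 2 or len(l) < 2 or (np.ptp(e) == 0 and np.ptp(l) == 0):
            rows.append(
                {"group_id": gid, "log2fc": math.nan, "t": math.nan, "p": math.nan,
                 "n_early": len(e), "n_late": len(l), "excluded": "degenerate group"}
            )
            continue
        t, p = sps.ttest_ind(l, e, equal_var=equal_var)
        rows.append(
            {"group_id": gid, "log2fc": float(np.mean(l) - np.mean(e)),
             "t": float(t), "p": float(p), "n_early": len(e), "n_late": len(l),
             "excluded": ""}
        )
    out = pd.DataFrame(rows).set_index("group_id")
    out["adj_p"] = np.nan
    mask = out["p"].notna()
    if mask.any():
        out.loc[mask, "adj_p"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def paired_t_test(matrix: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Paired-difference t-test for patient-matched designs.

    ``pairs`` lists (condition-A sample, condition-B sample) columns; the
    test is on the per-patient log2 differences B - A.
    """
    rows = []
    for gid in matrix.index:
        diffs = np.array(
            [matrix.loc[gid, b] - matrix.loc[gid, a] for a, b in pairs], dtype=float
        )
        diffs = diffs[~np.isnan(diffs)]
        if len(diffs) < 2:
            rows.append({"group_id": gid, "log2fc": math.nan, "t": math.nan,
                         "p": math.nan, "n_pairs": len(diffs)})
            continue
        t, p = sps.ttest_1samp(diffs, 0.0)
        rows.append({"group_id": gid, "log2fc": float(np.mean(diffs)),
                     "t": float(t), "p": float(p), "n_pairs": len(diffs)})
    out = pd.DataFrame(rows).set_index("group_id")
    mask = out["p"].notna()
    out["adj_p"] = np.nan
    if mask.any():
        out.loc[mask, "adj_p"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# enrichment


def hypergeom_enrichment(
    selected: set[str], term_map: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the selected set.

    The universe is the whole set of quantified ids; term sets are
    intersected with it.  P(X >= overlap) per term, BH across terms.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected ids must be a subset of the universe")
    m = len(universe)
    n_sel = len(selected)
    rows = []
    for term, ids in sorted(term_map.items()):
        cat = set(ids) & universe
        overlap = len(cat & selected)
        p = float(sps.hypergeom.sf(overlap - 1, m, len(cat), n_sel))
        rows.append(
            {"term_id": term, "overlap": overlap, "selected_size": n_sel,
             "category_size": len(cat), "universe_size": m, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows).set_index("term_id")
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    else:
        out["adj_p"] = []
    return out
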