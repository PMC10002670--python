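"""Statistics on regional loads and load × gene-expression integration.

Covers: expected-read-count gene filtering, Benjamini–Hochberg FDR,
Pearson correlation of expression against load with and without age
adjustment (within-age-group centering, the standard multilevel/partial
construction), gene classification into age-dependent / age-independent /
both / ns, two-factor (age + strain) ANOVA on regional loads, and the paired
Wilcoxon signed-rank comparison of linear vs nonlinear registration loads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

CATEGORIES = ("age_dependent", "age_independent", "both", "ns")


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    fdr_method: str = "bh"
    erc_min: float = 10.0  # strict: count must exceed this
    erc_sample_frac: float = 0.5  # strict: in more than this fraction of samples

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def filter_genes(counts: pd.DataFrame, cfg: StatsConfig = StatsConfig()) -> pd.DataFrame:
    """Keep genes with count > erc_min in strictly more than half the samples.

    ``counts`` is genes × samples.  Both comparisons are strict: a gene at
    exactly the count floor, or passing in exactly half the samples, is
    removed.
    """
    if counts.empty:
        raise ValueError("counts matrix is empty")
    n_pass = (counts > cfg.erc_min).sum(axis=1)
    keep = n_pass > cfg.erc_sample_frac * counts.shape[1]
    return counts.loc[keep]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _pearson_p(r: float, df: int) -> float:
    if df <= 0:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def corr_unadjusted(expr: Sequence[float], load: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided p from the t transform, df = n − 2.

    Returns (nan, nan) when either vector has zero variance.
    """
    x = np.asarray(expr, dtype=float)
    y = np.asarray(load, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expr and load must be 1D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, _pearson_p(r, x.size - 2)


def corr_age_adjusted(
    expr: Sequence[float], load: Sequence[float], age_group: Sequence
) -> tuple[float, float]:
    """Within-group-centered Pearson correlation (multilevel construction).

    Both variables are mean-centered within each age group; r is the Pearson
    correlation of the pooled centered values and p comes from the t
    transform with df = n − g − 1 (g groups).  Groups with fewer than two
    observations are dropped with a warning.
    """
    x = np.asarray(expr, dtype=float)
    y = np.asarray(load, dtype=float)
    g = np.asarray(age_group)
    if not (x.shape == y.shape == g.shape):
        raise ValueError("expr, load and age_group must have equal length")
    keep = np.ones(x.size, dtype=bool)
    groups = pd.unique(g)
    for grp in groups:
        members = g == grp
        if members.sum() < 2:
            warnings.warn(f"dropping age group {grp!r} with n < 2", stacklevel=2)
            keep &= ~members
    x, y, g = x[keep], y[keep], g[keep]
    groups = pd.unique(g)
    n, ng = x.size, len(groups)
    if ng < 1 or n - ng - 1 <= 0:
        raise ValueError("not enough observations after dropping small groups")
    xc = np.empty_like(x)
    yc = np.empty_like(y)
    for grp in groups:
        members = g == grp
        xc[members] = x[members] - x[members].mean()
        yc[members] = y[members] - y[members].mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    return r, _pearson_p(r, n - ng - 1)


def classify_gene(p_unadjusted: float, p_adjusted: float, alpha: float = 0.05) -> str:
    """Category from the two uncorrected p-values at level alpha."""
    sig_un = p_unadjusted < alpha
    sig_adj = p_adjusted < alpha
    if sig_un and sig_adj:
        return "both"
    if sig_un:
        return "age_dependent"
    if sig_adj:
        return "age_independent"
    return "ns"


def classify_genes(results: pd.DataFrame, cfg: StatsConfig = StatsConfig()) -> pd.Series:
    """Vectorized :func:`classify_gene` over a results frame.

    Expects columns ``p_unadjusted`` and ``p_adjusted``.
    """
    return pd.Series(
        [
            classify_gene(pu, pa, cfg.alpha)
            for pu, pa in zip(results["p_unadjusted"], results["p_adjusted"])
        ],
        index=results.index,
        name="category",
    )


def correlate_expression_with_load(
    expr: pd.DataFrame,
    load: Sequence[float],
    age_group: Sequence,
    cfg: StatsConfig = StatsConfig(),
) -> pd.DataFrame:
    """Per-gene unadjusted and age-adjusted correlation with FDR and category.

    ``expr`` is genes × samples (normalized); ``load`` and ``age_group`` are
    per-sample.  Returns a frame indexed by gene with columns
    r/p/q_unadjusted, r/p/q_adjusted and category.
    """
    load = np.asarray(load, dtype=float)
    age_group = np.asarray(age_group)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene, values in expr.iterrows():
            x = values.to_numpy(dtype=float)
            r_un, p_un = corr_unadjusted(x, load)
            r_adj, p_adj = corr_age_adjusted(x, load, age_group)
            rows.append((gene, r_un, p_un, r_adj, p_adj))
    out = pd.DataFrame(
        rows, columns=["gene", "r_unadjusted", "p_unadjusted", "r_adjusted", "p_adjusted"]
    ).set_index("gene")
    for col in ("p_unadjusted", "p_adjusted"):
        q = np.full(len(out), np.nan)
        ok = out[col].notna().to_numpy()
        if ok.any():
            q[ok] = bh_fdr(out.loc[ok, col].to_numpy())
        out[col.replace("p_", "q_")] = q
    out["category"] = classify_genes(out, cfg)
    return out


def age_effect_test(
    table: pd.DataFrame,
    load_col: str = "load",
    age_col: str = "age_group",
    strain_col: str = "strain",
) -> tuple[float, float]:
    """Two-factor fixed-effects ANOVA (age + strain, no interaction).

    Type-II sums of squares for unbalanced designs; returns the age factor's
    (F, p).  A design where strain perfectly confounds age raises ValueError.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[load_col, age_col, strain_col]].copy()
    df.columns = ["load", "age", "strain"]
    if df["age"].nunique() < 2:
        raise ValueError("both age groups must be represented")
    formula = "load ~ C(age)" if df["strain"].nunique() < 2 else "load ~ C(age) + C(strain)"
    model = smf.ols(formula, data=df).fit()
    exog = model.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("singular design: strain is confounded with age")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = sm.stats.anova_lm(model, typ=2)
    row = anova.loc["C(age)"]
    f, p = float(row["F"]), float(row["PR(>F)"])
    if not np.isfinite(f) or not np.isfinite(p):
        raise ValueError("singular design: age effect not estimable")
    return f, p


def age_effect_by_region(
    table: pd.DataFrame,
    region_col: str = "region_id",
    **kwargs,
) -> pd.DataFrame:
    """Per-region ANOVA age effects with BH correction across regions.

    Regions with singular designs are reported with NaN and flagged; they do
    not enter the FDR correction.
    """
    rows = []
    for region, sub in table.groupby(region_col):
        try:
            f, p = age_effect_test(sub, **kwargs)
            rows.append((region, f, p, ""))
        except ValueError as exc:
            rows.append((region, np.nan, np.nan, str(exc)))
    out = pd.DataFrame(rows, columns=["region_id", "F", "p", "flag"]).set_index("region_id")
    q = np.full(len(out), np.nan)
    ok = out["p"].notna().to_numpy()
    if ok.any():
        q[ok] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    return out


def method_difference_test(
    load_linear: Sequence[float], load_nonlinear: Sequence[float]
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank on per-animal regional loads.

    Exact null distribution for n ≤ 25 without ties/zeros, otherwise the
    normal approximation with tie correction.  All-zero differences give
    (0.0, 1.0).
    """
    x = np.asarray(load_linear, dtype=float)
    y = np.asarray(load_nonlinear, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = y - x
    if np.all(d == 0):
        return 0.0, 1.0
    nz = d[d != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    if len(nz) <= 25 and not has_ties and len(nz) == len(d):
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(y, x, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


def method_difference_by_region(
    loads: pd.DataFrame,
    region_col: str = "region_id",
    linear_col: str = "load_linear",
    nonlinear_col: str = "load_nonlinear",
) -> pd.DataFrame:
    """Per-region paired Wilcoxon with BH correction across regions."""
    rows = []
    for region, sub in loads.groupby(region_col):
        stat, p = method_difference_test(
            sub[linear_col].to_numpy(), sub[nonlinear_col].to_numpy()
        )
        rows.append((region, stat, p))
    out = pd.DataFrame(rows, columns=["region_id", "statistic", "p"]).set_index("region_id")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
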