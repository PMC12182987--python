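"""Quantitative evaluation of harmonization.

The battery mirrors a standard multi-site connectome analysis: connectivity
is first squashed into [0, 1) with the bounded transform c -> 1 - exp(-c/c_bar)
(c_bar the cross-subject mean of the connection), each connection is Pearson-
correlated with a covariate of interest, per-connection significance is
s = -log p with Bonferroni correction over the tested connections, and
harmonization methods are compared through a one-sided Wilcoxon signed-rank
test on the paired |r| plus the change in significance Delta-s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConnectivityTable, SubjectMetadata
from .zig import DEFAULT_MIN_NONZERO, ZIGParams, fit_zig

__all__ = [
    "EvaluationSummary",
    "SubsampleResult",
    "bounded_transform",
    "correlate",
    "compare_to_baseline",
    "rank_by_delta_s",
    "subsample_stability",
]

DEFAULT_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)


def bounded_transform(table: ConnectivityTable) -> ConnectivityTable:
    """Map each value to 1 - exp(-c / c_bar); outputs lie in [0, 1).

    c_bar is the per-connection mean across subjects; an all-zero connection
    (c_bar = 0) stays all-zero.  The transform is strictly increasing in c, so
    within-connection rank order is preserved.
    """
    c_bar = table.values.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - np.exp(-table.values / c_bar)
    out[:, c_bar == 0] = 0.0
    return table.with_values(out)


def correlate(
    table: ConnectivityTable,
    meta: SubjectMetadata,
    covariate: str,
    apply_bounded: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of every connection with a covariate.

    Subjects with a missing covariate are dropped.  Returns one row per
    connection with columns ``i, j, r, p, p_bonf, s, n_used``; p-values are
    two-sided, the Bonferroni factor is the number of connections with a
    defined correlation in this run, and s = -log p (natural log).
    Zero-variance connections get NaN statistics and are excluded from the
    Bonferroni count.
    """
    x = meta.covariate(covariate, table.subject_ids)
    keep = ~np.isnan(x)
    x = x[keep]
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"fewer than 3 subjects with non-missing {covariate!r}")
    values = table.values[keep]
    if apply_bounded:
        sub = ConnectivityTable(
            values=values,
            subject_ids=[s for s, k in zip(table.subject_ids, keep) if k],
            n_regions=table.n_regions,
        )
        values = bounded_transform(sub).values

    xc = x - x.mean()
    yc = values - values.mean(axis=0)
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    zero_var = sy == 0
    if sx == 0:
        raise ValueError(f"covariate {covariate!r} has zero variance")
    r[zero_var] = np.nan
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance connections excluded from correlation"
        )
    # two-sided p via the exact t reference distribution, as pearsonr does
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    n_tested = int((~zero_var).sum())
    p_bonf = np.minimum(1.0, p * n_tested)
    with np.errstate(divide="ignore"):
        s = -np.log(p)
    pairs = np.array(table.pair_index)
    return pd.DataFrame(
        {
            "i": pairs[:, 0],
            "j": pairs[:, 1],
            "r": r,
            "p": p,
            "p_bonf": p_bonf,
            "s": s,
            "n_used": n,
        }
    )


@dataclass
class EvaluationSummary:
    """The four comparison measures plus the per-connection Delta-s."""

    mean_abs_r: float
    std_abs_r: float
    wilcoxon_p: float
    n_significant: int
    min_p_bonf: float
    delta_s: pd.Series  # indexed like the stats tables; s_post - s_pre


def compare_to_baseline(
    post: pd.DataFrame, pre: pd.DataFrame
) -> EvaluationSummary:
    """Compare post-harmonization correlation stats with a baseline.

    The Wilcoxon signed-rank test is one-sided with alternative
    |r_post| > |r_pre|; zero differences are discarded before ranking.
    Connections with undefined r in either table are dropped from all
    summaries.  Significance counts and min p are taken from ``post``.
    """
    if len(post) != len(pre) or not (
        (post["i"].to_numpy() == pre["i"].to_numpy()).all()
        and (post["j"].to_numpy() == pre["j"].to_numpy()).all()
    ):
        raise ValueError("stats tables cover different connection sets")
    ok = post["r"].notna() & pre["r"].notna()
    abs_post = post.loc[ok, "r"].abs().to_numpy()
    abs_pre = pre.loc[ok, "r"].abs().to_numpy()
    diffs = abs_post - abs_pre
    if (diffs == 0).all():
        warnings.warn("all paired |r| differences are zero; Wilcoxon p reported as 1")
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(
            stats.wilcoxon(
                abs_post, abs_pre, alternative="greater", zero_method="wilcox"
            ).pvalue
        )
    delta_s = pd.Series(np.where(ok, post["s"] - pre["s"], np.nan), index=post.index)
    return EvaluationSummary(
        mean_abs_r=float(abs_post.mean()),
        std_abs_r=float(abs_post.std(ddof=1)) if ok.sum() > 1 else float("nan"),
        wilcoxon_p=wilcoxon_p,
        n_significant=int((post.loc[ok, "p_bonf"] < 0.05).sum()),
        min_p_bonf=float(post.loc[ok, "p_bonf"].min()),
        delta_s=delta_s,
    )


def rank_by_delta_s(
    summary: EvaluationSummary,
    pairs: list[tuple[int, int]],
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
) -> list[tuple[int, int]]:
    """Connections at the requested Delta-s quantiles (nearest-rank rule).

    Defaults to the minimum, 25th percentile, median, 75th percentile, and
    maximum.  Ties are broken by connection index, so the result is
    deterministic even when many connections share a Delta-s.
    """
    ds = summary.delta_s.to_numpy()
    valid = np.flatnonzero(~np.isnan(ds))
    if valid.size == 0:
        raise ValueError("no Delta-s values available")
    order = valid[np.lexsort((valid, ds[valid]))]  # by (delta_s, index)
    n = order.size
    chosen = []
    for q in quantiles:
        # nearest-rank: the ceil(q*n)-th order statistic (1-based); q=0 -> first
        rank = max(1, int(np.ceil(q * n)))
        chosen.append(pairs[order[rank - 1]])
    return chosen


@dataclass
class SubsampleResult:
    """ZIG fits over random subsets plus the full-sample fit."""

    fits: list[ZIGParams]
    full_fit: ZIGParams
    subset_size: int

    def density_curves(self, grid: np.ndarray) -> np.ndarray:
        """Continuous mixture density of each subset fit on a grid."""
        from .zig import zig_pdf

        curves = np.zeros((len(self.fits), len(grid)))
        for k, params in enumerate(self.fits):
            if not params.degenerate:
                curves[k] = zig_pdf(grid, params)
        return curves


def subsample_stability(
    values: np.ndarray,
    subset_size: int,
    n_perm: int,
    seed: int,
    min_nonzero: int = DEFAULT_MIN_NONZERO,
) -> SubsampleResult:
    """Refit one connection's ZIG model on random subject subsets.

    Draws ``n_perm`` uniform subsets of ``subset_size`` without replacement
    and fits the ZIG parameters on each, quantifying how much a smaller
    cohort perturbs the estimated distribution relative to the full-sample
    fit.  Fully reproducible from ``seed``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if subset_size >= values.size:
        raise ValueError("subset_size must be smaller than the sample size")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_perm):
            subset = rng.choice(values, size=subset_size, replace=False)
            fits.append(fit_zig(subset, min_nonzero=min_nonzero))
        full_fit = fit_zig(values, min_nonzero=min_nonzero)
    return SubsampleResult(fits=fits, full_fit=full_fit, subset_size=subset_size)
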