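"""Two-group differential testing shared by the methylation and expression arms.

Each feature (probe M-value or gene log2 expression) is fit with a two-group
linear model.  With ``moderate=True`` the per-feature residual variances are
shrunk toward a pooled prior fitted by method-of-moments on the log residual
variances (the empirical-Bayes moderated t of microarray practice); with
``moderate=False`` the classical pooled-variance two-sample t is used.
Multiple testing is controlled by Benjamini-Hochberg, applied across exactly
the features tested in one call.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Output columns of :func:`fit_two_group`, in on-disk order.
DIFF_COLUMNS = ["feature_id", "logFC", "t", "p", "fdr", "mean_a", "mean_b"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone non-decreasing in rank, capped at 1, and >= the raw p elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on the inverse)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) for residual variances.

    Matches the mean and variance of log(s^2) against the scaled-F model
    s^2 ~ s0^2 * F(df, d0): the excess spread of the log variances beyond the
    trigamma(df/2) sampling noise determines the prior df d0.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 features with positive variance to moderate")
    z = np.log(s2[ok])
    e = z - special.polygamma(0, df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1) - float(special.polygamma(1, df / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(np.mean(e) + special.polygamma(0, d0 / 2) - np.log(d0 / 2))
    else:
        d0 = np.inf
        s0_sq = np.exp(np.mean(e))
    return float(d0), float(s0_sq)


def fit_two_group(
    values: pd.DataFrame,
    labels,
    group_a: str = "A",
    group_b: str = "B",
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-feature two-group differential test.

    Parameters
    ----------
    values : DataFrame
        Features in rows, samples in columns, on the analysis scale
        (M-values or log2 expression).
    labels : mapping or Series
        Sample id -> group label; only samples labeled ``group_a`` or
        ``group_b`` are used.
    moderate : bool
        Empirical-Bayes variance moderation (default) vs ordinary pooled t.

    Returns
    -------
    DataFrame indexed like ``values`` with columns logFC (= mean_a - mean_b),
    t, p (two-sided), fdr (BH over the tested features), mean_a, mean_b,
    df and zero_variance flag.
    """
    labels = pd.Series(labels)
    a_cols = labels.index[labels == group_a].intersection(values.columns)
    b_cols = labels.index[labels == group_b].intersection(values.columns)
    na, nb = len(a_cols), len(b_cols)
    if na == 0 or nb == 0:
        raise ValueError(f"empty group: n_{group_a}={na}, n_{group_b}={nb}")
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group for a variance estimate")

    xa = values[list(a_cols)].to_numpy(dtype=float)
    xb = values[list(b_cols)].to_numpy(dtype=float)
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    diff = mean_a - mean_b
    ssa = ((xa - mean_a[:, None]) ** 2).sum(axis=1)
    ssb = ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    df_resid = na + nb - 2
    s2 = (ssa + ssb) / df_resid
    zero_var = s2 <= 0

    if moderate and len(values) < 2:
        warnings.warn("fewer than 2 features: falling back to ordinary t")
        moderate = False

    if moderate:
        d0, s0_sq = _fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0
    else:
        s2_post = s2
        df_total = float(df_resid)

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    res = pd.DataFrame(
        {
            "logFC": diff,
            "t": t,
            "p": p,
            "fdr": bh_adjust(p),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "df": df_total,
            "zero_variance": zero_var,
        },
        index=values.index,
    )
    if zero_var.any():
        logger.info("%d feature(s) with zero residual variance flagged", int(zero_var.sum()))
    return res


def write_diff_table(res: pd.DataFrame, path) -> None:
    out = res.reset_index(names="feature_id")[DIFF_COLUMNS]
    out.to_csv(path, sep="\t", index=False)
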