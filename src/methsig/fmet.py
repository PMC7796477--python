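"""Functional-methylation (fMET) detection.

A gene is functionally methylated when its promoter methylation shows a
significant inverse association with its own expression: ordinary least
squares of log2 expression on promoter beta, requiring a negative slope,
BH-adjusted p < 0.05 and R^2 above a cut (default 0.1).  Promoter
methylation is summarised per gene as the unweighted mean beta over the
gene's promoter probes (configurable to median or the most variable probe).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PROMOTER_CLASSES, MethylationMatrix, ProbeAnnotation
from .linmod import bh_adjust

logger = logging.getLogger(__name__)

FMET_COLUMNS = ["gene", "slope", "r2", "p", "fdr", "n", "qualifies"]


def gene_promoter_beta(
    mat: MethylationMatrix,
    ann: ProbeAnnotation,
    gene: str | None = None,
    classes=PROMOTER_CLASSES,
    aggregate: str = "mean",
) -> pd.DataFrame | pd.Series:
    """Per-sample promoter methylation per gene.

    Returns a genes x samples beta frame (or a Series for a single ``gene``).
    Genes without promoter probes in ``mat`` are skipped with a logged reason.
    """
    pairs = ann.subset(mat.probes).gene_promoter_probes(classes)
    if gene is not None:
        probes = pairs.loc[pairs["gene"] == gene, "probe_id"]
        if probes.empty:
            raise ValueError(f"gene {gene!r} has no promoter probes in the matrix")
        return _aggregate(mat.beta.loc[probes], aggregate).rename(gene)
    if pairs.empty:
        return pd.DataFrame(columns=mat.samples)
    vals = mat.beta.loc[pairs["probe_id"]].to_numpy()
    out = pd.DataFrame(vals, index=pairs["gene"].to_numpy(), columns=mat.samples)
    if aggregate == "mean":
        agg = out.groupby(level=0).mean()
    elif aggregate == "median":
        agg = out.groupby(level=0).median()
    elif aggregate == "most_variable":
        var = out.var(axis=1).to_numpy()
        rows = [positions[int(np.argmax(var[positions]))]
                for positions in (np.flatnonzero(out.index == g)
                                  for g in out.index.unique())]
        agg = out.iloc[rows].set_axis(out.index.unique(), axis=0)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return agg.sort_index()


def _aggregate(beta: pd.DataFrame, how: str) -> pd.Series:
    if how == "mean":
        return beta.mean(axis=0)
    if how == "median":
        return beta.median(axis=0)
    if how == "most_variable":
        return beta.loc[beta.var(axis=1).idxmax()]
    raise ValueError(f"unknown aggregate {how!r}")


def fit_meth_expr(meth, expr) -> dict:
    """OLS of expression on methylation for one gene.

    Returns slope, r2 (= squared Pearson r), two-sided slope p and n.  A
    zero-variance regressor yields r2=0, p=1 with ``degenerate=True``.
    """
    meth = np.asarray(meth, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if meth.shape != expr.shape or meth.ndim != 1:
        raise ValueError("meth and expr must be paired 1-d vectors")
    n = meth.size
    if n < 4:
        raise ValueError("need >= 4 paired samples for the regression")
    if np.var(meth) == 0:
        return {"slope": 0.0, "r2": 0.0, "p": 1.0, "n": n, "degenerate": True}
    fit = stats.linregress(meth, expr)
    r2 = fit.rvalue**2
    return {"slope": fit.slope, "r2": r2, "p": fit.pvalue if np.isfinite(fit.pvalue) else 1.0,
            "n": n, "degenerate": False}


def fit_all_genes(meth: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-gene regression over genes shared by both frames.

    ``meth``: genes x samples promoter betas; ``expr``: genes x samples log2
    expression.  Samples are aligned on the intersection of columns; BH FDR
    is assigned across all genes tested here.
    """
    genes = meth.index.intersection(expr.index)
    samples = meth.columns.intersection(expr.columns)
    n = len(samples)
    if n < 4:
        raise ValueError("need >= 4 shared samples")
    if len(genes) == 0:
        raise ValueError("no shared genes between methylation and expression")
    x = meth.loc[genes, samples].to_numpy(dtype=float)
    y = expr.loc[genes, samples].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (xc**2).sum(axis=1)
    syy = (yc**2).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    degenerate = sxx == 0
    sxx_safe = np.where(degenerate, 1.0, sxx)
    slope = np.where(degenerate, 0.0, sxy / sxx_safe)
    denom = np.sqrt(sxx_safe * np.where(syy == 0, 1.0, syy))
    r = np.where(degenerate | (syy == 0), 0.0, sxy / denom)
    r2 = r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r2, 1e-300))
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(tstat), n - 2))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {"slope": slope, "r2": r2, "p": p, "fdr": bh_adjust(p), "n": n,
         "degenerate": degenerate},
        index=genes,
    )
    if degenerate.any():
        logger.info("%d gene(s) with constant promoter methylation flagged",
                    int(degenerate.sum()))
    return out


def run_fmet(
    mat: MethylationMatrix,
    ann: ProbeAnnotation,
    expr: pd.DataFrame,
    classes=PROMOTER_CLASSES,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Full fMET scan: promoter aggregation + per-gene regression + BH."""
    meth = gene_promoter_beta(mat, ann, classes=classes, aggregate=aggregate)
    skipped = expr.index.difference(meth.index)
    if len(skipped):
        logger.info("run_fmet: %d gene(s) without promoter probes skipped",
                    len(skipped))
    return fit_all_genes(meth, expr)


def select_fmet(records: pd.DataFrame, fdr_cut: float = 0.05,
                r2_min: float = 0.1) -> list[str]:
    """Genes with slope < 0, fdr < fdr_cut and r2 > r2_min (all strict).

    Deterministic ordering by (fdr, -r2, gene).
    """
    keep = records[(records["slope"] < 0) & (records["fdr"] < fdr_cut)
                   & (records["r2"] > r2_min)]
    keep = keep.sort_values(["fdr", "r2"], ascending=[True, False],
                            kind="mergesort")
    order = sorted(keep.index, key=lambda g: (keep.loc[g, "fdr"],
                                              -keep.loc[g, "r2"], str(g)))
    return list(order)
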