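"""Methylation-specific computation: scale conversions, differential calling,
promoter restriction and probe->gene summarisation.

Differential methylation is tested on the M scale (log2 beta odds, the
variance-stabilised scale appropriate for linear modeling) while the effect
size reported alongside it is the difference of group-mean beta values
(delta-beta), which is the interpretable methylation-fraction change.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import linmod
from .containers import (
    PROMOTER_CLASSES,
    MethylationMatrix,
    ProbeAnnotation,
    beta_from_m,
    m_from_beta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "beta_from_intensities",
    "m_from_beta",
    "beta_from_m",
    "call_dm_probes",
    "restrict_to_promoters",
    "probes_to_genes",
]

DM_COLUMNS = [
    "probe_id", "logFC", "t", "p", "fdr", "mean_a", "mean_b",
    "delta_beta", "direction",
]
DMG_COLUMNS = [
    "gene", "best_probe", "p", "fdr", "delta_beta", "logFC", "n_promoter_probes",
]


def beta_from_intensities(meth, unmeth, offset: float = 100.0):
    """Beta value from methylated/unmethylated intensities.

    beta = meth / (meth + unmeth + offset), clipped away from {0, 1} so that
    the M transform stays finite.  ``offset`` regularises low-intensity
    probes (the array-processing convention is 100).
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError("intensities must be non-negative")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    denom = meth + unmeth + offset
    if (denom == 0).any():
        raise ValueError("meth + unmeth + offset is zero for some probe")
    return np.clip(meth / denom, 1e-6, 1 - 1e-6)


def call_dm_probes(
    mat: MethylationMatrix,
    labels,
    p_cut: float = 0.05,
    dbeta_cut: float = 0.1,
    group_a: str = "resistant",
    group_b: str = "sensitive",
    moderate: bool = True,
) -> pd.DataFrame:
    """Differentially methylated probes between two sample groups.

    Fits the two-group model on M-values, computes delta-beta from the
    beta-scale group means, and retains probes with raw p < ``p_cut`` and
    |delta-beta| > ``dbeta_cut`` (both strict).  Retained probes are labeled
    ``hyper`` (delta-beta > 0 in group A) or ``hypo``.
    """
    if not (0 < p_cut <= 1) or not (0 <= dbeta_cut <= 1):
        raise ValueError("p_cut must be in (0,1] and dbeta_cut in [0,1]")
    res = linmod.fit_two_group(mat.M, labels, group_a, group_b, moderate=moderate)

    labels = pd.Series(labels)
    a_cols = labels.index[labels == group_a].intersection(mat.samples)
    b_cols = labels.index[labels == group_b].intersection(mat.samples)
    dbeta = mat.beta[list(a_cols)].mean(axis=1) - mat.beta[list(b_cols)].mean(axis=1)

    res = res.assign(delta_beta=dbeta)
    keep = (res["p"] < p_cut) & (res["delta_beta"].abs() > dbeta_cut)
    out = res.loc[keep].copy()
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    logger.info(
        "DM probes: %d / %d retained (p < %g, |dbeta| > %g)",
        len(out), len(res), p_cut, dbeta_cut,
    )
    return out


def restrict_to_promoters(
    dm: pd.DataFrame,
    ann: ProbeAnnotation,
    classes=PROMOTER_CLASSES,
) -> pd.DataFrame:
    """Keep probes annotated to a promoter region class for >= 1 gene.

    Probes missing from the annotation are dropped with a logged count.
    """
    annotated = dm.index.intersection(ann.probe_ids)
    n_unann = len(dm) - len(annotated)
    if n_unann:
        logger.info("restrict_to_promoters: dropped %d unannotated probe(s)", n_unann)
    promoter = ann.subset(annotated).promoter_probe_ids(classes)
    return dm.loc[dm.index.intersection(promoter)]


def probes_to_genes(
    dm: pd.DataFrame,
    ann: ProbeAnnotation,
    classes=PROMOTER_CLASSES,
) -> pd.DataFrame:
    """Summarise promoter DM probes to genes.

    A gene is differentially methylated if >= 1 of its promoter probes is in
    ``dm``; its statistics are inherited from the minimum-p probe (ties broken
    by larger |delta-beta|, then lexicographic probe id).  Probes annotated to
    several genes contribute to each of them.
    """
    pairs = ann.subset(dm.index).gene_promoter_probes(classes)
    pairs = pairs[pairs["probe_id"].isin(dm.index)]
    if pairs.empty:
        return pd.DataFrame(columns=DMG_COLUMNS[1:], index=pd.Index([], name="gene"))

    stats = dm[["p", "fdr", "delta_beta", "logFC"]].rename_axis("probe_id").reset_index()
    long = pairs.reset_index(drop=True).merge(stats, on="probe_id", how="left")
    long["abs_dbeta"] = long["delta_beta"].abs()
    long = long.sort_values(
        ["gene", "p", "abs_dbeta", "probe_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = long.groupby("gene", sort=True).first()
    counts = long.groupby("gene", sort=True).size()
    out = best.rename(columns={"probe_id": "best_probe"})[
        ["best_probe", "p", "fdr", "delta_beta", "logFC"]
    ]
    out["n_promoter_probes"] = counts
    return out
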