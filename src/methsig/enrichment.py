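"""Differential expression between clusters, over-representation analysis,
positional gene sets, and the exact multi-set intersection test.

The multi-set test generalises the two-set hypergeometric: for m fixed-size
sets drawn independently and uniformly from a background of N genes, the
distribution of the total (m-way) intersection size is computed exactly by
sequential convolution — intersecting the sets one at a time, the running
intersection size after adding a set of size n_i is hypergeometric given the
previous size.  Reported is the upper tail P(X >= observed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import linmod
from .containers import GeneSetCollection

logger = logging.getLogger(__name__)


def call_degs(
    expr: pd.DataFrame,
    clusters,
    fdr_cut: float = 0.05,
    lfc_cut: float = 0.58,
    moderate: bool = True,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Differentially expressed genes between hyper and hypo clusters.

    Retains genes with fdr < ``fdr_cut`` and |logFC| > ``lfc_cut`` (strict);
    ``down`` are the genes expressed lower in the hyper cluster (the expected
    direction for promoter-hypermethylated genes).  Returns (up, down, table).
    """
    labels = clusters.labels if hasattr(clusters, "labels") else pd.Series(clusters)
    res = linmod.fit_two_group(expr, labels, group_a="hyper", group_b="hypo",
                               moderate=moderate)
    keep = (res["fdr"] < fdr_cut) & (res["logFC"].abs() > lfc_cut)
    up = sorted(res.index[keep & (res["logFC"] > 0)])
    down = sorted(res.index[keep & (res["logFC"] < 0)])
    logger.info("DEGs: %d up, %d down (fdr < %g, |logFC| > %g)",
                len(up), len(down), fdr_cut, lfc_cut)
    return up, down, res


@dataclass
class EnrichmentResult:
    set_name: str
    k: int        # overlap
    K: int        # set size within background
    n: int        # query size
    N: int        # background size
    p: float
    fdr: float = float("nan")


def hypergeom_enrich(
    query,
    collection: GeneSetCollection,
    background,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    Sets are intersected with the background before testing; sets disjoint
    from the background are skipped with a warning.  BH FDR across the tested
    sets of this collection.
    """
    query = set(query)
    background = list(dict.fromkeys(background))
    bg = set(background)
    if not query:
        raise ValueError("empty query gene list")
    if not query <= bg:
        raise ValueError("query must be a subset of the background")
    N, n = len(bg), len(query)
    rows = []
    for set_name, members in collection:
        inset = set(members) & bg
        if not inset:
            logger.warning("set %r disjoint from background: skipped", set_name)
            continue
        K = len(inset)
        k = len(inset & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((set_name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    if len(out):
        out["fdr"] = linmod.bh_adjust(out["p"].to_numpy())
    else:
        out["fdr"] = []
    return out.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)


def positional_sets(gene_arms: pd.DataFrame, min_size: int = 10) -> GeneSetCollection:
    """One gene set per chromosome arm (named e.g. ``chr13q``).

    ``gene_arms``: frame indexed by gene with columns chrom, arm.  Arms with
    fewer than ``min_size`` genes are omitted.
    """
    sets = {}
    for (chrom, arm), sub in gene_arms.groupby(["chrom", "arm"], sort=True):
        if len(sub) >= min_size:
            name = f"chr{str(chrom).removeprefix('chr')}{arm}"
            sets[name] = sorted(sub.index)
    return GeneSetCollection(name="positional", sets=sets,
                             source="chromosome arms")


@dataclass
class MultiSetResult:
    sizes: tuple
    N: int
    x: int
    p: float
    distribution: np.ndarray  # P(X = k), k = 0..min(sizes)


def multiset_intersection_distribution(sizes, N: int) -> np.ndarray:
    """Exact pmf of the m-way intersection size of random fixed-size sets.

    Sequential convolution: X_1 = n_1 surely; given running intersection j,
    the intersection with an independent uniform set of size n_i is
    Hypergeom(N, j, n_i).
    """
    sizes = [int(s) for s in sizes]
    if any(s > N for s in sizes):
        raise ValueError("set size exceeds background size")
    if len(sizes) < 2:
        raise ValueError("need >= 2 sets")
    pmf = np.zeros(sizes[0] + 1)
    pmf[sizes[0]] = 1.0
    for n_i in sizes[1:]:
        kmax = min(len(pmf) - 1, n_i)   # running intersection cannot exceed n_i
        new = np.zeros(kmax + 1)
        ks = np.arange(kmax + 1)
        for j, pj in enumerate(pmf):
            if pj > 0:
                new += pj * stats.hypergeom.pmf(ks, N, j, n_i)
        pmf = new
    return pmf


def multiset_intersection_test(sets, background) -> MultiSetResult:
    """Exact P(X >= observed) for the total intersection of m gene lists.

    ``background`` may be a gene list or an integer universe size (an integer
    requires ``sets`` to be the observed intersection size-compatible lists).
    """
    gene_sets = [list(dict.fromkeys(s)) for s in sets]
    if isinstance(background, int):
        N = background
    else:
        bg = set(background)
        N = len(bg)
        for i, s in enumerate(gene_sets):
            if not set(s) <= bg:
                raise ValueError(f"set {i} is not a subset of the background")
    sizes = tuple(len(s) for s in gene_sets)
    if any(sz > N for sz in sizes):
        raise ValueError("set larger than the background")
    inter = set(gene_sets[0])
    for s in gene_sets[1:]:
        inter &= set(s)
    x = len(inter)
    pmf = multiset_intersection_distribution(sizes, N)
    p = float(np.clip(pmf[x:].sum(), np.finfo(float).tiny, 1.0))
    return MultiSetResult(sizes=sizes, N=N, x=x, p=p, distribution=pmf)
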