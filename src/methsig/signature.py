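"""Derivation cascade for the promoter-hypermethylation prognostic signature.

The cascade intersects differentially methylated genes (DMGs, per treatment
regimen) with functionally methylated (fMET) genes, applies regimen-specific
stringency thresholds, clusters the reference cohort on the candidate genes
(Ward linkage, Euclidean distance, M-values) into hypermethylated vs
hypomethylated samples, re-tests each candidate between the two clusters
(keeping genes with p < 0.05 and either a beta gap > 0.2 or an M-scale fold
change > 1), and finally unions the per-regimen signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import linmod
from .containers import PROMOTER_CLASSES, MethylationMatrix, ProbeAnnotation
from .fmet import gene_promoter_beta
from .containers import m_from_beta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegimenParams:
    """Stringency thresholds for one regimen's cascade step."""

    p_cut: float
    dbeta_cut: float
    r2_min: float


@dataclass(frozen=True)
class CascadeParams:
    """Full cascade parameterisation.

    Defaults: the oxaliplatin-regimen arm uses the stricter filter
    (p < 0.01, delta-beta > 0.2, R^2 > 0.5), the irinotecan-regimen arm the
    relaxed one (p < 0.05, delta-beta > 0.1, R^2 > 0.5); the cluster-refine
    step keeps genes with p < 0.05 and (delta-beta > 0.2 or M-logFC > 1).
    """

    regimens: dict = field(
        default_factory=lambda: {
            "FOLFOX": RegimenParams(0.01, 0.2, 0.5),
            "FOLFIRI": RegimenParams(0.05, 0.1, 0.5),
        }
    )
    refine_p_cut: float = 0.05
    refine_dbeta_cut: float = 0.2
    refine_logfc_cut: float = 1.0


@dataclass
class Signature:
    """Derived gene signature with per-gene provenance.

    ``provenance`` maps gene -> sorted list of regimen names whose cascade the
    gene survived; direction is hypermethylated-in-poor-prognosis throughout.
    """

    genes: list
    provenance: dict
    direction: str = "hyper-in-poor"

    def __post_init__(self) -> None:
        missing = [g for g in self.genes if g not in self.provenance]
        if missing:
            raise ValueError(f"genes without provenance: {missing}")


@dataclass
class ClusterAssignment:
    """Two-cluster sample split on the signature genes.

    ``labels``: sample -> 'hyper' / 'hypo'; the hyper cluster has the strictly
    larger mean signature beta.  ``linkage_height`` is the merge height at the
    2-cluster cut of the dendrogram.
    """

    labels: pd.Series
    linkage_height: float
    signature_mean_beta: pd.Series

    def samples(self, which: str) -> list:
        return list(self.labels.index[self.labels == which])


def cascade_select(
    dmg: pd.DataFrame,
    fmet_records: pd.DataFrame,
    params: RegimenParams,
) -> list[str]:
    """Hypermethylated DMG ∩ fMET genes passing the regimen thresholds.

    ``dmg`` is the gene-level DM table (p, delta_beta columns);
    ``fmet_records`` carries r2 per gene.  Retains genes with p < p_cut,
    delta-beta > dbeta_cut (hyper direction) and r2 > r2_min, all strict.
    """
    common = dmg.index.intersection(fmet_records.index)
    sub = dmg.loc[common]
    r2 = fmet_records.loc[common, "r2"]
    keep = (
        (sub["p"] < params.p_cut)
        & (sub["delta_beta"] > params.dbeta_cut)
        & (r2 > params.r2_min)
    )
    genes = sorted(common[keep])
    if not genes:
        logger.warning("cascade_select: no genes survive the thresholds")
    return genes


def cluster_samples(mat: MethylationMatrix, k: int = 2) -> ClusterAssignment:
    """Ward/Euclidean hierarchical clustering of samples on signature probes.

    ``mat`` must already be restricted to the signature genes' probes.
    Clustering runs on M-values; the cluster with the larger mean signature
    beta is labeled hyper.
    """
    if len(mat.probes) < 2 or len(mat.samples) < 4:
        raise ValueError("need >= 2 features and >= 4 samples to cluster")
    X = mat.M.to_numpy(dtype=float).T  # samples x features
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("all samples identical: no 2-cluster structure")
    Z = linkage(X, method="ward")
    flat = fcluster(Z, k, criterion="maxclust")
    mean_beta = mat.beta.mean(axis=0)
    cluster_means = {c: mean_beta[flat == c].mean() for c in np.unique(flat)}
    hyper_cluster = max(cluster_means, key=cluster_means.get)
    labels = pd.Series(
        np.where(flat == hyper_cluster, "hyper", "hypo"),
        index=mat.samples, name="cluster",
    )
    if labels.nunique() < 2:
        raise ValueError("degenerate clustering: a single cluster returned")
    height = float(Z[-(k - 1), 2]) if k > 1 else 0.0
    return ClusterAssignment(labels=labels, linkage_height=height,
                             signature_mean_beta=mean_beta)


def cluster_samples_on_genes(
    mat: MethylationMatrix,
    ann: ProbeAnnotation,
    genes,
    classes=PROMOTER_CLASSES,
    k: int = 2,
) -> ClusterAssignment:
    """Convenience: restrict ``mat`` to the promoter probes of ``genes``."""
    pairs = ann.gene_promoter_probes(classes)
    probes = pairs.loc[pairs["gene"].isin(list(genes)), "probe_id"].unique()
    return cluster_samples(mat.subset_probes(probes), k=k)


def refine_by_cluster(
    candidates,
    mat: MethylationMatrix,
    ann: ProbeAnnotation,
    clusters: ClusterAssignment,
    params: CascadeParams,
    moderate: bool = True,
) -> list[str]:
    """Re-test candidates between the hyper and hypo clusters.

    Gene-level promoter-mean betas are converted to M and fit hyper vs hypo;
    a gene is retained when p < refine_p_cut and either its beta gap exceeds
    refine_dbeta_cut or its M-scale logFC exceeds refine_logfc_cut, in the
    hyper-in-hyper-cluster direction (signed thresholds, not absolute).
    """
    candidates = list(candidates)
    if not candidates:
        return []
    beta_g = gene_promoter_beta(mat, ann)
    beta_g = beta_g.loc[beta_g.index.intersection(candidates)]
    m_g = pd.DataFrame(m_from_beta(beta_g.to_numpy()), index=beta_g.index,
                       columns=beta_g.columns)
    res = linmod.fit_two_group(m_g, clusters.labels, group_a="hyper",
                               group_b="hypo", moderate=moderate)
    hyper_cols = clusters.samples("hyper")
    hypo_cols = clusters.samples("hypo")
    dbeta = beta_g[hyper_cols].mean(axis=1) - beta_g[hypo_cols].mean(axis=1)
    keep = (res["p"] < params.refine_p_cut) & (
        (dbeta > params.refine_dbeta_cut) | (res["logFC"] > params.refine_logfc_cut)
    )
    return sorted(res.index[keep])


def combine_signatures(per_regimen: dict) -> Signature:
    """Union of the per-regimen refined gene lists, with provenance.

    ``per_regimen`` maps regimen name -> gene list.  |union| equals
    sum of sizes minus overlaps, by construction.
    """
    provenance: dict[str, list[str]] = {}
    for regimen, genes in per_regimen.items():
        for g in genes:
            provenance.setdefault(g, []).append(regimen)
    genes = sorted(provenance)
    if not genes:
        raise ValueError("combined signature is empty")
    return Signature(genes=genes,
                     provenance={g: sorted(v) for g, v in provenance.items()})
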