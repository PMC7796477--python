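"""CpG-island methylator phenotype (CIMP) classification and its prognostic
comparison with the hypermethylation signature clusters.

Two classifiers are provided over a configurable marker-probe panel:

* ``cluster3`` (default) — Ward/Euclidean hierarchical clustering of the
  panel M-values cut at three clusters, ranked by mean panel beta into
  CIMP-H / CIMP-L / no-CIMP.  Clustering is how CIMP subgroups were
  originally defined, so this is the default.
* ``threshold`` — a marker is called methylated at beta > 0.3; samples with
  > 60% methylated markers are CIMP-H, 20-60% CIMP-L, otherwise no-CIMP.
  The constants are documented conventions, exposed as parameters.

Neither variant claims to reproduce any specific published panel's calls;
the panel itself is an input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import ClinicalTable, MethylationMatrix
from .signature import ClusterAssignment
from .survival import logrank_test

logger = logging.getLogger(__name__)

CIMP_LEVELS = ("CIMP-H", "CIMP-L", "no-CIMP")


@dataclass
class CimpCall:
    labels: pd.Series           # sample -> CIMP-H / CIMP-L / no-CIMP / unclassified
    panel_mean_beta: pd.Series
    method: str


def classify_cimp(
    mat: MethylationMatrix,
    panel,
    method: str = "cluster3",
    beta_cut: float = 0.3,
    high_frac: float = 0.6,
    low_frac: float = 0.2,
    min_coverage: float = 0.5,
) -> CimpCall:
    """Classify samples into CIMP-H / CIMP-L / no-CIMP from a marker panel."""
    panel = list(panel)
    present = [p for p in panel if p in mat.probes]
    if len(present) < max(1, int(np.ceil(len(panel) / 2))):
        raise ValueError(
            f"only {len(present)}/{len(panel)} panel probes present (need >= half)"
        )
    sub = mat.subset_probes(present)
    coverage = sub.beta.notna().mean(axis=0)
    panel_mean = sub.beta.mean(axis=0)

    if method == "threshold":
        frac = (sub.beta > beta_cut).mean(axis=0)
        labels = pd.Series(
            np.select(
                [frac > high_frac, frac >= low_frac],
                ["CIMP-H", "CIMP-L"],
                default="no-CIMP",
            ),
            index=sub.samples,
        )
    elif method == "cluster3":
        # beta scale: Euclidean distance on M grossly overweights markers near
        # the 0/1 boundaries (the logit blows up their variance), which lets a
        # fully unmethylated stratum dominate Ward's objective; panel betas
        # are bounded and keep the three strata equidistant.
        X = sub.beta.to_numpy(dtype=float).T
        Z = linkage(X, method="ward")
        flat = fcluster(Z, 3, criterion="maxclust")
        order = sorted(np.unique(flat),
                       key=lambda c: panel_mean[flat == c].mean(), reverse=True)
        name_of = {c: lvl for c, lvl in zip(order, CIMP_LEVELS)}
        labels = pd.Series([name_of[c] for c in flat], index=sub.samples)
    else:
        raise ValueError(f"unknown CIMP method {method!r}")

    uncovered = coverage < min_coverage
    if uncovered.any():
        logger.warning("%d sample(s) below panel coverage: unclassified",
                       int(uncovered.sum()))
        labels[uncovered] = "unclassified"
    labels.name = "cimp"
    return CimpCall(labels=labels, panel_mean_beta=panel_mean, method=method)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = t.astype(int)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def cimp_cluster_table(clusters: ClusterAssignment, calls: CimpCall,
                       cimp_positive=("CIMP-H",)) -> np.ndarray:
    """2x2 table: (hyper/hypo cluster) x (CIMP-positive / not)."""
    common = clusters.labels.index.intersection(calls.labels.index)
    cl = clusters.labels.loc[common]
    cp = calls.labels.loc[common].isin(list(cimp_positive))
    return np.array(
        [
            [int(((cl == "hyper") & cp).sum()), int(((cl == "hyper") & ~cp).sum())],
            [int(((cl == "hypo") & cp).sum()), int(((cl == "hypo") & ~cp).sum())],
        ]
    )


def compare_stratifiers(
    clinical: ClinicalTable,
    clusters: ClusterAssignment,
    cimp_calls: CimpCall,
    endpoints=("os", "rfs", "efs"),
    cimp_positive=("CIMP-H",),
) -> pd.DataFrame:
    """Side-by-side log-rank p-values: signature clusters vs CIMP status.

    Both stratifications must cover every clinical sample.  CIMP is binarised
    as CIMP-positive (default CIMP-H) vs the rest for the two-group test.
    """
    samples = clinical.sample_ids
    for name, strat in (("cluster", clusters.labels), ("cimp", cimp_calls.labels)):
        missing = samples.difference(strat.index)
        if len(missing):
            raise ValueError(f"{name} stratification missing sample {missing[0]!r}")
    rows = []
    for ep in endpoints:
        times, events = clinical.endpoint(ep)
        cl = clusters.labels.loc[samples]
        lr_sig = logrank_test(times, events, cl.to_numpy())
        cimp_bin = np.where(
            cimp_calls.labels.loc[samples].isin(list(cimp_positive)),
            "cimp_pos", "cimp_neg",
        )
        if len(pd.unique(cimp_bin)) < 2:
            logger.warning("endpoint %s: CIMP stratifier has one level; p = 1", ep)
            rows.append((ep, lr_sig.p, lr_sig.chi2, 1.0, 0.0))
            continue
        lr_cimp = logrank_test(times, events, cimp_bin)
        rows.append((ep, lr_sig.p, lr_sig.chi2, lr_cimp.p, lr_cimp.chi2))
    return pd.DataFrame(
        rows,
        columns=["endpoint", "signature_p", "signature_chi2", "cimp_p", "cimp_chi2"],
    ).set_index("endpoint")
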