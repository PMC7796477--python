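"""In-memory containers for methylation-array cohort analysis.

The pipeline works on three kinds of tabular data: probe-level methylation
(beta and M scales), gene-level log2 expression, and per-sample clinical
records.  All of them are thin wrappers around :class:`pandas.DataFrame`
that enforce the invariants the downstream statistics rely on (beta values
bounded in [0, 1], unique identifiers, paired gene/region annotation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Illumina-manifest region classes counted as "promoter" for a gene.
PROMOTER_CLASSES = ("TSS1500", "TSS200", "5'UTR", "1stExon")

#: All recognised region classes.
REGION_CLASSES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")

#: Clinical survival endpoints handled by the pipeline.
ENDPOINTS = ("os", "rfs", "efs")

BETA_EPS = 1e-6  # clipping bound keeping M = log2(beta/(1-beta)) finite
BETA_TOL = 1e-9  # tolerance for the [0, 1] range check


def m_from_beta(beta):
    """M-value from beta: log2(beta / (1 - beta)), beta clipped away from {0,1}."""
    b = np.clip(np.asarray(beta, dtype=float), BETA_EPS, 1.0 - BETA_EPS)
    return np.log2(b / (1.0 - b))


def beta_from_m(m):
    """Inverse of :func:`m_from_beta`: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    # logistic on the log2 scale; stable for large |M|
    return 1.0 / (1.0 + np.exp2(-m))


@dataclass
class MethylationMatrix:
    """Probes x samples methylation values on the beta and M scales.

    Parameters
    ----------
    beta : pandas.DataFrame
        Methylation fraction per probe (rows) and sample (columns), in [0, 1].
    M : pandas.DataFrame
        log2(beta / (1 - beta)) with the same index/columns.
    scale_tag : str
        Which scale(s) were read from disk: ``"beta"``, ``"M"`` or ``"both"``.
    """

    beta: pd.DataFrame
    M: pd.DataFrame
    scale_tag: str = "both"

    def __post_init__(self) -> None:
        if self.beta.columns.duplicated().any():
            raise ValueError("duplicate sample ids in methylation matrix")
        if self.beta.index.duplicated().any():
            raise ValueError("duplicate probe ids in methylation matrix")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -BETA_TOL or finite.max() > 1 + BETA_TOL):
            bad = np.argwhere((vals < -BETA_TOL) | (vals > 1 + BETA_TOL))
            r, c = bad[0]
            raise ValueError(
                f"beta value out of [0, 1] at probe {self.beta.index[r]!r}, "
                f"sample {self.beta.columns[c]!r}: {vals[r, c]}"
            )
        if not self.M.index.equals(self.beta.index) or not self.M.columns.equals(
            self.beta.columns
        ):
            raise ValueError("beta and M matrices must share index and columns")

    @classmethod
    def from_beta(cls, beta: pd.DataFrame, scale_tag: str = "beta") -> "MethylationMatrix":
        beta = beta.astype(float)
        M = pd.DataFrame(m_from_beta(beta.to_numpy()), index=beta.index, columns=beta.columns)
        return cls(beta=beta, M=M, scale_tag=scale_tag)

    @classmethod
    def from_m(cls, M: pd.DataFrame) -> "MethylationMatrix":
        M = M.astype(float)
        beta = pd.DataFrame(beta_from_m(M.to_numpy()), index=M.index, columns=M.columns)
        return cls(beta=beta, M=M, scale_tag="M")

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        idx = self.beta.index.intersection(pd.Index(probe_ids))
        return MethylationMatrix(self.beta.loc[idx], self.M.loc[idx], self.scale_tag)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        cols = [s for s in sample_ids if s in self.beta.columns]
        return MethylationMatrix(self.beta[cols], self.M[cols], self.scale_tag)


class ProbeAnnotation:
    """Probe -> genomic position and gene/region assignment.

    Wraps a frame indexed by probe id with columns ``chrom``, ``pos`` (1-based),
    ``arm`` ('p'/'q'), ``genes`` (tuple of symbols), ``region_classes`` (tuple,
    pairwise with ``genes``) and ``relation_to_island`` (optional).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "pos", "arm", "genes", "region_classes"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"annotation frame missing columns: {sorted(missing)}")
        if frame.index.duplicated().any():
            dup = frame.index[frame.index.duplicated()][0]
            raise ValueError(f"duplicate probe id in annotation: {dup!r}")
        if (frame["pos"].astype(int) < 1).any():
            raise ValueError("annotation positions must be >= 1 (1-based)")
        for pid, row in frame.iterrows():
            if len(row["genes"]) != len(row["region_classes"]):
                raise ValueError(
                    f"probe {pid!r}: genes and region_classes differ in length"
                )
        if "relation_to_island" not in frame.columns:
            frame = frame.assign(relation_to_island=None)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index

    def subset(self, probe_ids) -> "ProbeAnnotation":
        idx = self.frame.index.intersection(pd.Index(probe_ids))
        return ProbeAnnotation(self.frame.loc[idx])

    def gene_promoter_probes(self, classes=PROMOTER_CLASSES) -> pd.DataFrame:
        """Long table (probe_id, gene) of probe->gene promoter assignments."""
        cls = set(classes)
        rows = []
        for pid, row in self.frame.iterrows():
            for gene, region in zip(row["genes"], row["region_classes"]):
                if region in cls:
                    rows.append((pid, gene))
        return pd.DataFrame(rows, columns=["probe_id", "gene"]).drop_duplicates()

    def promoter_probe_ids(self, classes=PROMOTER_CLASSES) -> pd.Index:
        """Probes annotated to a promoter class for at least one gene."""
        cls = set(classes)
        keep = [
            pid
            for pid, row in self.frame.iterrows()
            if any(region in cls for region in row["region_classes"])
        ]
        return pd.Index(keep)

    def gene_arms(self) -> pd.DataFrame:
        """Per-gene (chrom, arm) table, majority vote over the gene's probes."""
        rows = []
        for _, row in self.frame.iterrows():
            for gene in row["genes"]:
                rows.append((gene, row["chrom"], row["arm"]))
        long = pd.DataFrame(rows, columns=["gene", "chrom", "arm"])
        if long.empty:
            return pd.DataFrame(columns=["chrom", "arm"])
        return (
            long.groupby("gene")[["chrom", "arm"]]
            .agg(lambda s: s.mode().iloc[0])
            .sort_index()
        )


class ClinicalTable:
    """Per-sample clinical records: arm, regimen, survival endpoints, CIMP label."""

    GROUPS = ("resistant", "sensitive", "unknown")
    REGIMENS = ("FOLFOX", "FOLFIRI", "NA")

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        for ep in ENDPOINTS:
            tcol, ecol = f"{ep}_time", f"{ep}_event"
            if tcol in frame.columns:
                t = frame[tcol].dropna()
                if (t < 0).any():
                    raise ValueError(f"negative {ep} survival time")
                ev = frame[ecol].dropna()
                if not ev.isin([0, 1]).all():
                    raise ValueError(f"{ep} event indicator must be 0/1")
        self.frame = frame

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def endpoint(self, name: str, samples=None) -> tuple[pd.Series, pd.Series]:
        """(times, events) for an endpoint, restricted to ``samples`` if given."""
        name = name.lower()
        if name not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {name!r}; expected one of {ENDPOINTS}")
        sub = self.frame if samples is None else self.frame.loc[list(samples)]
        return sub[f"{name}_time"], sub[f"{name}_event"].astype(int)

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.frame.loc[list(sample_ids)])


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (GMT semantics)."""

    name: str
    sets: dict = field(default_factory=dict)
    source: str | None = None

    def __post_init__(self) -> None:
        cleaned = {}
        for set_name, members in self.sets.items():
            uniq = list(dict.fromkeys(members))  # dedup, keep order
            if len(uniq) < len(members):
                logger.warning(
                    "gene set %r: removed %d duplicate member(s)",
                    set_name,
                    len(members) - len(uniq),
                )
            if not uniq:
                raise ValueError(f"gene set {set_name!r} is empty")
            cleaned[set_name] = uniq
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneSetCollection)
            and self.name == other.name
            and self.sets == other.sets
        )
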