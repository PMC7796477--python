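"""Readers and writers for the on-disk artifacts.

All tables are TSV with features in rows and samples in columns (the GEO
series-matrix convention); the first column holds the feature id.  Gene sets
use standard GMT.  Probe annotation follows the Illumina manifest columns
(``UCSC_RefGene_Name`` / ``UCSC_RefGene_Group``, semicolon-separated) with a
minimal 6-column dialect also accepted.  Coordinates are 1-based; chromosome
arms come either from an ``arm`` column or from a cytoband TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ENDPOINTS,
    BETA_TOL,
    ClinicalTable,
    GeneSetCollection,
    MethylationMatrix,
    ProbeAnnotation,
    beta_from_m,
)
from .methylation import beta_from_intensities

logger = logging.getLogger(__name__)

NA_DROP_FRACTION = 0.20  # probes with more NA than this are dropped


def _read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
    return df.astype(float)


def _handle_missing(beta: pd.DataFrame) -> pd.DataFrame:
    """Drop probes with >20% NA; mean-impute the rest (logged)."""
    na_frac = beta.isna().mean(axis=1)
    drop = na_frac > NA_DROP_FRACTION
    if drop.any():
        logger.warning("dropping %d probe(s) with > %.0f%% missing betas",
                       int(drop.sum()), 100 * NA_DROP_FRACTION)
        beta = beta.loc[~drop]
    n_na = int(beta.isna().to_numpy().sum())
    if n_na:
        logger.info("imputing %d missing beta value(s) with the probe mean", n_na)
        beta = beta.apply(lambda row: row.fillna(row.mean()), axis=1)
    return beta


def read_matrix(path, scale: str = "beta") -> MethylationMatrix:
    """Read a methylation matrix TSV.

    ``scale`` is ``"beta"``, ``"M"`` or ``"intensity-pair"``.  An
    intensity-pair file carries two columns per sample, suffixed
    ``_Meth`` / ``_Unmeth``; betas are computed with the standard offset 100.
    """
    df = _read_tsv_matrix(path)
    if scale == "beta":
        vals = df.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -BETA_TOL or finite.max() > 1 + BETA_TOL):
            r, c = np.argwhere((vals < -BETA_TOL) | (vals > 1 + BETA_TOL))[0]
            raise ValueError(
                f"{path}: beta outside [0, 1] at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}: {vals[r, c]}"
            )
        beta = _handle_missing(df)
        return MethylationMatrix.from_beta(beta, scale_tag="both")
    if scale == "M":
        beta = _handle_missing(pd.DataFrame(beta_from_m(df.to_numpy()),
                                            index=df.index, columns=df.columns))
        return MethylationMatrix.from_beta(beta, scale_tag="both")
    if scale == "intensity-pair":
        meth_cols = [c for c in df.columns if c.endswith("_Meth")]
        samples = [c[: -len("_Meth")] for c in meth_cols]
        missing = [s for s in samples if f"{s}_Unmeth" not in df.columns]
        if missing or not samples:
            raise ValueError(f"{path}: incomplete Meth/Unmeth column pairs")
        beta = pd.DataFrame(
            {
                s: beta_from_intensities(df[f"{s}_Meth"], df[f"{s}_Unmeth"])
                for s in samples
            },
            index=df.index,
        )
        beta = _handle_missing(beta)
        return MethylationMatrix.from_beta(beta, scale_tag="both")
    raise ValueError(f"unknown scale {scale!r}")


def write_matrix(mat: MethylationMatrix, path, scale: str = "beta") -> None:
    df = mat.beta if scale == "beta" else mat.M
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_expression(path) -> pd.DataFrame:
    """Gene x sample log2 expression TSV."""
    return _read_tsv_matrix(path)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


# -- probe annotation ---------------------------------------------------------

ANNOTATION_COLUMNS = ["probe_id", "chrom", "pos", "arm", "genes", "region_classes",
                      "relation_to_island"]


def read_annotation(path, cytoband_path=None) -> ProbeAnnotation:
    """Probe annotation TSV (Illumina-manifest or minimal 6-column dialect).

    Recognised headers: ``probe_id``/``IlmnID``, ``chrom``/``CHR``,
    ``pos``/``MAPINFO``, ``genes``/``UCSC_RefGene_Name``,
    ``region_classes``/``UCSC_RefGene_Group``,
    ``relation_to_island``/``Relation_to_UCSC_CpG_Island`` and optionally
    ``arm``.  When ``arm`` is absent a cytoband TSV must be supplied.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    aliases = {
        "IlmnID": "probe_id", "CHR": "chrom", "MAPINFO": "pos",
        "UCSC_RefGene_Name": "genes", "UCSC_RefGene_Group": "region_classes",
        "Relation_to_UCSC_CpG_Island": "relation_to_island",
    }
    df = df.rename(columns=aliases)
    required = {"probe_id", "chrom", "pos", "genes", "region_classes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation column(s) {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    df["genes"] = df["genes"].apply(lambda s: tuple(g for g in s.split(";") if g))
    df["region_classes"] = df["region_classes"].apply(
        lambda s: tuple(g for g in s.split(";") if g)
    )
    if "relation_to_island" not in df.columns:
        df["relation_to_island"] = None
    if "arm" not in df.columns:
        if cytoband_path is None:
            raise ValueError(f"{path}: no 'arm' column and no cytoband file given")
        bands = read_cytoband(cytoband_path)
        df["arm"] = [
            arm_for_position(bands, c, p) for c, p in zip(df["chrom"], df["pos"])
        ]
    return ProbeAnnotation(df.set_index("probe_id"))


def write_annotation(ann: ProbeAnnotation, path) -> None:
    df = ann.frame.copy()
    df["genes"] = df["genes"].apply(";".join)
    df["region_classes"] = df["region_classes"].apply(";".join)
    df.reset_index(names="probe_id")[ANNOTATION_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def read_cytoband(path) -> pd.DataFrame:
    """Cytoband TSV: chrom, start, end, band.  Arm = first letter of band."""
    bands = pd.read_csv(path, sep="\t",
                        names=["chrom", "start", "end", "band"], dtype=str,
                        comment="#")
    bands["start"] = bands["start"].astype(int)
    bands["end"] = bands["end"].astype(int)
    bands["arm"] = bands["band"].str[0]
    return bands


def arm_for_position(bands: pd.DataFrame, chrom: str, pos: int) -> str:
    hit = bands[(bands["chrom"] == chrom) & (bands["start"] < pos)
                & (bands["end"] >= pos)]
    if hit.empty:
        raise ValueError(f"no cytoband covers {chrom}:{pos}")
    return hit["arm"].iloc[0]


def harmonize_annotation(a: ProbeAnnotation, b: ProbeAnnotation) -> ProbeAnnotation:
    """Intersect two annotation sets on probe id, keeping b's annotation.

    Used to reduce a larger platform to the probes of a reference platform so
    cross-cohort comparisons are over the same features.
    """
    common = a.probe_ids.intersection(b.probe_ids)
    if len(common) == 0:
        raise ValueError("annotation sets share no probes")
    logger.info("harmonize_annotation: %d common probe(s)", len(common))
    return b.subset(common)


# -- clinical -----------------------------------------------------------------

def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id",
                     keep_default_na=False, na_values=[""],
                     float_precision="round_trip")
    for ep in ENDPOINTS:
        if f"{ep}_time" in df.columns:
            df[f"{ep}_time"] = df[f"{ep}_time"].astype(float)
            df[f"{ep}_event"] = df[f"{ep}_event"].astype(int)
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.frame.to_csv(path, sep="\t", index_label="sample_id")


# -- gene sets (GMT) ----------------------------------------------------------

def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Standard GMT: tab-separated set_name, description, members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            sets[fields[0]] = fields[2:]
    return GeneSetCollection(name=name or Path(path).stem, sets=sets,
                             source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_name, members in collection:
            fh.write("\t".join([set_name, collection.source or "na", *members]) + "\n")
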