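"""End-to-end orchestration of the signature derivation cascade.

Two entry points: :func:`derive_signature_from_cohort` works on in-memory
containers (the library path used by the tests and the simulation studies);
:func:`run_pipeline` drives the same stages file-to-file from a YAML config
(the CLI path), writing every intermediate table plus a manifest of input
hashes so a rerun with identical inputs is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io_formats, methylation
from .cimp import classify_cimp, cimp_cluster_table, compare_stratifiers, fisher_exact_2x2
from .containers import ENDPOINTS, ClinicalTable, MethylationMatrix, ProbeAnnotation
from .enrichment import call_degs, hypergeom_enrich, multiset_intersection_test
from .fmet import run_fmet, select_fmet
from .signature import (
    CascadeParams,
    ClusterAssignment,
    Signature,
    cascade_select,
    cluster_samples_on_genes,
    combine_signatures,
    refine_by_cluster,
)
from .survival import km_by_group, logrank_test

logger = logging.getLogger(__name__)

#: probe-level pre-filter applied before the regimen cascades
DM_BASE_P_CUT = 0.05
DM_BASE_DBETA_CUT = 0.1


@dataclass
class SignatureRun:
    """All artifacts of one cascade run."""

    dmg: dict                           # regimen -> gene-level DM table
    fmet_table: pd.DataFrame
    fmet_genes: list
    candidates: dict                    # regimen -> cascade survivors
    refined: dict                       # regimen -> refined gene list
    signature: Signature
    clusters: ClusterAssignment         # reference cohort, final signature
    survival: pd.DataFrame = field(default_factory=pd.DataFrame)


def derive_signature_from_cohort(
    mat: MethylationMatrix,
    expr: pd.DataFrame,
    ann: ProbeAnnotation,
    clinical: ClinicalTable,
    params: CascadeParams | None = None,
    moderate: bool = True,
) -> SignatureRun:
    """Run the full derivation cascade on one cohort bundle.

    Regimen datasets are the samples whose clinical ``regimen`` is not
    ``"NA"`` (resistant vs sensitive contrast); the reference cohort is the
    set of samples present in the expression matrix.
    """
    params = params or CascadeParams()
    clin = clinical.frame

    # fMET scan on the reference cohort
    ref_samples = [s for s in expr.columns if s in mat.samples]
    ref_mat = mat.subset_samples(ref_samples)
    fmet_table = run_fmet(ref_mat, ann, expr)
    fmet_genes = select_fmet(fmet_table)
    logger.info("fMET genes: %d", len(fmet_genes))
    fmet_records = fmet_table.loc[fmet_genes]

    dmg: dict[str, pd.DataFrame] = {}
    candidates: dict[str, list] = {}
    refined: dict[str, list] = {}
    for regimen in sorted(r for r in clin["regimen"].unique() if r != "NA"):
        reg_samples = clin.index[clin["regimen"] == regimen]
        reg_mat = mat.subset_samples(reg_samples)
        labels = clin.loc[reg_samples, "group"]
        dm = methylation.call_dm_probes(
            reg_mat, labels, p_cut=DM_BASE_P_CUT, dbeta_cut=DM_BASE_DBETA_CUT,
            moderate=moderate,
        )
        dm = methylation.restrict_to_promoters(dm, ann)
        dmg[regimen] = methylation.probes_to_genes(dm, ann)
        reg_params = params.regimens.get(regimen)
        if reg_params is None:
            raise KeyError(f"no cascade parameters for regimen {regimen!r}")
        cand = cascade_select(dmg[regimen], fmet_records, reg_params)
        candidates[regimen] = cand
        if len(cand) >= 2:
            cl = cluster_samples_on_genes(ref_mat, ann, cand)
            refined[regimen] = refine_by_cluster(
                cand, ref_mat, ann, cl, params, moderate=moderate
            )
        else:
            logger.warning(
                "regimen %s: %d candidate(s); refine step skipped", regimen, len(cand)
            )
            refined[regimen] = list(cand)

    sig = combine_signatures(refined)
    clusters = cluster_samples_on_genes(ref_mat, ann, sig.genes)

    times_events = []
    for ep in ENDPOINTS:
        if f"{ep}_time" not in clin.columns:
            continue
        times, events = clinical.endpoint(ep, samples=clusters.labels.index)
        lr = logrank_test(times.to_numpy(), events.to_numpy(),
                          clusters.labels.to_numpy())
        times_events.append((ep, lr.chi2, lr.p))
    surv = pd.DataFrame(times_events, columns=["endpoint", "chi2", "p"]).set_index(
        "endpoint"
    )
    return SignatureRun(
        dmg=dmg, fmet_table=fmet_table, fmet_genes=fmet_genes,
        candidates=candidates, refined=refined, signature=sig,
        clusters=clusters, survival=surv,
    )


# -- file-based pipeline ------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """File-to-file pipeline: dm -> fmet -> derive -> survival -> enrich -> cimp.

    ``config`` keys: ``methylation`` (beta TSV), ``annotation`` (TSV),
    ``clinical`` (TSV), optional ``expression`` (TSV), optional ``gene_sets``
    (GMT), optional ``cimp_panel`` (text file, one probe per line), optional
    ``cascade`` overrides.  Stages needing expression are skipped with an
    explicit notice when it is absent.  Returns the manifest (also written as
    ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"inputs": {}, "outputs": {}, "skipped": []}
    for key in ("methylation", "annotation", "clinical", "expression",
                "gene_sets", "cimp_panel"):
        if key in config and config[key]:
            p = Path(config[key])
            if not p.exists():
                raise FileNotFoundError(f"{key} input not found: {p}")
            manifest["inputs"][key] = _sha256(p)

    mat = io_formats.read_matrix(config["methylation"], scale="beta")
    ann = io_formats.read_annotation(config["annotation"],
                                     config.get("cytoband"))
    clinical = io_formats.read_clinical(config["clinical"])

    params = CascadeParams()
    if "cascade" in config:
        from .signature import RegimenParams
        c = config["cascade"]
        regs = {
            name: RegimenParams(**vals) for name, vals in c.get("regimens", {}).items()
        } or params.regimens
        params = CascadeParams(
            regimens=regs,
            refine_p_cut=c.get("refine_p_cut", params.refine_p_cut),
            refine_dbeta_cut=c.get("refine_dbeta_cut", params.refine_dbeta_cut),
            refine_logfc_cut=c.get("refine_logfc_cut", params.refine_logfc_cut),
        )

    expr = None
    if config.get("expression"):
        expr = io_formats.read_expression(config["expression"])
    else:
        notice = "no expression matrix: fmet, derive, enrich stages skipped"
        logger.warning(notice)
        manifest["skipped"] += ["fmet", "derive", "enrich"]

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    # methylation-only stage: per-regimen DM tables
    clin = clinical.frame
    for regimen in sorted(r for r in clin["regimen"].unique() if r != "NA"):
        reg_samples = clin.index[clin["regimen"] == regimen]
        dm = methylation.call_dm_probes(
            mat.subset_samples(reg_samples), clin.loc[reg_samples, "group"],
            p_cut=DM_BASE_P_CUT, dbeta_cut=DM_BASE_DBETA_CUT,
        )
        dm = methylation.restrict_to_promoters(dm, ann)
        dmg = methylation.probes_to_genes(dm, ann)
        _write(f"dm_probes_{regimen}.tsv",
               lambda p, d=dm: d.reset_index(names="probe_id").to_csv(p, sep="\t", index=False))
        _write(f"dm_genes_{regimen}.tsv",
               lambda p, d=dmg: d.reset_index().to_csv(p, sep="\t", index=False))

    if expr is not None:
        run = derive_signature_from_cohort(mat, expr, ann, clinical, params)
        _write("fmet.tsv",
               lambda p: run.fmet_table.reset_index(names="gene").to_csv(p, sep="\t", index=False))
        _write("signature.tsv", lambda p: pd.DataFrame(
            {"gene": run.signature.genes,
             "provenance": [",".join(run.signature.provenance[g])
                            for g in run.signature.genes]}
        ).to_csv(p, sep="\t", index=False))
        _write("clusters.tsv",
               lambda p: run.clusters.labels.to_frame().to_csv(p, sep="\t", index_label="sample_id"))
        _write("provenance.json", lambda p: Path(p).write_text(
            json.dumps({"signature": run.signature.genes,
                        "provenance": run.signature.provenance,
                        "candidates": run.candidates,
                        "refined": run.refined}, indent=2)))
        _write("survival_logrank.tsv",
               lambda p: run.survival.to_csv(p, sep="\t"))
        for ep in ENDPOINTS:
            if f"{ep}_time" not in clin.columns:
                continue
            times, events = clinical.endpoint(ep, samples=run.clusters.labels.index)
            curves = km_by_group(times.to_numpy(), events.to_numpy(),
                                 run.clusters.labels.to_numpy())
            for grp, curve in curves.items():
                _write(f"km_{ep}_{grp}.tsv", lambda p, c=curve: pd.DataFrame(
                    {"time": c.times, "survival": c.survival,
                     "at_risk": c.at_risk, "events": c.events}
                ).to_csv(p, sep="\t", index=False))

        up, down, deg_table = call_degs(expr, run.clusters)
        _write("degs.tsv",
               lambda p: deg_table.reset_index(names="gene").to_csv(p, sep="\t", index=False))
        if config.get("gene_sets"):
            sets = io_formats.read_gmt(config["gene_sets"])
            background = list(expr.index)
            query = sorted(set(up) | set(down))
            if query:
                enr = hypergeom_enrich(query, sets, background)
                _write("enrichment.tsv", lambda p: enr.to_csv(p, sep="\t", index=False))

        if config.get("cimp_panel"):
            panel = [ln.strip() for ln in Path(config["cimp_panel"]).read_text().splitlines()
                     if ln.strip()]
            calls = classify_cimp(mat.subset_samples(run.clusters.labels.index), panel)
            _write("cimp_calls.tsv",
                   lambda p: calls.labels.to_frame().to_csv(p, sep="\t", index_label="sample_id"))
            table = cimp_cluster_table(run.clusters, calls)
            report = compare_stratifiers(
                clinical.subset(run.clusters.labels.index), run.clusters, calls
            )
            report["cimp_fisher_p"] = fisher_exact_2x2(table)
            _write("cimp_comparison.tsv", lambda p: report.to_csv(p, sep="\t"))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
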