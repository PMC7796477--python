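"""Seeded generator of complete synthetic cohorts with known planted truth.

The generator emulates the statistical structure the derivation cascade
assumes: two treatment-regimen case/control datasets (drug-resistant vs
drug-sensitive arms) profiled for methylation only, plus a reference cohort
with paired methylation and expression that splits into hypermethylated and
hypomethylated clusters.  Planted functionally methylated genes carry
promoter betas elevated by ``cluster_delta_beta`` in the hyper cluster (and,
for signature genes, in the resistant arm of their regimen) and expression
coupled to the realised promoter beta with a negative slope.  Null genes
have methylation and expression independent.  Survival is exponential with
the hazard multiplied by ``hazard_ratio`` in poor-prognosis samples
(resistant / hyper-cluster), with independent exponential censoring tuned to
the requested censoring fraction; the memoryless model keeps the planted
hazard ratio available in closed form for verification.

A single integer seed drives one master :class:`numpy.random.SeedSequence`;
per-block child streams (structure, methylation, expression, clinical, gene
sets) are derived deterministically so blocks can be regenerated
independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    ClinicalTable,
    GeneSetCollection,
    MethylationMatrix,
    ProbeAnnotation,
)

logger = logging.getLogger(__name__)

_ENDPOINT_MEDIANS = {"os": 24.0, "rfs": 18.0, "efs": 15.0}  # months


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Arm sizes default to the study design the pipeline targets: 16 resistant
    + 4 sensitive oxaliplatin-regimen tumors, 8 + 8 irinotecan-regimen
    tumors, and a 33-sample reference cohort splitting 22 hypo / 11 hyper.
    """

    n_resistant: dict = field(default_factory=lambda: {"FOLFOX": 16, "FOLFIRI": 8})
    n_sensitive: dict = field(default_factory=lambda: {"FOLFOX": 4, "FOLFIRI": 8})
    n_reference_hypo: int = 22
    n_reference_hyper: int = 11
    reference_is_inhouse: bool = False  # tiny fixtures: cluster = arm

    n_genes: int = 300
    n_probes: int = 700                 # total incl. promoter, panel, body filler
    promoter_probes_per_gene: int = 2
    cimp_panel_size: int = 10

    n_fmet_true: int = 8
    #: planted signature genes per regimen, in sorted-regimen order:
    #: (first-regimen only, second-regimen only, shared by both)
    sig_counts: tuple = (3, 4, 1)

    beta_baseline: float = 0.30         # null-probe mean beta
    silenced_beta_low: float = 0.20     # planted genes, hypo/sensitive samples
    cluster_delta_beta: float = 0.40    # hyper - hypo promoter beta gap
    beta_noise_sd: float = 0.05
    beta_mode: str = "truncnorm"        # or "betadist"

    expr_baseline_range: tuple = (6.0, 10.0)  # log2 units
    fmet_slope: float = -4.0            # log2 expression per unit beta
    expr_noise_sd: float = 0.30

    hazard_ratio: float = 3.0           # poor vs good prognosis
    censoring_rate: float = 0.30
    cimp_strata_means: tuple = (0.7, 0.4, 0.1)   # CIMP-H / CIMP-L / no-CIMP
    cimp_strata_probs: tuple = (0.15, 0.25, 0.60)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.promoter_probes_per_gene < 1:
            raise ValueError("n_genes and promoter_probes_per_gene must be >= 1")
        n_promoter = self.n_genes * self.promoter_probes_per_gene
        if self.n_probes < n_promoter + self.cimp_panel_size:
            raise ValueError(
                "n_probes too small: need >= n_genes * promoter_probes_per_gene"
                " + cimp_panel_size"
            )
        if sum(self.sig_counts) > self.n_fmet_true:
            raise ValueError("planted signature must be a subset of planted fMET genes")
        hi = self.silenced_beta_low + self.cluster_delta_beta
        for name, v in [
            ("beta_baseline", self.beta_baseline),
            ("silenced_beta_low", self.silenced_beta_low),
            ("silenced_beta_low + cluster_delta_beta", hi),
            *[(f"cimp_strata_means[{i}]", m) for i, m in enumerate(self.cimp_strata_means)],
        ]:
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} = {v} leaves the valid beta range (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth planted by :func:`generate_cohort`."""

    fmet_genes: list
    signature_genes: list
    regimen_genes: dict                 # regimen -> planted gene list
    reference_clusters: pd.Series      # reference sample -> hyper/hypo
    poor_samples: list                 # samples whose hazard is multiplied
    cimp_strata: pd.Series             # sample -> CIMP-H/CIMP-L/no-CIMP
    effect_sizes: pd.Series            # planted gene -> delta beta


def _draw_beta(rng, mean, sd, mode):
    mean = np.asarray(mean, dtype=float)
    if mode == "truncnorm":
        vals = rng.normal(mean, sd)
        return np.clip(vals, 1e-4, 1 - 1e-4)
    if mode == "betadist":
        var = min(sd**2, 0.9 * float((mean * (1 - mean)).min()))
        k = mean * (1 - mean) / var - 1
        return rng.beta(np.maximum(mean * k, 1e-3), np.maximum((1 - mean) * k, 1e-3))
    raise ValueError(f"unknown beta_mode {mode!r}")


def generate_cohort(cfg: SimConfig):
    """Generate one complete cohort bundle.

    Returns ``(MethylationMatrix, expression DataFrame, ProbeAnnotation,
    ClinicalTable, GeneSetCollection, TruthRecord)``, fully reproducible from
    ``cfg.seed``.
    """
    master = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_meth, rng_expr, rng_clin, rng_sets = (
        np.random.default_rng(s) for s in master.spawn(5)
    )

    regimens = sorted(set(cfg.n_resistant) | set(cfg.n_sensitive))
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]

    # ---- planted truth ------------------------------------------------------
    fmet_idx = rng_struct.choice(cfg.n_genes, size=cfg.n_fmet_true, replace=False)
    fmet_genes = sorted(genes[i] for i in fmet_idx)
    n_a, n_b, n_shared = cfg.sig_counts
    sig_genes = fmet_genes[: n_a + n_b + n_shared]
    reg_a = regimens[0] if regimens else "FOLFOX"
    reg_b = regimens[1] if len(regimens) > 1 else reg_a
    regimen_genes = {
        reg_a: sorted(sig_genes[:n_a] + sig_genes[n_a + n_b:]),
        reg_b: sorted(sig_genes[n_a:n_a + n_b] + sig_genes[n_a + n_b:]),
    }
    if reg_a == reg_b:
        regimen_genes = {reg_a: sorted(set(sig_genes))}

    # ---- samples ------------------------------------------------------------
    sample_rows = []  # (sample, group, regimen, poor, has_expression)
    for r in regimens:
        for i in range(cfg.n_resistant.get(r, 0)):
            sample_rows.append((f"{r}_R{i + 1:02d}", "resistant", r, True))
        for i in range(cfg.n_sensitive.get(r, 0)):
            sample_rows.append((f"{r}_S{i + 1:02d}", "sensitive", r, False))
    inhouse = [s[0] for s in sample_rows]

    if cfg.reference_is_inhouse:
        ref_samples = list(inhouse)
        hyper_set = {s for s, g, _, _ in sample_rows if g == "resistant"}
    else:
        n_ref = cfg.n_reference_hypo + cfg.n_reference_hyper
        ref_samples = [f"REF{i + 1:02d}" for i in range(n_ref)]
        hyper_pick = rng_struct.choice(n_ref, size=cfg.n_reference_hyper, replace=False)
        hyper_set = {ref_samples[i] for i in hyper_pick}
        for s in ref_samples:
            sample_rows.append((s, "unknown", "NA", s in hyper_set))
    all_samples = [s[0] for s in sample_rows]
    poor = {s: p for s, _, _, p in sample_rows}
    ref_clusters = pd.Series(
        {s: ("hyper" if s in hyper_set else "hypo") for s in ref_samples},
        name="cluster",
    ).sort_index()

    # ---- probes and annotation ---------------------------------------------
    n_promoter = cfg.n_genes * cfg.promoter_probes_per_gene
    n_body = cfg.n_probes - n_promoter - cfg.cimp_panel_size
    probe_ids = [f"cg{i + 1:08d}" for i in range(cfg.n_probes)]
    promoter_probes = probe_ids[:n_promoter]
    panel_probes = probe_ids[n_promoter:n_promoter + cfg.cimp_panel_size]
    body_probes = probe_ids[n_promoter + cfg.cimp_panel_size:]

    gene_chrom = rng_struct.integers(1, 23, size=cfg.n_genes).astype(str)
    gene_arm = rng_struct.choice(["p", "q"], size=cfg.n_genes)
    promoter_regions = ["TSS200", "TSS1500", "5'UTR", "1stExon"]
    ann_rows = []
    for gi, gene in enumerate(genes):
        for j in range(cfg.promoter_probes_per_gene):
            pid = promoter_probes[gi * cfg.promoter_probes_per_gene + j]
            ann_rows.append(
                (pid, gene_chrom[gi], 1_000_000 * (gi + 1) + 50 * j, gene_arm[gi],
                 (gene,), (promoter_regions[j % len(promoter_regions)],), "Island")
            )
    body_gene_idx = rng_struct.integers(0, cfg.n_genes, size=n_body)
    for k, gi in enumerate(body_gene_idx):
        ann_rows.append(
            (body_probes[k], gene_chrom[gi], 1_000_000 * (gi + 1) + 5_000 + k,
             gene_arm[gi], (genes[gi],), ("Body",), "OpenSea")
        )
    for k, pid in enumerate(panel_probes):
        ann_rows.append((pid, "1", 500 + k, "p", (), (), "Island"))
    ann = ProbeAnnotation(
        pd.DataFrame(
            ann_rows,
            columns=["probe_id", "chrom", "pos", "arm", "genes",
                     "region_classes", "relation_to_island"],
        ).set_index("probe_id")
    )

    # ---- CIMP strata --------------------------------------------------------
    strata_labels = ("CIMP-H", "CIMP-L", "no-CIMP")
    strata = rng_clin.choice(3, size=len(all_samples), p=cfg.cimp_strata_probs)
    cimp_strata = pd.Series([strata_labels[i] for i in strata], index=all_samples,
                            name="cimp")

    # ---- methylation means --------------------------------------------------
    mean = np.full((cfg.n_probes, len(all_samples)), cfg.beta_baseline)
    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    col = {s: j for j, s in enumerate(all_samples)}
    low, hi = cfg.silenced_beta_low, cfg.silenced_beta_low + cfg.cluster_delta_beta

    planted_high: dict[str, set] = {}  # gene -> samples with elevated promoter
    for gene in fmet_genes:
        high = {s for s in ref_samples if s in hyper_set}
        in_regimens = [r for r, gl in regimen_genes.items() if gene in gl]
        if not cfg.reference_is_inhouse:
            for s, grp, r, _ in sample_rows:
                if r in in_regimens and grp == "resistant":
                    high.add(s)
        planted_high[gene] = high
        gi = genes.index(gene)
        rows = [probe_pos[promoter_probes[gi * cfg.promoter_probes_per_gene + j]]
                for j in range(cfg.promoter_probes_per_gene)]
        for s in all_samples:
            is_ref = s in ref_clusters.index
            if is_ref or in_regimens or cfg.reference_is_inhouse:
                mean[np.ix_(rows, [col[s]])] = hi if s in high else low
    for k, pid in enumerate(panel_probes):
        r = probe_pos[pid]
        for s in all_samples:
            mean[r, col[s]] = cfg.cimp_strata_means[
                strata_labels.index(cimp_strata[s])
            ]

    beta = _draw_beta(rng_meth, mean, cfg.beta_noise_sd, cfg.beta_mode)
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=all_samples)
    mat = MethylationMatrix.from_beta(beta_df, scale_tag="both")

    # ---- expression (reference samples) ------------------------------------
    baseline = rng_expr.uniform(*cfg.expr_baseline_range, size=cfg.n_genes)
    expr = np.tile(baseline[:, None], (1, len(ref_samples)))
    ref_cols = [col[s] for s in ref_samples]
    for gene in fmet_genes:
        gi = genes.index(gene)
        rows = [probe_pos[promoter_probes[gi * cfg.promoter_probes_per_gene + j]]
                for j in range(cfg.promoter_probes_per_gene)]
        prom_beta = beta[np.ix_(rows, ref_cols)].mean(axis=0)
        expr[gi] = baseline[gi] + cfg.fmet_slope * prom_beta
    expr += rng_expr.normal(0.0, cfg.expr_noise_sd, size=expr.shape)
    expr_df = pd.DataFrame(expr, index=genes, columns=ref_samples)

    # ---- clinical -----------------------------------------------------------
    clin = pd.DataFrame(
        {
            "group": [g for _, g, _, _ in sample_rows],
            "regimen": [r for _, _, r, _ in sample_rows],
        },
        index=pd.Index(all_samples, name="sample_id"),
    )
    hr = np.array([cfg.hazard_ratio if poor[s] else 1.0 for s in all_samples])
    for ep, median in _ENDPOINT_MEDIANS.items():
        lam = (np.log(2) / median) * hr
        t_event = rng_clin.exponential(1.0 / lam)
        if cfg.censoring_rate > 0:
            mu = lam.mean() * cfg.censoring_rate / (1 - cfg.censoring_rate)
            t_cens = rng_clin.exponential(1.0 / mu, size=len(all_samples))
        else:
            t_cens = np.full(len(all_samples), np.inf)
        clin[f"{ep}_time"] = np.minimum(t_event, t_cens)
        clin[f"{ep}_event"] = (t_event <= t_cens).astype(int)
    clin["cimp_label"] = cimp_strata
    clinical = ClinicalTable(clin)

    # ---- gene sets ----------------------------------------------------------
    others = [g for g in genes if g not in fmet_genes]
    planted_set = sorted(
        fmet_genes + list(rng_sets.choice(others, size=min(5, len(others)),
                                          replace=False))
    )
    sets = {"PLANTED_SILENCED": planted_set}
    for i in range(5):
        size = min(20, cfg.n_genes)
        sets[f"RANDOM_{i + 1}"] = sorted(
            rng_sets.choice(genes, size=size, replace=False)
        )
    collection = GeneSetCollection(name="synthetic_sets", sets=sets,
                                   source="synthetic")

    truth = TruthRecord(
        fmet_genes=fmet_genes,
        signature_genes=sorted(sig_genes),
        regimen_genes=regimen_genes,
        reference_clusters=ref_clusters,
        poor_samples=sorted(s for s in all_samples if poor[s]),
        cimp_strata=cimp_strata,
        effect_sizes=pd.Series(
            {g: cfg.cluster_delta_beta for g in fmet_genes}, name="delta_beta"
        ),
    )
    return mat, expr_df, ann, clinical, collection, truth


def generate_worked_fixture(seed: int = 42):
    """Tiny deterministic cohort (12 samples, 30 probes) for worked examples.

    One regimen of 6 resistant + 6 sensitive samples which double as the
    expression-bearing reference cohort (resistant = hyper cluster); 10 genes
    with 2 promoter probes each, 3 of them planted silenced signature genes.
    Low noise keeps every stage hand-checkable.
    """
    cfg = SimConfig(
        n_resistant={"FOLFOX": 6},
        n_sensitive={"FOLFOX": 6},
        reference_is_inhouse=True,
        n_genes=10,
        n_probes=30,
        promoter_probes_per_gene=2,
        cimp_panel_size=5,
        n_fmet_true=3,
        sig_counts=(3, 0, 0),
        beta_noise_sd=0.02,
        expr_noise_sd=0.15,
        censoring_rate=0.25,
        seed=seed,
    )
    return (*generate_cohort(cfg), cfg)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A no-signal configuration: HR = 1 and no cluster beta gap."""
    return replace(
        SimConfig(seed=seed), hazard_ratio=1.0, cluster_delta_beta=1e-6,
        silenced_beta_low=0.3, fmet_slope=0.0, **overrides
    )
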