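"""Cascade selection, Ward clustering, refinement and signature combination."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from methsig import signature as sig
from methsig.containers import MethylationMatrix, m_from_beta
from methsig.pipeline import derive_signature_from_cohort
from methsig.simulate import SimConfig, generate_cohort

from conftest import make_matrix

FOLFOX = sig.RegimenParams(0.01, 0.2, 0.5)


def _dmg(rows):
    return pd.DataFrame(rows).set_index("gene")


def _fmet(rows):
    return pd.DataFrame(rows).set_index("gene")


class TestCascadeSelect:
    def test_all_criteria_met(self):
        dmg = _dmg([{"gene": "G", "p": 0.005, "delta_beta": 0.25}])
        rec = _fmet([{"gene": "G", "r2": 0.6}])
        assert sig.cascade_select(dmg, rec, FOLFOX) == ["G"]

    def test_hypomethylated_gene_excluded(self):
        dmg = _dmg([{"gene": "G", "p": 0.005, "delta_beta": -0.25}])
        rec = _fmet([{"gene": "G", "r2": 0.6}])
        assert sig.cascade_select(dmg, rec, FOLFOX) == []

    def test_exhaustive_planted_survivors(self, rng):
        # 50 genes; plant 8 that satisfy all three strict thresholds
        genes = [f"G{i:02d}" for i in range(50)]
        survivors = sorted(rng.choice(genes, size=8, replace=False))
        rows, recs = [], []
        for g in genes:
            win = g in survivors
            rows.append({
                "gene": g,
                "p": rng.uniform(0.0001, 0.009) if win else rng.uniform(0.02, 1.0),
                "delta_beta": rng.uniform(0.25, 0.4) if win else rng.uniform(-0.15, 0.15),
            })
            recs.append({"gene": g,
                         "r2": rng.uniform(0.55, 0.9) if win else rng.uniform(0, 0.45)})
        assert sig.cascade_select(_dmg(rows), _fmet(recs), FOLFOX) == survivors

    def test_empty_result_is_valid(self):
        dmg = _dmg([{"gene": "G", "p": 0.5, "delta_beta": 0.0}])
        rec = _fmet([{"gene": "G", "r2": 0.0}])
        assert sig.cascade_select(dmg, rec, FOLFOX) == []


def _blob_matrix(rng, n_hyper=10, n_hypo=10, n_probes=6,
                 beta_hyper=0.8, beta_hypo=0.2, sd_m=0.3):
    m_hyper = m_from_beta(beta_hyper)
    m_hypo = m_from_beta(beta_hypo)
    M = np.concatenate(
        [rng.normal(m_hyper, sd_m, size=(n_probes, n_hyper)),
         rng.normal(m_hypo, sd_m, size=(n_probes, n_hypo))], axis=1,
    )
    samples = [f"H{i}" for i in range(n_hyper)] + [f"L{i}" for i in range(n_hypo)]
    return MethylationMatrix.from_m(
        pd.DataFrame(M, index=[f"cg{i}" for i in range(n_probes)], columns=samples)
    )


class TestClusterSamples:
    def test_separated_blobs_perfect_split(self, rng):
        mat = _blob_matrix(rng)
        out = sig.cluster_samples(mat)
        assert set(out.samples("hyper")) == {f"H{i}" for i in range(10)}
        assert set(out.samples("hypo")) == {f"L{i}" for i in range(10)}

    def test_high_beta_blob_labeled_hyper(self, rng):
        mat = _blob_matrix(rng, beta_hyper=0.8, beta_hypo=0.2)
        out = sig.cluster_samples(mat)
        hyper_mean = out.signature_mean_beta[out.samples("hyper")].mean()
        hypo_mean = out.signature_mean_beta[out.samples("hypo")].mean()
        assert hyper_mean > hypo_mean

    def test_invariant_to_sample_and_probe_order(self, rng):
        mat = _blob_matrix(rng)
        out = sig.cluster_samples(mat)
        perm_s = list(rng.permutation(mat.samples))
        perm_p = list(rng.permutation(mat.probes))
        shuffled = MethylationMatrix(mat.beta.loc[perm_p, perm_s],
                                     mat.M.loc[perm_p, perm_s])
        out2 = sig.cluster_samples(shuffled)
        pd.testing.assert_series_equal(
            out.labels.sort_index(), out2.labels.sort_index(), check_names=False
        )

    def test_identical_samples_error(self):
        mat = make_matrix(np.full((3, 6), 0.5))
        with pytest.raises(ValueError, match="identical"):
            sig.cluster_samples(mat)

    def test_matches_exhaustive_minimum_wss_bipartition(self):
        """Ward's 2-cut equals the optimal 2-partition on clustered data."""
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            n_hyper = int(rng.integers(1, n))
            mat = _blob_matrix(rng, n_hyper=n_hyper, n_hypo=n - n_hyper,
                               n_probes=int(rng.integers(3, 8)))
            out = sig.cluster_samples(mat)
            X = mat.M.to_numpy().T
            got = _wss(X, [mat.samples.get_loc(s) for s in out.samples("hyper")])
            best = min(
                _wss(X, idx)
                for k in range(1, n // 2 + 1)
                for idx in combinations(range(n), k)
            )
            assert got == pytest.approx(best, rel=1e-9)


def _wss(X, idx):
    idx = list(idx)
    rest = [i for i in range(len(X)) if i not in idx]
    a, b = X[idx], X[rest]
    out = ((a - a.mean(0)) ** 2).sum() if len(a) else 0.0
    out += ((b - b.mean(0)) ** 2).sum() if len(b) else 0.0
    return out


class TestRefineByCluster:
    @pytest.mark.parametrize(
        "dbeta,logfc_scale,expected",
        [
            (0.25, None, True),    # delta-beta arm of the OR
            (0.12, 3.0, True),     # logFC arm (M gap > 1)
            (0.05, None, False),   # neither arm
        ],
    )
    def test_or_rule(self, rng, dbeta, logfc_scale, expected):
        # build a 2-cluster cohort where gene G's promoter beta gap is dbeta
        from methsig.containers import ProbeAnnotation
        n = 12
        samples = [f"S{j}" for j in range(n)]
        base = 0.3
        hyper = samples[:6]
        beta = np.clip(rng.normal(base, 0.015, size=(4, n)), 0.01, 0.99)
        # gene G probes 0-1; make the hyper cluster higher by dbeta
        beta[0:2, :6] = np.clip(rng.normal(base + dbeta, 0.015, (2, 6)), 0.01, 0.99)
        if logfc_scale is not None:
            # exaggerate on M scale via low baseline: beta .07 -> .12+dbeta
            beta[0:2, 6:] = np.clip(rng.normal(0.07, 0.005, (2, 6)), 0.01, 0.99)
            beta[0:2, :6] = np.clip(rng.normal(0.07 + dbeta, 0.005, (2, 6)), 0.01, 0.99)
        mat = make_matrix(beta, probes=["cg1", "cg2", "cg3", "cg4"], samples=samples)
        ann = ProbeAnnotation(pd.DataFrame(
            {"chrom": "1", "pos": [1, 2, 3, 4], "arm": "p",
             "genes": [("G",), ("G",), ("X",), ("X",)],
             "region_classes": [("TSS200",)] * 4,
             "relation_to_island": "Island"},
            index=pd.Index(["cg1", "cg2", "cg3", "cg4"], name="probe_id"),
        ))
        clusters = sig.ClusterAssignment(
            labels=pd.Series(["hyper"] * 6 + ["hypo"] * 6, index=samples),
            linkage_height=1.0,
            signature_mean_beta=mat.beta.mean(axis=0),
        )
        out = sig.refine_by_cluster(["G"], mat, ann, clusters,
                                    sig.CascadeParams(), moderate=False)
        assert ("G" in out) is expected


class TestCombineSignatures:
    def test_five_plus_four_with_one_shared_gives_eight(self):
        a = ["g1", "g2", "g3", "g4", "g5"]
        b = ["g5", "g6", "g7", "g8"]
        out = sig.combine_signatures({"FOLFOX": a, "FOLFIRI": b})
        assert len(out.genes) == 8
        assert out.provenance["g5"] == ["FOLFIRI", "FOLFOX"]

    def test_disjoint_union(self):
        out = sig.combine_signatures({"A": ["g1", "g2", "g3", "g4", "g5"],
                                      "B": ["g6", "g7", "g8", "g9"]})
        assert len(out.genes) == 9

    def test_idempotent_on_identical_lists(self):
        out = sig.combine_signatures({"A": ["g1", "g2"], "B": ["g1", "g2"]})
        assert out.genes == ["g1", "g2"]


class TestFullCascade:
    def test_recovers_planted_signature(self, default_cohort):
        mat, expr, ann, clinical, _, truth = default_cohort
        run = derive_signature_from_cohort(mat, expr, ann, clinical)
        assert run.signature.genes == truth.signature_genes
        for regimen, genes in truth.regimen_genes.items():
            assert run.refined[regimen] == genes

    def test_provenance_covers_every_gene(self, default_cohort):
        mat, expr, ann, clinical, _, truth = default_cohort
        run = derive_signature_from_cohort(mat, expr, ann, clinical)
        assert set(run.signature.provenance) == set(run.signature.genes)
        for g, regs in run.signature.provenance.items():
            for r in regs:
                assert g in run.refined[r]

    def test_clusters_recover_planted_reference_split(self, default_cohort):
        mat, expr, ann, clinical, _, truth = default_cohort
        run = derive_signature_from_cohort(mat, expr, ann, clinical)
        agreement = (run.clusters.labels.sort_index()
                     == truth.reference_clusters.sort_index()).mean()
        assert agreement == 1.0
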