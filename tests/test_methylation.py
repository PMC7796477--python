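"""Scale conversions, differential-methylation calling and gene summarisation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methsig import methylation
from methsig.containers import m_from_beta, beta_from_m

from conftest import make_matrix


class TestScaleConversions:
    @pytest.mark.parametrize(
        "meth,unmeth,offset,expected",
        [(100, 100, 0, 0.5), (300, 100, 0, 0.75), (300, 100, 100, 0.6)],
    )
    def test_beta_from_intensities(self, meth, unmeth, offset, expected):
        assert methylation.beta_from_intensities(
            np.array([meth]), np.array([unmeth]), offset
        )[0] == pytest.approx(expected)

    def test_zero_total_intensity_errors(self):
        with pytest.raises(ValueError, match="zero"):
            methylation.beta_from_intensities(np.array([0.0]), np.array([0.0]), 0.0)

    def test_m_value_landmarks(self):
        assert m_from_beta(0.5) == pytest.approx(0.0)
        assert m_from_beta(0.75) == pytest.approx(np.log2(3))

    def test_m_beta_inverse_on_grid(self):
        grid = np.linspace(1e-4, 1 - 1e-4, 1000)
        np.testing.assert_allclose(beta_from_m(m_from_beta(grid)), grid, atol=1e-9)


class TestCallDmProbes:
    def _labels(self, n_a, n_b):
        names = [f"S{j}" for j in range(1, n_a + n_b + 1)]
        return pd.Series(["resistant"] * n_a + ["sensitive"] * n_b, index=names)

    def test_planted_probe_recovered_as_hyper(self, rng):
        beta = np.clip(rng.normal(0.5, 0.05, size=(20, 20)), 0.01, 0.99)
        beta[0, :10] = np.clip(rng.normal(0.8, 0.05, 10), 0.01, 0.99)
        beta[0, 10:] = np.clip(rng.normal(0.2, 0.05, 10), 0.01, 0.99)
        mat = make_matrix(beta)
        out = methylation.call_dm_probes(mat, self._labels(10, 10),
                                         p_cut=0.05, dbeta_cut=0.1)
        assert "cg1" in out.index
        assert out.loc["cg1", "direction"] == "hyper"

    def test_strict_delta_beta_threshold(self):
        # clear group difference on M but |dbeta| = 0.05 < 0.1 -> excluded
        beta = np.array([[0.50, 0.501, 0.502, 0.45, 0.451, 0.452]])
        mat = make_matrix(beta)
        out = methylation.call_dm_probes(mat, self._labels(3, 3),
                                         p_cut=0.05, dbeta_cut=0.1, moderate=False)
        assert len(out) == 0

    def test_no_thresholds_returns_all_probes(self, rng):
        mat = make_matrix(np.clip(rng.uniform(0.1, 0.9, size=(30, 8)), 0, 1))
        out = methylation.call_dm_probes(mat, self._labels(4, 4),
                                         p_cut=1.0, dbeta_cut=0.0)
        assert len(out) == 30

    def test_null_matrix_false_positive_bound(self):
        rng = np.random.default_rng(3)
        n_probes, reps = 1000, 1
        beta = np.clip(rng.normal(0.5, 0.05, size=(n_probes, 20)), 0.01, 0.99)
        mat = make_matrix(beta)
        out = methylation.call_dm_probes(mat, self._labels(10, 10),
                                         p_cut=0.05, dbeta_cut=0.1, moderate=False)
        # joint rate bounded by the p-filter rate alone; add binomial slack
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_probes)
        assert len(out) / n_probes <= bound

    def test_direction_antisymmetric_under_group_swap(self, rng):
        beta = np.clip(rng.uniform(0.2, 0.8, size=(15, 10)), 0, 1)
        mat = make_matrix(beta)
        labels = self._labels(5, 5)
        fwd = methylation.call_dm_probes(mat, labels, 1.0, 0.0, moderate=False)
        swapped = labels.map({"resistant": "sensitive", "sensitive": "resistant"})
        rev = methylation.call_dm_probes(mat, swapped, 1.0, 0.0, moderate=False)
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert (rev["direction"] == fwd["direction"].map(flip)).all()


class TestPromoterRestriction:
    def test_promoter_kept_body_dropped(self, small_annotation):
        dm = pd.DataFrame({"p": [0.01, 0.01]}, index=["cg1", "cg2"])
        out = methylation.restrict_to_promoters(dm, small_annotation)
        assert list(out.index) == ["cg1"]  # cg2 is Body-only

    def test_planted_promoter_count(self, rng):
        n = 100
        ids = [f"cg{i}" for i in range(n)]
        promoter = set(rng.choice(ids, size=40, replace=False))
        frame = pd.DataFrame(
            {
                "chrom": "1", "pos": range(1, n + 1), "arm": "p",
                "genes": [("G",)] * n,
                "region_classes": [("TSS200",) if p in promoter else ("Body",)
                                   for p in ids],
                "relation_to_island": "Island",
            },
            index=pd.Index(ids, name="probe_id"),
        )
        ann = methylation.ProbeAnnotation(frame)
        dm = pd.DataFrame({"p": np.full(n, 0.01)}, index=ids)
        out = methylation.restrict_to_promoters(dm, ann)
        assert len(out) == 40
        assert set(out.index) == promoter

    def test_unannotated_probe_dropped(self, small_annotation):
        dm = pd.DataFrame({"p": [0.01, 0.01]}, index=["cg1", "cg_unknown"])
        out = methylation.restrict_to_promoters(dm, small_annotation)
        assert list(out.index) == ["cg1"]


class TestProbesToGenes:
    def _dm(self, rows):
        return pd.DataFrame(rows).set_index("probe_id")

    def test_min_p_probe_wins(self, small_annotation):
        dm = self._dm([
            {"probe_id": "cg3", "p": 0.01, "fdr": 0.1, "delta_beta": 0.3, "logFC": 1.0},
            {"probe_id": "cg4", "p": 0.001, "fdr": 0.02, "delta_beta": 0.2, "logFC": 0.8},
        ])
        out = methylation.probes_to_genes(dm, small_annotation)
        assert out.loc["GB", "p"] == 0.001
        assert out.loc["GB", "best_probe"] == "cg4"
        assert out.loc["GB", "n_promoter_probes"] == 2

    def test_multi_gene_probe_emits_both_genes(self, small_annotation):
        dm = self._dm([
            {"probe_id": "cg4", "p": 0.001, "fdr": 0.02, "delta_beta": 0.2, "logFC": 0.8},
        ])
        out = methylation.probes_to_genes(dm, small_annotation)
        assert set(out.index) == {"GB", "GC"}

    def test_exhaustive_small_case_against_brute_force(self, rng):
        # 20 probes over 8 genes; oracle: direct per-gene min-p scan
        genes = [f"G{k}" for k in range(8)]
        ids = [f"cg{i}" for i in range(20)]
        assign = [tuple(rng.choice(genes, size=rng.integers(1, 3), replace=False))
                  for _ in ids]
        frame = pd.DataFrame(
            {
                "chrom": "1", "pos": range(1, 21), "arm": "p",
                "genes": assign,
                "region_classes": [("TSS200",) * len(a) for a in assign],
                "relation_to_island": "Island",
            },
            index=pd.Index(ids, name="probe_id"),
        )
        ann = methylation.ProbeAnnotation(frame)
        dm = pd.DataFrame(
            {
                "p": rng.uniform(1e-5, 0.05, size=20),
                "fdr": rng.uniform(0.0001, 0.1, size=20),
                "delta_beta": rng.uniform(-0.5, 0.5, size=20),
                "logFC": rng.normal(size=20),
            },
            index=ids,
        )
        out = methylation.probes_to_genes(dm, ann)
        expected = {}
        for pid, gs in zip(ids, assign):
            for g in gs:
                cur = expected.get(g)
                if cur is None or dm.loc[pid, "p"] < dm.loc[cur, "p"]:
                    expected[g] = pid
        assert set(out.index) == set(expected)
        for g, pid in expected.items():
            assert out.loc[g, "best_probe"] == pid
            assert out.loc[g, "p"] == dm.loc[pid, "p"]

    def test_gene_count_never_exceeds_probe_count(self, small_annotation):
        dm = self._dm([
            {"probe_id": "cg1", "p": 0.01, "fdr": 0.1, "delta_beta": 0.1, "logFC": 0.5},
            {"probe_id": "cg3", "p": 0.02, "fdr": 0.1, "delta_beta": 0.1, "logFC": 0.5},
        ])
        out = methylation.probes_to_genes(dm, small_annotation)
        assert len(out) <= len(dm) + 1  # one multi-gene probe may add one gene
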