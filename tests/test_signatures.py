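"""Size factors, the NB-GLM LRT engine, signature extraction, scoring, polarization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asceco import signatures, synthetic
from asceco.signatures import DEResult, SignatureError, SignatureSet


def _counts(arr, genes=None, cells=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=cells)


def _nb_counts(rng, mu, alpha, n):
    lam = rng.gamma(1.0 / alpha, alpha * mu[:, None] * np.ones((1, n)))
    return rng.poisson(lam).astype(float)


class TestSizeFactors:
    @pytest.mark.parametrize("scheme", ["tmm", "median_ratio"])
    def test_identical_cells_get_unit_factors(self, scheme, rng):
        col = rng.poisson(20.0, 50) + 1
        counts = _counts(np.column_stack([col, col]))
        sf = signatures.size_factors(counts, scheme)
        assert np.allclose(sf.to_numpy(), 1.0)

    @pytest.mark.parametrize("scheme", ["tmm", "median_ratio"])
    def test_pure_depth_doubling(self, scheme, rng):
        col = rng.poisson(30.0, 80) + 1
        counts = _counts(np.column_stack([col, 2 * col]))
        sf = signatures.size_factors(counts, scheme)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0, rel=1e-6)

    def test_median_ratio_matches_direct_formula(self, rng):
        arr = _nb_counts(rng, rng.lognormal(3, 1, 40), 0.2, 6) + 1
        counts = _counts(arr)
        sf = signatures.size_factors(counts, "median_ratio")
        # direct median-of-ratios on all-positive genes
        logs = np.log(arr)
        ratios = np.exp(np.median(logs - logs.mean(axis=1, keepdims=True), axis=0))
        expect = ratios / np.exp(np.mean(np.log(ratios)))
        assert np.allclose(sf.to_numpy(), expect)

    def test_median_ratio_cross_checked_against_deseq2(self, rng):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        arr = _nb_counts(rng, rng.lognormal(3, 1.2, 60), 0.2, 10).astype(int) + 1
        counts = _counts(arr)
        sf = signatures.size_factors(counts, "median_ratio")
        meta = pd.DataFrame({"condition": ["a"] * 5 + ["b"] * 5}, index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        ref = np.asarray(dds.obs["size_factors"], dtype=float)
        ref = ref / np.exp(np.mean(np.log(ref)))
        assert np.allclose(sf.to_numpy(), ref, rtol=1e-6)

    def test_median_ratio_without_positive_gene_raises(self):
        counts = _counts([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(SignatureError, match="all-positive"):
            signatures.size_factors(counts, "median_ratio")

    def test_zero_total_cell_raises(self):
        with pytest.raises(SignatureError, match="zero total"):
            signatures.size_factors(_counts([[0.0, 1.0]]), "tmm")


class TestNbLrtDe:
    def test_planted_fold_change_recovered(self, rng):
        G, n = 300, 80
        mu = rng.lognormal(np.log(50), 1.0, G)
        y = np.hstack([
            _nb_counts(rng, mu, 0.2, 40),
            _nb_counts(rng, mu * np.where(np.arange(G) == 0, 8.0, 1.0), 0.2, 40),
        ])
        counts = _counts(y)
        groups = pd.Series(["a"] * 40 + ["b"] * 40, index=counts.columns)
        de = signatures.nb_lrt_de(counts, groups, scheme="tmm", contrast=("a", "b"))
        row = de.table.loc["g0"]
        assert row["fdr"] < 0.05
        assert abs(row["log2fc"] - 3.0) < 0.5

    def test_label_permutation_keeps_p_uniform(self, rng):
        G, n = 500, 60
        mu = rng.lognormal(np.log(40), 1.0, G)
        y = _nb_counts(rng, mu, 0.3, n)
        counts = _counts(y)
        perm = rng.permutation(["a"] * 30 + ["b"] * 30)
        groups = pd.Series(perm, index=counts.columns)
        de = signatures.nb_lrt_de(counts, groups, scheme="median_ratio")
        ks = stats.kstest(de.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_all_zero_genes_excluded(self, rng):
        y = _nb_counts(rng, np.full(10, 20.0), 0.2, 8)
        y[3] = 0.0
        counts = _counts(y)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.columns)
        de = signatures.nb_lrt_de(counts, groups)
        assert de.excluded_genes == ["g3"]
        assert "g3" not in de.table.index

    def test_contrast_orientation(self, rng):
        mu = np.full(40, 30.0)
        mu_hi = mu.copy()
        mu_hi[:2] *= 16.0  # two genes up in the "hi" group
        y = np.hstack([_nb_counts(rng, mu, 0.1, 10), _nb_counts(rng, mu_hi, 0.1, 10)])
        counts = _counts(y)
        groups = pd.Series(["lo"] * 10 + ["hi"] * 10, index=counts.columns)
        de_fwd = signatures.nb_lrt_de(counts, groups, contrast=("lo", "hi"))
        de_rev = signatures.nb_lrt_de(counts, groups, contrast=("hi", "lo"))
        assert (de_fwd.table["log2fc"].iloc[:2] > 2).all()
        assert np.allclose(de_fwd.table["log2fc"], -de_rev.table["log2fc"])

    def test_small_group_raises(self, rng):
        counts = _counts(_nb_counts(rng, np.full(5, 10.0), 0.1, 3))
        groups = pd.Series(["a", "b", "b"], index=counts.columns)
        with pytest.raises(SignatureError, match="< 2"):
            signatures.nb_lrt_de(counts, groups)


def _mk_de(donor, scheme, sig_up=(), sig_down=()):
    genes = [f"g{i}" for i in range(20)]
    table = pd.DataFrame(
        {"log2fc": 0.0, "stat": 0.0, "p": 1.0, "fdr": 1.0, "mean_norm": 10.0}, index=genes
    )
    for g in sig_up:
        table.loc[g, ["log2fc", "fdr"]] = [3.0, 0.001]
    for g in sig_down:
        table.loc[g, ["log2fc", "fdr"]] = [-3.0, 0.001]
    return DEResult(table=table, donor=donor, scheme=scheme, contrast=("M2", "M1"))


class TestExtractSignature:
    def test_scheme_intersection_excludes_single_method_hits(self):
        des = [
            _mk_de("d1", "tmm", sig_up=["g1", "g2"]),
            _mk_de("d1", "median_ratio", sig_up=["g2"]),
            _mk_de("d2", "tmm", sig_up=["g1", "g2"]),
            _mk_de("d2", "median_ratio", sig_up=["g1", "g2"]),
        ]
        up, _ = signatures.extract_signature(des)
        assert up.genes == ("g2",)

    def test_donor_intersection_excludes_single_donor_hits(self):
        des = [
            _mk_de("d1", "tmm", sig_up=["g1", "g2"]),
            _mk_de("d1", "median_ratio", sig_up=["g1", "g2"]),
            _mk_de("d2", "tmm", sig_up=["g2"]),
            _mk_de("d2", "median_ratio", sig_up=["g2"]),
        ]
        up, _ = signatures.extract_signature(des)
        assert up.genes == ("g2",)

    def test_order_invariance_and_down_side(self):
        des = [
            _mk_de("d1", "tmm", sig_down=["g5"]),
            _mk_de("d1", "median_ratio", sig_down=["g5"]),
            _mk_de("d2", "tmm", sig_down=["g5"]),
            _mk_de("d2", "median_ratio", sig_down=["g5"]),
        ]
        _, down1 = signatures.extract_signature(des)
        _, down2 = signatures.extract_signature(des[::-1])
        assert down1.genes == down2.genes == ("g5",)

    def test_threshold_monotonicity(self):
        table = pd.DataFrame(
            {
                "log2fc": [2.5, 3.5, 2.5],
                "stat": 1.0,
                "p": [0.001, 0.001, 0.01],
                "fdr": [0.01, 0.01, 0.04],
                "mean_norm": 10.0,
            },
            index=["a", "b", "c"],
        )
        des = [DEResult(table, "d1", s, ("M2", "M1")) for s in ("tmm", "median_ratio")]
        strict, _ = signatures.extract_signature(des, lfc_min=3.0, fdr_max=0.02)
        loose, _ = signatures.extract_signature(des, lfc_min=2.0, fdr_max=0.05)
        assert set(strict.genes) <= set(loose.genes)

    def test_empty_intersection_warns_not_fatal(self):
        des = [
            _mk_de("d1", "tmm", sig_up=["g1"]),
            _mk_de("d1", "median_ratio"),
        ]
        up, down = signatures.extract_signature(des)
        assert len(up) == 0 and len(down) == 0

    def test_missing_scheme_raises(self):
        with pytest.raises(SignatureError, match="2 schemes"):
            signatures.extract_signature([_mk_de("d1", "tmm")])

    def test_dissociation_gene_filter(self):
        sig = SignatureSet("M2", ("FOS", "CITED2", "DAB2"))
        filtered = sig.without(signatures.DISSOCIATION_GENES)
        assert filtered.genes == ("CITED2", "DAB2")


class TestScoring:
    def test_mean_of_two_genes(self):
        E = pd.DataFrame([[2.0], [4.0]], index=["a", "b"], columns=["c"])
        s = signatures.signature_score(E, SignatureSet("S", ("a", "b")))
        assert s.scores["c"] == pytest.approx(3.0)
        assert s.genes_used == 2

    def test_missing_genes_reduce_genes_used(self):
        E = pd.DataFrame([[2.0], [4.0]], index=["a", "b"], columns=["c"])
        s = signatures.signature_score(E, SignatureSet("S", ("a", "b", "zzz")))
        assert s.genes_used == 2 and s.missing_genes == ("zzz",)
        assert s.scores["c"] == pytest.approx(3.0)

    def test_no_gene_present_raises(self):
        E = pd.DataFrame([[1.0]], index=["a"], columns=["c"])
        with pytest.raises(SignatureError, match="zzz"):
            signatures.signature_score(E, SignatureSet("S", ("zzz",)))

    def test_matches_row_subset_mean_and_order_invariance(self, rng):
        arr = rng.uniform(0, 5, size=(30, 100))
        E = pd.DataFrame(arr, index=[f"g{i}" for i in range(30)], columns=[f"c{j}" for j in range(100)])
        genes = ["g3", "g7", "g11", "g20"]
        s1 = signatures.signature_score(E, SignatureSet("S", tuple(genes)))
        s2 = signatures.signature_score(E, SignatureSet("S", tuple(genes[::-1])))
        expect = arr[[3, 7, 11, 20]].mean(axis=0)
        assert np.allclose(s1.scores.to_numpy(), expect)
        assert np.allclose(s1.scores.to_numpy(), s2.scores.to_numpy())

    def test_non_signature_perturbation_invariance(self, rng):
        arr = rng.uniform(0, 5, size=(10, 6))
        E = pd.DataFrame(arr, index=[f"g{i}" for i in range(10)], columns=list("abcdef"))
        sig = SignatureSet("S", ("g0", "g1"))
        before = signatures.signature_score(E, sig).scores
        E2 = E.copy()
        E2.loc["g9"] = 99.0
        after = signatures.signature_score(E2, sig).scores
        assert np.allclose(before, after)


class TestRescale:
    def test_anchor_example(self):
        out = signatures.rescale_scores(pd.Series([0.0, 5.0, 10.0]))
        assert np.allclose(out, [-1.0, 0.0, 1.0])

    def test_closed_form_and_bounds(self, rng):
        x = pd.Series(rng.normal(size=50))
        out = signatures.rescale_scores(x)
        expect = 2 * (x - x.min()) / (x.max() - x.min()) - 1
        assert np.allclose(out, expect)
        assert out.min() == pytest.approx(-1.0) and out.max() == pytest.approx(1.0)

    def test_constant_input_raises(self):
        with pytest.raises(SignatureError, match="constant"):
            signatures.rescale_scores(pd.Series([1.0, 1.0]))


class TestPolarizationFit:
    def test_identity_line(self):
        x = pd.Series(np.linspace(0, 1, 10))
        fit = signatures.polarization_fit(x, x)
        assert fit.slope == pytest.approx(1.0) and fit.intercept == pytest.approx(0.0)

    def test_affine_line(self):
        x = pd.Series(np.linspace(0, 1, 10))
        fit = signatures.polarization_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0) and fit.intercept == pytest.approx(1.0)

    def test_ci_covers_planted_slope(self, rng):
        x = pd.Series(rng.uniform(0, 2, 200))
        y = 1.5 * x + rng.normal(0, 0.1, 200)
        fit = signatures.polarization_fit(x, pd.Series(y))
        lo, hi = fit.slope_ci
        assert lo < 1.5 < hi

    def test_degenerate_x_raises(self):
        x = pd.Series([1.0, 1.0, 1.0])
        with pytest.raises(SignatureError, match="constant"):
            signatures.polarization_fit(x, x)


class TestOverlap:
    def test_disjoint_identical_random(self, rng):
        sig = SignatureSet("S", ("a", "b", "c"))
        out = signatures.overlap_with_reference(sig, {"empty": ["x"], "same": ["a", "b", "c"]})
        assert out["empty"]["count"] == 0
        assert out["same"]["count"] == 3
        ref = list(rng.choice(list("abcdefgh"), 4, replace=False))
        out = signatures.overlap_with_reference(sig, {"r": ref})
        assert out["r"]["count"] == len({"a", "b", "c"} & set(ref))


class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = {"M1": ["a", "b"], "M2": ["c"]}
        signatures.write_gmt(sets, tmp_path / "s.gmt")
        back = signatures.read_gmt(tmp_path / "s.gmt")
        assert back == sets

    def test_signature_sets_written(self, tmp_path):
        sigs = [SignatureSet("M2", ("x", "y"))]
        signatures.write_gmt(sigs, tmp_path / "s.gmt")
        assert signatures.read_gmt(tmp_path / "s.gmt")["M2"] == ["x", "y"]

    def test_malformed_line_raises(self, tmp_path):
        (tmp_path / "bad.gmt").write_text("onlyname\n")
        with pytest.raises(SignatureError, match="malformed"):
            signatures.read_gmt(tmp_path / "bad.gmt")


class TestReferenceRecovery:
    def test_m2_cells_score_higher_on_m2_signature(self):
        """Extracted signatures separate simulated M2 from M1 cells (>= 95% of cells)."""
        from asceco import io_qc

        sim = synthetic.simulate_reference_macrophages(synthetic.ReferenceConfig(seed=8, n_genes=1200))
        m1, m2, _ = signatures.extract_m1_m2(sim.counts, sim.cell_meta["donor"],
                                             sim.cell_meta["polarization"])
        E = io_qc.log_normalize_tpm(io_qc.tpm_from_counts(sim.counts))
        s1 = signatures.signature_score(E.values, m1).scores
        s2 = signatures.signature_score(E.values, m2).scores
        m2_cells = sim.cell_meta.index[sim.cell_meta["polarization"] == "M2"]
        frac = (s2[m2_cells] > s1[m2_cells]).mean()
        assert frac >= 0.95
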