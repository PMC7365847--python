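"""Tests for count-matrix preparation: I/O, imputation, TMM, log-cpm, PCA."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from monoflame import prep


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {"A": [10, 0, 5, 100], "B": [20, 1, 5, 80]},
        index=["g1", "g2", "g3", "g4"],
        dtype=float,
    ).rename_axis("gene_id")


class TestCountsIO:
    def test_round_trip_identity(self, tmp_path, toy_counts):
        path = tmp_path / "c.tsv"
        prep.write_counts(toy_counts, path)
        back = prep.read_counts(path)
        pd.testing.assert_frame_equal(back, toy_counts, check_dtype=False)

    def test_round_trip_preserves_missing(self, tmp_path, toy_counts):
        toy_counts.loc["g2", "B"] = np.nan
        path = tmp_path / "c.tsv"
        prep.write_counts(toy_counts, path)
        back = prep.read_counts(path)
        assert np.isnan(back.loc["g2", "B"])
        assert back.drop("g2").equals(toy_counts.drop("g2"))

    def test_na_cell_becomes_missing(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\tA\tB\ng1\t3\tNA\ng2\t1\t2\n")
        m = prep.read_counts(path)
        assert np.isnan(m.loc["g1", "B"])
        assert m.loc["g1", "A"] == 3

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\tA\ng1\t3\ng1\t4\n")
        with pytest.raises(ValueError, match="duplicate gene ids"):
            prep.read_counts(path)

    def test_negative_counts_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\tA\ng1\t-3\n")
        with pytest.raises(ValueError, match="negative"):
            prep.read_counts(path)


class TestImputation:
    @staticmethod
    def _design(n=3):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "donor": [f"d{i}" for i in range(n)],
                "arm": ["resolving"] * n,
                "time_h": [24.0] * n,
            }
        )

    @pytest.mark.parametrize(
        "row,expected",
        [
            ([np.nan, 4, 6], [5, 4, 6]),      # one missing -> mean of other two
            ([7, np.nan, np.nan], [7, 0, 0]),  # one replica available -> zeros
            ([3, 3, 3], [3, 3, 3]),            # complete -> unchanged
        ],
    )
    def test_three_replicate_rule(self, row, expected):
        counts = pd.DataFrame([row], index=["g1"], columns=["s0", "s1", "s2"])
        out = prep.impute_missing_replicates(counts, self._design())
        assert out.loc["g1"].tolist() == expected

    def test_all_missing_is_error(self):
        counts = pd.DataFrame([[np.nan] * 3], index=["g1"], columns=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="all replicates missing"):
            prep.impute_missing_replicates(counts, self._design())

    def test_only_masked_cells_touched(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(50, 3)).astype(float),
            index=[f"g{i}" for i in range(50)],
            columns=["s0", "s1", "s2"],
        )
        holes = rng.random(size=counts.shape) < 0.1
        with_holes = counts.mask(holes)
        out = prep.impute_missing_replicates(with_holes, self._design())
        observed = ~holes
        assert (out.to_numpy()[observed] == counts.to_numpy()[observed]).all()
        assert not out.isna().any().any()

    def test_groups_imputed_independently(self):
        design = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
                "donor": list("uvwxyz"),
                "arm": ["resolving"] * 3 + ["persistent"] * 3,
                "time_h": [4.0] * 6,
            }
        )
        counts = pd.DataFrame(
            [[np.nan, 4, 6, 10, np.nan, 20]],
            index=["g1"],
            columns=design["sample_id"],
        )
        out = prep.impute_missing_replicates(counts, design)
        assert out.loc["g1", "a1"] == 5
        assert out.loc["g1", "b2"] == 15


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        col = pd.Series([100, 200, 50, 1000, 10], name="x")
        counts = pd.DataFrame({"A": col, "B": col, "C": col})
        f = prep.tmm_factors(counts)
        np.testing.assert_allclose(f, 1.0)

    def test_pure_scaling_gives_unit_factors(self, rng):
        a = rng.integers(1, 1000, size=200).astype(float)
        counts = pd.DataFrame({"A": a, "B": 2 * a, "C": 5 * a})
        f = prep.tmm_factors(counts)
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_scaling_invariance(self, rng):
        """Scaling one sample leaves M and A values unchanged, so factors
        are invariant up to the count-dependent precision weights (which
        change with depth); agreement is therefore approximate."""
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(300, 4)).astype(float),
            columns=list("ABCD"),
        )
        f1 = prep.tmm_factors(counts)
        scaled = counts.copy()
        scaled["B"] *= 7.0
        f2 = prep.tmm_factors(scaled)
        np.testing.assert_allclose(f1, f2, rtol=0.05)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]})
        with pytest.raises(ValueError, match="zero total"):
            prep.tmm_factors(counts)

    def test_missing_values_rejected(self):
        counts = pd.DataFrame({"A": [1.0, np.nan], "B": [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing"):
            prep.tmm_factors(counts)

    def test_geometric_mean_one(self, rng):
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(300, 5)).astype(float),
            columns=list("ABCDE"),
        )
        f = prep.tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, rel=1e-12)

    def test_matches_naive_definition_on_toy(self):
        """Independent brute-force evaluation of the trimmed weighted mean
        on a 20-gene pair of samples (reference chosen explicitly)."""
        rng = np.random.default_rng(3)
        a = rng.integers(50, 500, size=20).astype(float)
        b = a.copy()
        b[0] *= 8  # one 8-fold gene
        counts = pd.DataFrame({"A": a, "B": b})
        f = prep.tmm_factors(counts, ref="A")

        # oracle: literal definition with explicit sorts
        na, nb = a.sum(), b.sum()
        m = np.log2((b / nb) / (a / na))
        aval = 0.5 * np.log2((b / nb) * (a / na))
        w = (nb - b) / (nb * b) + (na - a) / (na * a)
        n = len(m)
        keep = np.ones(n, bool)
        lo_m, lo_a = int(np.floor(n * 0.3)), int(np.floor(n * 0.05))
        m_order = np.argsort(m, kind="stable")
        keep[m_order[:lo_m]] = False
        keep[m_order[n - lo_m:]] = False
        a_order = np.argsort(aval, kind="stable")
        keep[a_order[:lo_a]] = False
        keep[a_order[n - lo_a:]] = False
        expected_b = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
        expected = np.array([1.0, expected_b])
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(f.to_numpy(), expected, rtol=1e-10)

    def test_matches_edger_reference(self, tmp_path, rng):
        """Cross-check against the edgeR calcNormFactors implementation."""
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(200, 4)).astype(float),
            index=[f"g{i}" for i in range(200)],
            columns=list("ABCD"),
        )
        counts.iloc[:20, 1] *= 8
        path = tmp_path / "c.tsv"
        counts.to_csv(path, sep="\t")
        r = subprocess.run(
            [
                "Rscript",
                "-e",
                f'suppressMessages(library(edgeR)); '
                f'x<-as.matrix(read.delim("{path}",row.names=1)); '
                'cat(calcNormFactors(x, method="TMM"), sep="\\n")',
            ],
            capture_output=True,
            text=True,
            check=True,
        )
        ref = np.array([float(v) for v in r.stdout.split()])
        mine = prep.tmm_factors(counts).to_numpy()
        np.testing.assert_allclose(mine, ref, atol=5e-6)


class TestLogCpmAndFilter:
    def test_log_cpm_formula(self):
        # one gene with count 0 in a library engineered to effective size 1e6
        counts = pd.DataFrame({"A": [0.0, 1e6 - 0.0]}, index=["g1", "g2"])
        expr = prep.log_cpm(counts, pd.Series({"A": 1.0}))
        expected = np.log2((0 + 0.5) / (1e6 + 1) * 1e6)
        assert expr.logcpm.loc["g1", "A"] == pytest.approx(expected)
        assert expected == pytest.approx(-1.0, abs=2e-5)

    def test_log_cpm_depth_invariance_for_moderate_counts(self, rng):
        counts = pd.DataFrame({"A": rng.integers(10, 10000, size=500).astype(float)})
        doubled = counts * 2
        e1 = prep.log_cpm(counts).logcpm
        e2 = prep.log_cpm(doubled).logcpm
        assert np.abs(e1.to_numpy() - e2.to_numpy()).max() < 0.01

    def test_filter_keeps_gene_with_four_samples_above(self):
        # cpm (1.5, 1.2, 0.8, 1.1, 2.0) via equal library sizes of 1e6
        counts = pd.DataFrame(
            [[1.5, 1.2, 0.8, 1.1, 2.0], [0, 0, 0, 0, 0]],
            index=["keep", "drop"],
            columns=list("ABCDE"),
            dtype=float,
        )
        filler = pd.DataFrame(
            [[1e6 - c for c in counts.loc["keep"]]], index=["bulk"], columns=counts.columns
        ) - counts.loc[["drop"]].to_numpy()
        m = pd.concat([counts, filler])
        out = prep.filter_by_cpm(m, pd.Series(1.0, index=m.columns), 1.0, 4)
        assert "keep" in out.index and "drop" not in out.index

    def test_filter_matches_brute_force(self, small_sim):
        counts, _ = small_sim
        factors = prep.tmm_factors(counts)
        out = prep.filter_by_cpm(counts, factors, 1.0, 4)
        c = counts / (counts.sum(axis=0) * factors) * 1e6
        expected = [g for g in counts.index if int((c.loc[g] > 1.0).sum()) >= 4]
        assert list(out.index) == expected

    def test_filter_invariant_to_sample_order(self, small_sim):
        counts, _ = small_sim
        factors = prep.tmm_factors(counts)
        shuffled = counts[counts.columns[::-1]]
        out1 = prep.filter_by_cpm(counts, factors, 1.0, 4)
        out2 = prep.filter_by_cpm(shuffled, factors, 1.0, 4)
        assert list(out1.index) == list(out2.index)

    def test_min_samples_exceeding_n_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="min_samples"):
            prep.filter_by_cpm(toy_counts, None, 1.0, 3)


class TestPCA:
    def test_identical_samples_have_equal_scores(self, rng):
        col = rng.normal(size=50)
        logcpm = pd.DataFrame({"A": col, "B": col, "C": rng.normal(size=50)})
        res = prep.pca_scores(logcpm, k=2)
        np.testing.assert_allclose(res.scores.loc["A"], res.scores.loc["B"], atol=1e-9)

    def test_variance_explained_non_increasing(self, small_sim):
        counts, _ = small_sim
        expr = prep.log_cpm(counts)
        res = prep.pca_scores(expr, k=5)
        assert (np.diff(res.variance_explained) <= 1e-12).all()
        assert res.variance_explained.sum() <= 1.0 + 1e-12

    def test_k_too_large_rejected(self, rng):
        logcpm = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="k="):
            prep.pca_scores(logcpm, k=4)

    def test_pc1_separates_late_arm_samples(self, full_design, small_sim):
        """The simulated arm divergence after 14 h must dominate PC1:
        late resolving and persistent samples separate (silhouette > 0)."""
        counts, _ = small_sim
        factors = prep.tmm_factors(counts)
        expr = prep.log_cpm(prep.filter_by_cpm(counts, factors), factors)
        res = prep.pca_scores(expr, k=2)
        design = full_design.set_index("sample_id")
        late = design[
            ((design.arm == "resolving") & (design.time_h >= 24))
            | ((design.arm == "persistent") & (design.time_h >= 24))
        ]
        pc = res.scores.loc[late.index]
        labels = (late.arm == "persistent").to_numpy()
        from sklearn.metrics import silhouette_score

        pcs = pc.to_numpy()
        for axis in range(2):
            score = silhouette_score(pcs[:, [axis]], labels)
            if score > 0:
                return
        raise AssertionError("no leading component separates late arm samples")
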