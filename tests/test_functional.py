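"""KO abundance normalization, rollups, correlations and ordination."""

import numpy as np
import pandas as pd
import pytest

from aerobiome import functional as fn


def _ann(sample, ko_counts, gene_len):
    rows = []
    i = 0
    for ko, n in ko_counts.items():
        for _ in range(n):
            rows.append((f"{sample}_p{i}", sample, ko, gene_len[ko]))
            i += 1
    return pd.DataFrame(rows, columns=["peptide_id", "sample", "ko",
                                       "gene_len_aa"])


class TestKOAbundance:
    def test_equal_gene_lengths_weights_cancel(self):
        ann = _ann("A", {"K00001": 2, "K00002": 1}, {"K00001": 200,
                                                     "K00002": 200})
        mat = fn.ko_abundance(ann, {"A": 350.0})
        assert mat.loc["A", "K00001"] == pytest.approx(2 / 3)
        assert mat.loc["A", "K00002"] == pytest.approx(1 / 3)

    def test_gene_length_weighting_ratio(self):
        # genes of 1000 and 2000 nt, mean read 350: ratio 2349/1349
        ann = _ann("A", {"K1": 1, "K2": 1}, {"K1": 1000 / 3, "K2": 2000 / 3})
        mat = fn.ko_abundance(ann, {"A": 350.0})
        assert mat.loc["A", "K1"] / mat.loc["A", "K2"] == \
            pytest.approx(2349 / 1349)

    def test_normalized_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        frames = []
        for s in ("A", "B", "C"):
            counts = {f"K{i:05d}": int(rng.integers(1, 20)) for i in range(8)}
            lens = {k: int(rng.integers(100, 700)) for k in counts}
            frames.append(_ann(s, counts, lens))
        mat = fn.ko_abundance(pd.concat(frames), {"A": 250.0, "B": 350.0,
                                                  "C": 450.0})
        assert np.allclose(mat.sum(axis=1), 1.0)
        assert (mat.to_numpy() >= 0).all()

    def test_raw_mode_is_plain_counts(self):
        ann = _ann("A", {"K1": 3, "K2": 1}, {"K1": 100, "K2": 900})
        mat = fn.ko_abundance(ann, {"A": 350.0}, mode="raw")
        assert mat.loc["A", "K1"] == 3 and mat.loc["A", "K2"] == 1

    def test_missing_gene_length_raises_with_offenders(self):
        ann = _ann("A", {"K1": 1}, {"K1": 0})
        with pytest.raises(ValueError, match="A_p0"):
            fn.ko_abundance(ann, {"A": 350.0})

    def test_length_bias_removed_between_samples(self):
        """Identical KO composition at mean read lengths 250 vs 450:
        normalized profiles agree per KO, raw profiles do not."""
        gene_len = {"K1": 150, "K2": 400, "K3": 800}
        copies = {"K1": 30, "K2": 20, "K3": 10}
        frames = {}
        for sample, lbar in (("S250", 250.0), ("S450", 450.0)):
            counts = {ko: round(copies[ko] * (3 * gene_len[ko] + lbar - 1))
                      for ko in copies}
            frames[sample] = _ann(sample, counts, gene_len)
        ann = pd.concat(frames.values())
        lbars = {"S250": 250.0, "S450": 450.0}
        norm = fn.ko_abundance(ann, lbars, mode="length_normalized")
        raw = fn.ko_abundance(ann, lbars, mode="raw")
        raw = raw.div(raw.sum(axis=1), axis=0)
        for ko in copies:
            rel = abs(norm.loc["S250", ko] - norm.loc["S450", ko]) \
                / norm.loc["S450", ko]
            assert rel <= 0.02
        assert (abs(raw.loc["S250"] - raw.loc["S450"])
                / raw.loc["S450"]).max() > 0.05


class TestRollup:
    def test_sums_and_multi_membership(self):
        mat = pd.DataFrame({"K1": [0.2], "K2": [0.3], "K3": [0.5]},
                           index=["A"])
        komap = {"K1": ["cat1"], "K2": ["cat1"], "K3": ["cat1", "cat2"]}
        out = fn.category_rollup(mat, komap)
        # pre-normalization masses: cat1 = 0.5 + 0.5, cat2 = 0.5
        assert out.loc["A", "cat1"] == pytest.approx(1.0 / 1.5)
        assert out.loc["A", "cat2"] == pytest.approx(0.5 / 1.5)
        assert out.sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_unmapped_bucket(self):
        mat = pd.DataFrame({"K1": [0.6], "KX": [0.4]}, index=["A"])
        out = fn.category_rollup(mat, {"K1": ["cat1"]})
        assert out.loc["A", "unmapped"] == pytest.approx(0.4)


class TestCorrelation:
    def test_identical_and_reversed_profiles(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                            [3.0, 2.0, 1.0]], index=["a", "b", "c"])
        corr, mean = fn.profile_correlation(mat)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert mean == pytest.approx((1.0 - 1.0 - 1.0) / 3)

    def test_constant_profile_excluded(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]],
                           index=["a", "flat"])
        _, mean = fn.profile_correlation(mat)
        assert np.isnan(mean)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            fn.profile_correlation(pd.DataFrame([[1.0, 2.0]], index=["a"]))


class TestOrdination:
    def test_variance_fractions_match_eigendecomposition(self):
        X = pd.DataFrame([[0.1, 0.5, 0.4], [0.3, 0.3, 0.4],
                          [0.6, 0.2, 0.2], [0.25, 0.25, 0.5]],
                         index=list("abcd"))
        result = fn.pca_ordination(X)
        # independent oracle: eigendecomposition of the feature covariance
        A = X.to_numpy() - X.to_numpy().mean(axis=0)
        evals = np.linalg.eigvalsh(A.T @ A / (len(X) - 1))[::-1]
        expected = evals / evals.sum()
        np.testing.assert_allclose(result.variance_fractions,
                                   expected[:len(result.variance_fractions)],
                                   atol=1e-8)

    def test_rank_one_matrix_single_axis(self):
        base = np.array([1.0, 2.0, 3.0])
        X = pd.DataFrame(np.outer([1.0, 2.0, 3.0, 4.0], base))
        result = fn.pca_ordination(X)
        assert result.variance_fractions[0] == pytest.approx(1.0)

    def test_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.random((5, 7)))
        vf = fn.pca_ordination(X).variance_fractions
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() <= 1.0 + 1e-9

    def test_translation_invariant_scores(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.random((4, 5)))
        shifted = X + 3.0
        s1 = fn.pca_ordination(X).scores
        s2 = fn.pca_ordination(shifted).scores
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_sign_convention_stable(self):
        X = pd.DataFrame(np.random.default_rng(10).random((4, 6)))
        tops = fn.pca_ordination(X).top_loadings
        for t in tops:
            assert t.iloc[0] > 0  # largest-|loading| entry positive

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            fn.pca_ordination(pd.DataFrame(np.eye(2)))


class TestStringentFilter:
    @pytest.mark.parametrize("ident,cov,kept", [
        (90.0, 90.0, True),    # inclusive boundary retained
        (89.9, 99.0, False),
        (99.0, 89.9, False),
        (95.0, 95.0, True),
    ])
    def test_inclusive_boundaries(self, ident, cov, kept):
        hits = pd.DataFrame({"pct_identity": [ident], "pct_coverage": [cov]})
        out = fn.stringent_match_filter(hits)
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        out = fn.stringent_match_filter(pd.DataFrame())
        assert len(out) == 0
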