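"""Network scoring: LD clumping, signed weighted summation, categorization."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from eprsqol.genotypes import GenotypeMatrix
from eprsqol.score import (
    compute_eprs,
    ld_clump,
    reconcile_alleles,
    standardize_and_categorize,
)

from conftest import make_weights


def clump_oracle(weights: pd.DataFrame, window_bp: int) -> list[str]:
    """Independent re-implementation of greedy lowest-p clumping."""
    remaining = weights.sort_values("clump_p", kind="stable").copy()
    retained = []
    while len(remaining):
        top = remaining.iloc[0]
        retained.append(top["snp_id"])
        near = (remaining["chrom"] == top["chrom"]) & (
            (remaining["pos"] - top["pos"]).abs() <= window_bp
        )
        remaining = remaining[~near]
    return sorted(retained)


class TestLdClump:
    def test_distant_snps_all_retained(self):
        w = make_weights(
            [
                ("a", 1, 1_000_000, "A", "G", "g1", 0.1, 1, 0.5),
                ("b", 1, 2_000_000, "A", "G", "g1", 0.2, 1, 0.1),
                ("c", 2, 1_000_000, "A", "G", "g2", 0.3, -1, 0.9),
            ]
        )
        out = ld_clump(w, window_bp=250_000)
        assert list(out["snp_id"]) == ["a", "b", "c"]

    def test_lowest_p_snp_wins_within_window(self):
        w = make_weights(
            [
                ("weak", 1, 100_000, "A", "G", "g1", 0.1, 1, 1e-3),
                ("strong", 1, 110_000, "A", "G", "g1", 0.2, 1, 1e-8),
            ]
        )
        out = ld_clump(w, window_bp=250_000)
        assert list(out["snp_id"]) == ["strong"]

    def test_random_table_matches_independent_oracle(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(50):
            rows.append(
                (
                    f"s{i}", int(rng.integers(1, 4)), int(rng.integers(1, 2_000_000)),
                    "A", "G", f"g{i // 5}",
                    float(rng.normal()), int(rng.choice([-1, 1])),
                    float(rng.uniform(1e-9, 1)),
                )
            )
        w = make_weights(rows)
        out = ld_clump(w, window_bp=150_000)
        assert sorted(out["snp_id"]) == clump_oracle(w, 150_000)
        # original order is preserved
        order = {s: i for i, s in enumerate(w["snp_id"])}
        assert list(out["snp_id"]) == sorted(out["snp_id"], key=order.get)

    def test_missing_positions_rejected(self):
        w = make_weights([("a", 1, np.nan, "A", "G", "g1", 0.1, 1, 0.5)])
        with pytest.raises(ValueError):
            ld_clump(w)


def _single_marker_gm(dosages, ref="A", alt="G"):
    markers = pd.DataFrame(
        {"snp_id": ["m1"], "chrom": [1], "pos": [100], "ref": [ref], "alt": [alt]}
    )
    dos = np.asarray(dosages, dtype=float).reshape(-1, 1)
    return GenotypeMatrix(dos, [f"s{i}" for i in range(len(dos))], markers)


class TestComputeEprs:
    def test_single_snp_dosage_times_beta(self):
        gm = _single_marker_gm([2.0, 0.0])
        w = make_weights([("m1", 1, 100, "G", "A", "g1", 0.3, 1, 0.1)])
        scores = compute_eprs(gm, w)
        assert scores.tolist() == pytest.approx([0.6, 0.0])

    def test_negative_coexpression_sign_flips_score(self):
        gm = _single_marker_gm([2.0])
        w = make_weights([("m1", 1, 100, "G", "A", "g1", 0.3, -1, 0.1)])
        assert compute_eprs(gm, w).iloc[0] == pytest.approx(-0.6)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        n, m = 3, 3
        dos = rng.integers(0, 3, size=(n, m)).astype(float)
        markers = pd.DataFrame(
            {
                "snp_id": [f"m{j}" for j in range(m)],
                "chrom": [1] * m,
                "pos": [100 * (j + 1) for j in range(m)],
                "ref": ["A"] * m,
                "alt": ["G"] * m,
            }
        )
        gm = GenotypeMatrix(dos, ["a", "b", "c"], markers)
        w = make_weights(
            [
                (f"m{j}", 1, 100 * (j + 1), "G", "A", "g1",
                 float(rng.normal()), int(rng.choice([-1, 1])), 0.5)
                for j in range(m)
            ]
        )
        scores = compute_eprs(gm, w)
        for i in range(n):
            expected = 0.0
            for j in range(m):
                expected += dos[i, j] * w["beta"][j] * w["sign"][j]
            assert scores.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_allele_swap_uses_flipped_dosage(self):
        gm = _single_marker_gm([2.0, 1.0], ref="A", alt="G")
        w = make_weights([("m1", 1, 100, "A", "G", "g1", 1.0, 1, 0.1)])
        # effect allele is the panel ref: dosage becomes 2 - d
        assert compute_eprs(gm, w).tolist() == pytest.approx([0.0, 1.0])

    def test_ambiguous_snps_dropped(self):
        gm = _single_marker_gm([2.0], ref="A", alt="T")
        w = make_weights([("m1", 1, 100, "A", "T", "g1", 1.0, 1, 0.1)])
        kept, aligned, report = reconcile_alleles(gm, w)
        assert report.n_ambiguous_dropped == 1 and aligned.shape[1] == 0
        with pytest.raises(ValueError):
            compute_eprs(gm, w)

    def test_no_overlap_is_an_error(self, tiny_genotypes):
        w = make_weights([("zz", 1, 100, "A", "G", "g1", 1.0, 1, 0.1)])
        with pytest.raises(ValueError):
            compute_eprs(tiny_genotypes, w)


class TestScoreInvariants:
    @pytest.fixture()
    def gm_and_weights(self):
        rng = np.random.default_rng(10)
        n, m = 30, 12
        dos = rng.integers(0, 3, size=(n, m)).astype(float)
        markers = pd.DataFrame(
            {
                "snp_id": [f"m{j}" for j in range(m)],
                "chrom": [1] * m,
                "pos": 1000 * np.arange(m) + 1,
                "ref": ["A"] * m,
                "alt": ["G"] * m,
            }
        )
        gm = GenotypeMatrix(dos, [f"s{i}" for i in range(n)], markers)
        w = make_weights(
            [
                (f"m{j}", 1, 1000 * j + 1, "G", "A", f"g{j % 3}",
                 float(rng.normal()), int(rng.choice([-1, 1])),
                 float(rng.uniform()))
                for j in range(m)
            ]
        )
        return gm, w

    def test_linearity_over_disjoint_weight_tables(self, gm_and_weights):
        gm, w = gm_and_weights
        s_all = compute_eprs(gm, w)
        s_a = compute_eprs(gm, w.iloc[:6])
        s_b = compute_eprs(gm, w.iloc[6:])
        np.testing.assert_allclose(s_all, s_a + s_b, atol=1e-12)

    def test_negating_signs_negates_scores(self, gm_and_weights):
        gm, w = gm_and_weights
        w2 = w.assign(sign=-w["sign"])
        np.testing.assert_allclose(
            compute_eprs(gm, w2), -compute_eprs(gm, w), atol=1e-12
        )

    def test_allele_flip_shifts_scores_by_constant(self, gm_and_weights):
        gm, w = gm_and_weights
        flipped = w.assign(
            effect_allele=w["other_allele"], other_allele=w["effect_allele"]
        )
        s1 = compute_eprs(gm, w)
        s2 = compute_eprs(gm, flipped)
        diff = s1 + s2  # d*b + (2-d)*b = 2b per SNP: constant
        assert np.ptp(diff.to_numpy()) < 1e-10
        z1 = standardize_and_categorize(s1)["z"]
        z2 = standardize_and_categorize(-s2)["z"]
        np.testing.assert_allclose(z1, z2, atol=1e-10)


class TestStandardizeAndCategorize:
    def test_boundary_semantics(self):
        # construct raw scores whose z-scores hit exactly 0 and beyond +/-0.5
        raw = pd.Series([0.0, 1.0, -1.0, 2.0, -2.0])
        out = standardize_and_categorize(raw)
        z = out["z"]
        assert out.loc[z == 0, "category"].iloc[0] == "moderate"
        assert (out.loc[z < -0.5, "category"] == "low").all()
        assert (out.loc[z > 0.5, "category"] == "high").all()

    def test_z_scores_standardized(self):
        rng = np.random.default_rng(11)
        out = standardize_and_categorize(pd.Series(rng.normal(10, 3, 500)))
        assert abs(out["z"].mean()) < 1e-9
        assert abs(out["z"].std(ddof=1) - 1) < 1e-9

    def test_constant_shift_leaves_z_and_categories(self):
        rng = np.random.default_rng(12)
        raw = pd.Series(rng.normal(size=200))
        a = standardize_and_categorize(raw)
        b = standardize_and_categorize(raw + 57.0)
        np.testing.assert_allclose(a["z"], b["z"], atol=1e-9)
        assert (a["category"] == b["category"]).all()

    def test_normal_sample_category_shares(self):
        rng = np.random.default_rng(13)
        n = 20_000
        out = standardize_and_categorize(pd.Series(rng.normal(size=n)))
        shares = out["category"].value_counts(normalize=True)
        p_low = st.norm.cdf(-0.5)
        for cat, p in (("low", p_low), ("moderate", 1 - 2 * p_low), ("high", p_low)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(shares[cat] - p) < 3 * se

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize_and_categorize(pd.Series([1.0, 1.0, 1.0]))
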