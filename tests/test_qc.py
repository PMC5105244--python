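"""QC tests: MAF, exact HWE vs enumeration, filters, duplicates, PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln, logsumexp

from csfqtl import (
    EmptyFilterError,
    SimulationConfig,
    compute_maf,
    detect_duplicates,
    filter_variants,
    hwe_exact_test,
    pca_population_structure,
    simulate_cohort,
    simulate_genotypes,
)
from conftest import make_counts_matrix


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Independent route: normalized log-probabilities of every feasible
    heterozygote count from the factorial formula, summed over configurations
    no more probable than the observed one."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0
    hs = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hs) // 2
    hom_common = n - hs - hom_rare
    logp = (
        hs * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hs + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logsumexp(logp)
    probs = np.exp(logp)
    p_obs = probs[hs == n_het][0]
    return min(float(probs[probs <= p_obs * (1 + 1e-10)].sum()), 1.0)


class TestComputeMaf:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (np.zeros(50), 0.0),  # monomorphic
            (np.r_[np.ones(10), np.full(5, 2.0), np.zeros(85)], 0.10),
            (np.r_[np.ones(10), np.full(5, 2.0), np.zeros(85), np.full(50, np.nan)], 0.10),
        ],
    )
    def test_known_values(self, counts, expected):
        assert compute_maf(counts) == pytest.approx(expected)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            compute_maf(np.full(10, np.nan))

    @given(st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=50)
    def test_invariant_to_allele_label_swap(self, counts):
        c = np.array(counts)
        assert compute_maf(c) == pytest.approx(compute_maf(2.0 - c))


class TestHweExactTest:
    def test_modal_configuration_gives_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_all_heterozygote_extreme(self):
        p = hwe_exact_test(0, 100, 0)
        assert p < 1e-6
        assert p == pytest.approx(hwe_enumeration_oracle(0, 100, 0), rel=1e-12)

    def test_matches_enumeration_on_skewed_table(self):
        assert hwe_exact_test(57, 14, 50) == pytest.approx(
            hwe_enumeration_oracle(57, 14, 50), rel=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    @settings(derandomize=True, max_examples=200)
    def test_equals_enumeration_for_random_tables(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(
            hwe_enumeration_oracle(a, b, c), rel=1e-10
        )


class TestFilterVariants:
    def _craft(self):
        # 50 clean filler variants keep per-sample call rates above the
        # threshold so the sample-first filter does not mask the variant cases
        rng = np.random.default_rng(0)
        n = 200
        fillers = [rng.binomial(2, 0.3, n).astype(float) for _ in range(50)]
        low_cr = fillers[0].copy()
        low_cr[rng.choice(n, 6, replace=False)] = np.nan  # call rate 0.97
        rare = np.zeros(n)
        rare[:7] = 1.0  # maf 7/400 = 0.0175 < 0.02
        hwe_bad = np.ones(n)  # all heterozygous
        ids = [f"clean{j}" for j in range(50)] + ["lowcr", "rare", "hwebad"]
        return make_counts_matrix(fillers + [low_cr, rare, hwe_bad], ids=ids)

    def test_exclusion_reasons_recorded(self):
        G = self._craft()
        Gq, report = filter_variants(G)
        tab = report.variant_table.set_index("id")
        assert list(Gq.variants["id"]) == [f"clean{j}" for j in range(50)]
        assert "call_rate" in tab.loc["lowcr", "reasons"]
        assert "maf" in tab.loc["rare", "reasons"]
        assert "hwe" in tab.loc["hwebad", "reasons"]
        excluded = report.variant_table.loc[~report.variant_table["pass"]]
        assert (excluded["reasons"] != "").all()

    def test_clean_simulated_cohort_fully_retained(self):
        G, _ = simulate_cohort(SimulationConfig(seed=3, n_null_variants=100))
        Gq, report = filter_variants(G)
        assert Gq.n_variants == G.n_variants
        assert report.variant_table["pass"].all()

    def test_idempotent(self):
        G = simulate_genotypes(379, np.linspace(0.1, 0.5, 200), missing_rate=0.005, seed=4)
        G1, _ = filter_variants(G)
        G2, _ = filter_variants(G1)
        assert list(G1.variants["id"]) == list(G2.variants["id"])
        assert G1.sample_ids == G2.sample_ids
        np.testing.assert_array_equal(G1.counts, G2.counts)

    def test_empty_result_signalled(self):
        G = make_counts_matrix([np.zeros(100), np.zeros(100)])
        with pytest.raises(EmptyFilterError):
            filter_variants(G)


class TestDetectDuplicates:
    def test_verbatim_duplicate_flagged_with_full_sharing(self):
        G = simulate_genotypes(20, np.full(500, 0.3), seed=5)
        counts = G.counts.copy()
        counts[1] = counts[0]
        G2 = make_counts_matrix(list(counts.T))
        pairs = detect_duplicates(G2)
        assert (G2.sample_ids[0], G2.sample_ids[1], 1.0) in pairs

    def test_duplicate_with_missingness_still_flagged(self):
        rng = np.random.default_rng(6)
        G = simulate_genotypes(10, np.full(1000, 0.3), seed=6)
        counts = G.counts.copy()
        counts[1] = counts[0]
        counts[1, rng.random(1000) < 0.05] = np.nan  # missing sites dropped pairwise
        G2 = make_counts_matrix(list(counts.T))
        pairs = detect_duplicates(G2)
        ids = {(a, b) for a, b, _ in pairs}
        assert (G2.sample_ids[0], G2.sample_ids[1]) in ids
        assert all(s == 1.0 for a, b, s in pairs)

    def test_unrelated_individuals_below_threshold(self):
        # Monte-Carlo oracle: expected concordance for independent genotypes
        # at MAF in [0.05, 0.5] is far below 0.95
        rng = np.random.default_rng(7)
        G = simulate_genotypes(40, rng.uniform(0.05, 0.5, 10_000), seed=7)
        assert detect_duplicates(G) == []

    def test_single_sample_warns_and_returns_empty(self):
        G = make_counts_matrix([[1.0]])
        with pytest.warns(UserWarning):
            assert detect_duplicates(G) == []


class TestPCA:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(8)
        m = 300
        p1 = rng.uniform(0.1, 0.4, m)
        p2 = np.clip(p1 + 0.25, 0.02, 0.5)
        c1 = rng.binomial(2, p1, size=(150, m)).astype(float)
        c2 = rng.binomial(2, p2, size=(150, m)).astype(float)
        G = make_counts_matrix(list(np.vstack([c1, c2]).T))
        pcs = pca_population_structure(G, k=2)
        label = np.r_[np.zeros(150), np.ones(150)]
        r = np.corrcoef(pcs.scores[:, 0], label)[0, 1]
        assert abs(r) > 0.9

    def test_eigenvalues_nonnegative_descending(self):
        G = simulate_genotypes(50, np.linspace(0.1, 0.5, 100), seed=9)
        pcs = pca_population_structure(G, k=5)
        assert (pcs.eigenvalues >= 0).all()
        assert (np.diff(pcs.eigenvalues) <= 1e-12).all()
        gram = pcs.scores.T @ pcs.scores
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_homogeneous_population_has_no_leading_structure(self):
        # null-simulation oracle: no eigenvalue separates from the bulk
        rng = np.random.default_rng(10)
        G = simulate_genotypes(300, rng.uniform(0.05, 0.5, 5000), seed=10)
        pcs = pca_population_structure(G, k=10)
        G2 = G.subset_variants(np.arange(G.n_variants))  # full spectrum via big k
        full = pca_population_structure(G2, k=299)
        assert full.eigenvalues[0] / full.eigenvalues.mean() < 3

    def test_scores_invariant_to_variant_permutation_up_to_sign(self):
        G = simulate_genotypes(60, np.linspace(0.1, 0.5, 200), seed=11)
        rng = np.random.default_rng(11)
        perm = rng.permutation(G.n_variants)
        s1 = pca_population_structure(G, k=2).scores
        s2 = pca_population_structure(G.subset_variants(perm), k=2).scores
        for j in range(2):
            assert abs(np.corrcoef(s1[:, j], s2[:, j])[0, 1]) > 1 - 1e-9

    def test_rank_deficient_input_rejected(self):
        base = np.array([[0.0, 1, 2, 1], [2.0, 1, 0, 1]])
        counts = np.repeat(base, 5, axis=0)  # 10 samples, 2 distinct rows
        G = make_counts_matrix(list(counts.T))
        with pytest.raises(ValueError, match="rank"):
            pca_population_structure(G, k=3)
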