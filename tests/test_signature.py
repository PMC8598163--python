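import math

import numpy as np
import pytest

from coilsig import (
    AlignedScoreMatrix,
    ConsistencyError,
    RangeError,
    SaturationError,
    SimConfig,
    UndefinedResultError,
    align_scores,
    call_conserved_domains,
    cc_conservation_score,
    column_identity,
    cv_length,
    filter_columns_by_coverage,
    gamma_poisson_distance,
    mean_pairwise_divergence,
    pairwise_p_distance,
    signature_metrics,
    simulate_family,
    sliding_window_identity,
)


class TestAlignScores:
    def test_scores_thread_through_gaps(self, make_msa, make_profile):
        msa = make_msa({"A": "ME-K", "B": "MEAK"})
        profiles = {
            "A": make_profile([0.1, 0.2, 0.3], residues="MEK", species="A"),
            "B": make_profile([0.5, 0.5, 0.5, 0.5], residues="MEAK", species="B"),
        }
        mat = align_scores(msa, profiles)
        row_a = mat.scores[0]
        assert np.allclose(row_a[[0, 1, 3]], [0.1, 0.2, 0.3])
        assert np.isnan(row_a[2])

    def test_length_mismatch_names_species(self, make_msa, make_profile):
        msa = make_msa({"A": "ME-K", "B": "MEAK"})
        profiles = {
            "A": make_profile([0.1, 0.2], residues="ME", species="A"),
            "B": make_profile([0.5] * 4, residues="MEAK", species="B"),
        }
        with pytest.raises(ConsistencyError, match="'A'"):
            align_scores(msa, profiles)

    def test_residue_mismatch_names_position(self, make_msa, make_profile):
        msa = make_msa({"A": "MEAK", "B": "MEAK"})
        profiles = {
            "A": make_profile([0.1] * 4, residues="MEVK", species="A"),
            "B": make_profile([0.5] * 4, residues="MEAK", species="B"),
        }
        with pytest.raises(ConsistencyError, match="position 2"):
            align_scores(msa, profiles)

    def test_identical_rows_give_identical_matrix_rows(self, make_msa, make_profile):
        msa = make_msa({"A": "MEAK", "B": "MEAK"})
        prof = [0.3, 0.4, 0.5, 0.6]
        profiles = {
            sp: make_profile(prof, residues="MEAK", species=sp) for sp in "AB"
        }
        mat = align_scores(msa, profiles)
        assert np.allclose(mat.scores[0], mat.scores[1])


class TestCoverageFilter:
    def _matrix(self, n_species, col_counts):
        scores = np.full((n_species, len(col_counts)), np.nan)
        for col, k in enumerate(col_counts):
            scores[:k, col] = 0.5
        return AlignedScoreMatrix("og", tuple(map(str, range(n_species))), scores)

    def test_eighty_percent_rule(self):
        mat = self._matrix(10, [7, 8, 10])
        filtered = filter_columns_by_coverage(mat, 0.8)
        assert list(filtered.retained_columns) == [1, 2]

    def test_seven_of_eight_mode(self):
        mat = self._matrix(8, [6, 7, 8])
        filtered = filter_columns_by_coverage(mat, 7 / 8)
        assert list(filtered.retained_columns) == [1, 2]

    def test_all_columns_removed_warns_not_raises(self):
        mat = self._matrix(10, [1, 2])
        with pytest.warns(UserWarning, match="removed"):
            filtered = filter_columns_by_coverage(mat, 0.8)
        assert len(filtered.retained_columns) == 0


class TestConservationScore:
    def test_all_ones_scores_one(self):
        mat = AlignedScoreMatrix("og", ("a", "b"), np.ones((2, 5)))
        assert cc_conservation_score(mat) == 1.0

    def test_one_species_without_coils_zeroes_the_score(self):
        scores = np.vstack([np.ones(5), np.zeros(5)])
        mat = AlignedScoreMatrix("og", ("a", "b"), scores)
        assert cc_conservation_score(mat) == 0.0

    def test_hand_example(self):
        mat = AlignedScoreMatrix(
            "og", ("a", "b"), np.array([[0.9, 0.4], [0.7, 0.8]])
        )
        assert cc_conservation_score(mat) == pytest.approx(0.55)

    def test_no_retained_columns_is_undefined(self):
        mat = AlignedScoreMatrix(
            "og", ("a", "b"), np.ones((2, 3)), retained_columns=np.array([], int)
        )
        with pytest.raises(UndefinedResultError):
            cc_conservation_score(mat)

    def test_adding_a_species_never_raises_the_score(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            base = rng.random((rng.integers(2, 8), rng.integers(1, 20)))
            extra = rng.random((1, base.shape[1]))
            small = AlignedScoreMatrix("og", ("s",) * base.shape[0], base)
            big = AlignedScoreMatrix(
                "og", ("s",) * (base.shape[0] + 1), np.vstack([base, extra])
            )
            assert cc_conservation_score(big) <= cc_conservation_score(small) + 1e-12


class TestConservedDomains:
    def _matrix(self, col_means, n_species=5, jitter=0.0):
        scores = np.tile(np.asarray(col_means, float), (n_species, 1))
        if jitter:
            scores += np.linspace(-jitter, jitter, n_species)[:, None]
        return AlignedScoreMatrix(
            "og", tuple(map(str, range(n_species))), np.clip(scores, 0, 1)
        )

    def test_thirty_uniform_columns_give_one_domain(self):
        calls = call_conserved_domains(self._matrix([0.95] * 30))
        assert len(calls) == 1
        assert calls[0].n_columns == 30
        assert np.allclose(calls[0].sd_profile, 0.0)

    def test_twenty_columns_is_below_minimum_length(self):
        assert call_conserved_domains(self._matrix([0.95] * 20)) == []

    def test_low_mean_column_splits_the_run(self):
        means = [0.95] * 21 + [0.5] + [0.95] * 21
        calls = call_conserved_domains(self._matrix(means))
        assert [c.n_columns for c in calls] == [21, 21]

    def test_high_sd_disqualifies(self):
        mat = self._matrix([0.9] * 30, jitter=0.3)
        assert call_conserved_domains(mat) == []


class TestDistances:
    def test_identical_rows_have_zero_p(self):
        assert pairwise_p_distance("AAAA", "AAAA") == 0.0

    def test_half_different(self):
        assert pairwise_p_distance("AAAA", "AATT") == 0.5

    def test_pairwise_deletion_excludes_gapped_columns(self):
        assert pairwise_p_distance("A-AA", "AAA-") == 0.0

    def test_all_gapped_pair_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            pairwise_p_distance("--AA", "AA--")

    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.0, 0.0),
            (0.5, 2 * (math.sqrt(2) - 1)),
            (0.99, 18.0),
        ],
    )
    def test_gamma_poisson_closed_form(self, p, expected):
        assert gamma_poisson_distance(p, 2.0) == pytest.approx(expected)

    def test_gamma_poisson_domain_errors(self):
        with pytest.raises(SaturationError):
            gamma_poisson_distance(1.0)
        with pytest.raises(RangeError):
            gamma_poisson_distance(-0.1)

    def test_gamma_poisson_monotone_and_linear_at_small_p(self):
        ps = np.linspace(0.0, 0.95, 200)
        ds = [gamma_poisson_distance(p) for p in ps]
        assert np.all(np.diff(ds) > 0)
        for p in np.linspace(0.001, 0.05, 25):
            d = gamma_poisson_distance(p)
            assert abs(d - p) < p * p

    def test_mean_pairwise_divergence_examples(self, make_msa):
        assert mean_pairwise_divergence(make_msa({"A": "AAAA", "B": "AAAA"})) == 0.0
        half = mean_pairwise_divergence(make_msa({"A": "AAAA", "B": "AATT"}))
        assert half == pytest.approx(2 * (math.sqrt(2) - 1))
        three = mean_pairwise_divergence(
            make_msa({"A": "AAAA", "B": "AAAA", "C": "AATT"})
        )
        assert three == pytest.approx((0 + half + half) / 3)

    def test_complete_deletion_mode(self, make_msa):
        msa = make_msa({"A": "A-TA", "B": "AAAA", "C": "AAAA"})
        # complete deletion keeps columns 0, 2, 3 only
        d = mean_pairwise_divergence(msa, deletion="complete")
        p = 1 / 3
        expected = (2 * gamma_poisson_distance(p) + 0) / 3
        assert d == pytest.approx(expected)


class TestLengthVariation:
    def test_equal_lengths_have_zero_cv(self):
        assert cv_length([300, 300, 300]) == 0.0

    def test_hand_example(self):
        assert cv_length([100, 100, 100, 120]) == pytest.approx(10 / 105)

    def test_single_length_rejected(self):
        with pytest.raises(ValueError):
            cv_length([1])


class TestColumnIdentity:
    def test_conserved_column(self, make_msa):
        msa = make_msa({s: "L" for s in "ABCDE"})
        assert column_identity(msa)[0] == 1.0

    def test_two_of_three_identical(self, make_msa):
        msa = make_msa({"A": "L", "B": "L", "C": "V"})
        assert column_identity(msa)[0] == pytest.approx(1 / 3)

    def test_consensus_mode(self, make_msa):
        msa = make_msa({"A": "L", "B": "L", "C": "V"})
        assert column_identity(msa, mode="consensus")[0] == pytest.approx(2 / 3)

    def test_single_residue_column_is_missing(self, make_msa):
        msa = make_msa({"A": "L-", "B": "-A"})
        assert np.isnan(column_identity(msa)).all()

    def test_smoothing_leaves_constant_series_unchanged(self):
        out = sliding_window_identity(np.full(30, 0.7), window=10)
        assert np.allclose(out, 0.7)

    def test_smoothing_skips_missing_values(self):
        vals = np.array([1.0, np.nan, 1.0, 1.0])
        assert np.allclose(sliding_window_identity(vals, window=3), 1.0)


class TestSignatureMetrics:
    def test_identical_family_is_fully_conserved(self, make_msa, make_profile):
        msa = make_msa({sp: "MEAKLV" for sp in "ABC"})
        profiles = {
            sp: make_profile([1.0] * 6, residues="MEAKLV", species=sp)
            for sp in "ABC"
        }
        m = signature_metrics(msa, profiles)
        assert (m.substitutions_per_site, m.cv_length, m.cc_conservation_score) == (
            0.0,
            0.0,
            1.0,
        )
        assert m.n_species == 3

    def test_single_member_rejected(self, make_profile):
        from coilsig import FormatError, OrthogroupAlignment

        with pytest.raises(FormatError):
            OrthogroupAlignment("og", {"A": "MEAK"})

    def test_disorder_profiles_flow_through_identically(self, make_msa, make_profile):
        msa = make_msa({"A": "MEAK", "B": "MEAK"})
        cc = {
            sp: make_profile([0.9, 0.9, 0.9, 0.9], residues="MEAK", species=sp)
            for sp in "AB"
        }
        dis = {
            sp: make_profile(
                [0.9, 0.9, 0.9, 0.9], residues="MEAK", kind="disorder", species=sp
            )
            for sp in "AB"
        }
        m_cc = align_scores(msa, cc)
        m_dis = align_scores(msa, dis)
        assert np.allclose(m_cc.scores, m_dis.scores)
        assert len(call_conserved_domains(m_cc, min_len=4)) == len(
            call_conserved_domains(m_dis, min_len=4)
        )


def test_conservation_score_matches_bruteforce_oracle():
    """Column-min/mean identity against an explicit per-column loop."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        n_sp = rng.integers(2, 21)
        n_col = rng.integers(1, 51)
        scores = rng.random((n_sp, n_col))
        scores[rng.random((n_sp, n_col)) < 0.2] = np.nan
        keep = np.flatnonzero(np.isfinite(scores).sum(axis=0) > 0)
        if keep.size == 0:
            continue
        mat = AlignedScoreMatrix(
            "og", tuple(map(str, range(n_sp))), scores, retained_columns=keep
        )
        expected = np.mean(
            [min(x for x in scores[:, c] if np.isfinite(x)) for c in keep]
        )
        assert cc_conservation_score(mat) == pytest.approx(expected)


def test_two_taxon_divergence_recovery():
    """Simulating a known expected distance and re-estimating it returns
    the truth to within 10% (gamma-Poisson estimator, 2,000 sites)."""
    estimates = []
    for seed in range(50):
        cfg = SimConfig(
            seed=seed,
            newick="(A:0.5,B:0.5);",
            ancestral_length=2000,
            cc_segments=(),
            indel_rate_in=0.0,
            indel_rate_out=0.0,
        )
        fam = simulate_family(cfg)
        estimates.append(mean_pairwise_divergence(fam.alignment))
    assert abs(np.mean(estimates) - 1.0) < 0.1
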