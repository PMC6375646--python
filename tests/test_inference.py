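import math

import numpy as np
import pandas as pd
import pytest

import sortbind as sb
from sortbind.inference import ScalingFactorMCMC, base_preference_test


class TestMatrixMCMC:
    def test_recovers_ground_truth_on_reduced_problem(self, small_posterior):
        est, ds, truth = small_posterior
        assert sb.compare_matrices(est.matrix_, truth) >= 0.85
        assert 0.0 < est.acceptance_rate_ < 1.0
        assert est.mutual_information_ > 0.5

    def test_posterior_mean_is_reference_gauged_and_oriented(self, small_posterior):
        est, ds, truth = small_posterior
        assert est.matrix_.gauge == "reference"
        assert est.matrix_.check_gauge()
        free = est.matrix_.values[est.matrix_.values != 0]
        # orientation convention: the typical mutation is penalizing, and the
        # unit convention pins the mean free entry at 1 arbitrary unit
        assert free.mean() == pytest.approx(1.0, rel=1e-6)

    def test_chain_is_bitwise_reproducible(self, small_experiment):
        ds, _ = small_experiment
        kwargs = dict(reference_seq=ds.reference_seq, n_iterations=400,
                      n_burnin=150, random_state=5)
        a = sb.EnergyMatrixMCMC(**kwargs).fit(ds.codes, ds.bins, sample_weight=ds.counts)
        b = sb.EnergyMatrixMCMC(**kwargs).fit(ds.codes, ds.bins, sample_weight=ds.counts)
        np.testing.assert_array_equal(a.matrix_.values, b.matrix_.values)
        assert a.mutual_information_ == b.mutual_information_

    def test_different_seeds_agree(self, small_posterior, small_experiment):
        est, ds, _ = small_posterior
        other = sb.EnergyMatrixMCMC(
            reference_seq=ds.reference_seq, n_iterations=2500, n_burnin=800,
            proposal_sd=0.2, random_state=99,
        ).fit(ds.codes, ds.bins, sample_weight=ds.counts)
        assert sb.compare_matrices(est.matrix_, other.matrix_) >= 0.9

    def test_position_without_diversity_is_flagged_and_zeroed(self):
        rng = np.random.default_rng(0)
        n = 400
        codes = rng.integers(0, 4, size=(n, 4)).astype(np.int8)
        codes[:, 2] = 1  # no diversity at position 2
        preds = codes[:, 0].astype(float)
        bins = (preds > 1).astype(int)
        with pytest.warns(UserWarning, match="diversity"):
            est = sb.EnergyMatrixMCMC(
                reference_seq="ACCA", n_iterations=300, n_burnin=100,
                random_state=0,
            ).fit(codes, bins)
        assert est.flagged_positions_ == [2]
        np.testing.assert_array_equal(est.matrix_.values[2], 0.0)

    def test_requires_reference_sequence(self, small_experiment):
        ds, _ = small_experiment
        with pytest.raises(ValueError, match="reference"):
            sb.EnergyMatrixMCMC(n_iterations=10, n_burnin=5).fit(ds.codes, ds.bins)

    def test_estimator_protocol(self):
        est = sb.EnergyMatrixMCMC(reference_seq="ACGT")
        params = est.get_params()
        assert params["n_iterations"] == 30_000 and params["n_burnin"] == 10_000
        est.set_params(n_iterations=5)
        assert est.n_iterations == 5
        with pytest.raises(ValueError):
            est.set_params(nope=1)

    def test_functional_wrapper_returns_posterior(self, small_experiment):
        ds, _ = small_experiment
        post = sb.mcmc_infer_matrix(
            ds, sb.MCMCConfig(n_iterations=400, n_burnin=150, seed=2))
        assert post.mean_matrix.check_gauge()
        assert post.sd.shape == post.mean_matrix.values.shape
        assert 0 < post.acceptance_rate < 1


class TestScalingFactor:
    def test_rescaled_matrix_halves_alpha(self, small_experiment):
        ds, truth = small_experiment
        tp = sb.ThermoParams(R=130, eps_R=-15.3)
        arb = sb.EnergyMatrix(truth.values / 1.5, units="arbitrary",
                              gauge="reference", reference_seq=truth.reference_seq)
        arb2 = sb.EnergyMatrix(truth.values / 3.0, units="arbitrary",
                               gauge="reference", reference_seq=truth.reference_seq)
        common = dict(thermo=tp, offset_wt=-15.3, n_iterations=800,
                      n_burnin=300, random_state=1)
        a1 = ScalingFactorMCMC(matrix=arb, **common).fit(
            ds.codes, ds.bins, sample_weight=ds.counts).alpha_
        a2 = ScalingFactorMCMC(matrix=arb2, **common).fit(
            ds.codes, ds.bins, sample_weight=ds.counts).alpha_
        assert a2 / a1 == pytest.approx(2.0, rel=0.1)

    def test_shuffled_bins_flagged_unidentifiable(self, small_experiment):
        ds, truth = small_experiment
        shuf = np.random.default_rng(0).permutation(ds.bins)
        arb = sb.EnergyMatrix(truth.values / 1.5, units="arbitrary",
                              gauge="reference", reference_seq=truth.reference_seq)
        est = ScalingFactorMCMC(
            matrix=arb, thermo=sb.ThermoParams(R=130, eps_R=-15.3),
            offset_wt=-15.3, n_iterations=800, n_burnin=300, random_state=1,
        ).fit(ds.codes, shuf, sample_weight=ds.counts)
        assert not est.identifiable_

    def test_rejects_kbt_matrix(self, small_experiment):
        ds, truth = small_experiment
        with pytest.raises(ValueError, match="arbitrary"):
            ScalingFactorMCMC(matrix=truth, thermo=sb.ThermoParams()).fit(
                ds.codes, ds.bins)


class TestAlternativeScaling:
    def test_least_squares_recovers_exact_affine_map(self, rng):
        m = sb.EnergyMatrix(rng.normal(0, 1, (8, 4)))
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 8)) for _ in range(12)]
        anchors = [(s, 1.2 * m.score(s) - 15.3) for s in seqs]
        alpha, offset = sb.scale_by_least_squares(m, anchors)
        assert alpha == pytest.approx(1.2, abs=1e-10)
        assert offset == pytest.approx(-15.3, abs=1e-9)

    def test_two_anchors_interpolate(self, rng):
        m = sb.EnergyMatrix(rng.normal(0, 1, (4, 4)))
        anchors = [("ACGT", -10.0), ("TGCA", -14.0)]
        alpha, offset = sb.scale_by_least_squares(m, anchors)
        for seq, e in anchors:
            assert alpha * m.score(seq) + offset == pytest.approx(e, abs=1e-9)

    def test_identical_scores_singular(self, rng):
        m = sb.EnergyMatrix(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="singular|share"):
            sb.scale_by_least_squares(m, [("ACGT", -10.0), ("TGCA", -14.0)])

    def test_theoretical_penalty_ratio(self):
        vals = np.zeros((2, 4))
        vals[:, 1:] = 2.0  # mean non-reference entry = 2 (reference base A)
        m = sb.EnergyMatrix(vals, gauge="reference", reference_seq="AA")
        assert sb.scale_by_theoretical_penalty(m, 1.0) == pytest.approx(0.5)
        assert sb.scale_by_theoretical_penalty(m, 2.0) == pytest.approx(1.0)

    def test_theoretical_penalty_self_consistent(self, rng):
        ref = "ACGTACGT"
        m = sb.EnergyMatrix(rng.normal(1, 0.5, (8, 4)), gauge="none",
                            reference_seq=ref).fix_gauge("reference")
        alpha = sb.scale_by_theoretical_penalty(m, 1.2)
        scaled = m.values * alpha
        ref_idx = [("ACGT".index(c)) for c in ref]
        mask = np.ones_like(scaled, dtype=bool)
        mask[np.arange(8), ref_idx] = False
        assert scaled[mask].mean() == pytest.approx(1.2, abs=1e-9)

    def test_zero_mean_penalty_rejected(self):
        m = sb.EnergyMatrix(np.zeros((3, 4)), gauge="reference", reference_seq="ACG")
        with pytest.raises(ValueError, match="0"):
            sb.scale_by_theoretical_penalty(m, 1.0)

    def test_least_squares_matches_truth_from_noiseless_anchors(self, small_experiment):
        """Anchor-based scaling pins down the exact affine map to kBT."""
        ds, truth = small_experiment
        arb = sb.EnergyMatrix(truth.values / 1.5, units="arbitrary",
                              gauge="reference", reference_seq=truth.reference_seq)
        anchors = [(s, truth.score(s) - 15.3) for s in ds.sequences()[:20]]
        alpha_ls, offset_ls = sb.scale_by_least_squares(arb, anchors)
        assert alpha_ls == pytest.approx(1.5, abs=1e-9)
        assert offset_ls == pytest.approx(-15.3, abs=1e-8)


def _welch_games_howell_oracle(probs):
    """Hand-coded Welch ANOVA + Games-Howell on a (k, 4) probability table."""
    k, g = probs.shape
    means, variances = probs.mean(0), probs.var(0, ddof=1)
    w = k / variances
    mw = (w * means).sum() / w.sum()
    tmp = ((1 - w / w.sum()) ** 2 / (k - 1)).sum() / (g**2 - 1)
    f = ((w * (means - mw) ** 2).sum() / (g - 1)) / (1 + 2 * (g - 2) * tmp)
    df1, df2 = g - 1, 1 / (3 * tmp)
    from scipy import stats

    anova_p = stats.f.sf(f, df1, df2)
    pairs = {}
    for i in range(g):
        for j in range(i + 1, g):
            se2 = variances[i] / k + variances[j] / k
            t = abs(means[i] - means[j]) / math.sqrt(se2)
            df = se2**2 / ((variances[i] / k) ** 2 / (k - 1)
                           + (variances[j] / k) ** 2 / (k - 1))
            p = stats.studentized_range.sf(t * math.sqrt(2), g, df)
            pairs[(i, j)] = p
    return anova_p, pairs


class TestBasePreference:
    def _replicates_from_probs(self, probs_list):
        # invert Boltzmann weights: energies = -log p (shift-invariant)
        mats = []
        for p in probs_list:
            vals = -np.log(np.asarray(p))
            mats.append(sb.EnergyMatrix(vals.reshape(1, 4)))
        return mats

    def test_dominant_base_in_identical_replicates(self):
        mats = self._replicates_from_probs([[0.85, 0.05, 0.05, 0.05]] * 3)
        res = base_preference_test(mats, 0)
        assert res.preferred_base == "A"
        assert res.anova_p == 0.0
        assert (res.pairwise["pval"] == 0.0).all()

    def test_uniform_replicates_have_no_preference(self):
        mats = self._replicates_from_probs([[0.25] * 4] * 3)
        res = base_preference_test(mats, 0)
        assert res.preferred_base is None

    def test_matches_hand_coded_welch_games_howell(self, rng):
        base = np.array([0.55, 0.25, 0.12, 0.08])
        probs = np.clip(base + rng.normal(0, 0.02, size=(4, 4)), 1e-3, None)
        probs /= probs.sum(axis=1, keepdims=True)
        mats = self._replicates_from_probs(list(probs))
        res = base_preference_test(mats, 0)
        oracle_p, oracle_pairs = _welch_games_howell_oracle(
            res.probabilities.to_numpy())
        assert res.anova_p == pytest.approx(oracle_p, rel=1e-6)
        bases = "ACGT"
        for _, row in res.pairwise.iterrows():
            i, j = sorted((bases.index(row["A"]), bases.index(row["B"])))
            assert row["pval"] == pytest.approx(oracle_pairs[(i, j)], rel=1e-3, abs=1e-9)

    def test_requires_three_replicates(self):
        mats = self._replicates_from_probs([[0.25] * 4] * 2)
        with pytest.raises(ValueError, match="3"):
            base_preference_test(mats, 0)
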