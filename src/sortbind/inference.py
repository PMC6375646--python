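"""Mutual-information-maximizing MCMC inference of energy matrices.

The sampler explores L×4 matrix values with a Metropolis–Hastings chain whose
target is p(data | model) ∝ 2^(N·I), where N is the number of sorted reads
and I the mutual information between the matrix's energy predictions and the
expression bins. Because MI is invariant under monotone transforms of the
predictions, the overall scale and sign of the matrix are unidentifiable
("diffeomorphic modes"): the chain runs in reference gauge (wild-type cells
pinned at 0), and the posterior mean is post-hoc oriented so that the
reference sequence is near-optimal and unit-normalized so the mean
single-mutant entry is 1 arbitrary unit.

Absolute units come from a second, single-parameter chain over the scaling
factor α in Δε_R = α·ε_mat + Δε_wt, which maximizes I(p_bound; μ): the
nonlinearity of the occupancy model p_bound makes the scale identifiable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import SortSeqDataset, split_replicates  # noqa: F401  (re-exported)
from .energy_matrix import EnergyMatrix, base_probabilities
from .mutual_info import (
    default_mi_bins,
    estimate_mutual_information,
    rank_bin,
    _joint_entropy_mi,
)
from .sequences import ALPHABET, encode, encode_many
from .thermo import ThermoParams

_LN2 = math.log(2.0)


@dataclass
class MCMCConfig:
    """Chain settings. Defaults follow the standard protocol (30000 kept
    iterations after a 10000-iteration burn-in)."""

    n_iterations: int = 30000
    n_burnin: int = 10000
    proposal_sd: float = 0.05
    seed: int = 0
    mi_bins: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive")


@dataclass
class MatrixPosterior:
    """Posterior summary of a matrix-inference chain."""

    mean_matrix: EnergyMatrix
    sd: np.ndarray
    acceptance_rate: float
    mutual_information: float
    flagged_positions: list = field(default_factory=list)
    seed: int = 0


def _as_codes(X) -> np.ndarray:
    if isinstance(X, np.ndarray) and X.ndim == 2:
        return X.astype(np.int8)
    return encode_many(X)


class EnergyMatrixMCMC:
    """Metropolis–Hastings inference of an energy matrix from sorted-library data.

    scikit-learn-style estimator: ``fit(X, y, sample_weight)`` with X the
    sequences (strings or an (n, L) integer-code array), y the expression
    bins and sample_weight the read counts. Fitted attributes:

    - ``matrix_`` : posterior-mean :class:`EnergyMatrix` (arbitrary units,
      reference gauge, oriented and unit-normalized)
    - ``matrix_sd_`` : per-cell posterior standard deviations (same scaling)
    - ``acceptance_rate_``, ``mutual_information_``, ``flagged_positions_``

    Proposals are independent Gaussians on all free (non-reference) cells;
    the step size adapts toward a 20–40% acceptance rate during burn-in and
    is frozen afterwards. The chain is bit-for-bit reproducible given
    ``random_state``.
    """

    def __init__(
        self,
        reference_seq: Optional[str] = None,
        n_iterations: int = 30000,
        n_burnin: int = 10000,
        proposal_sd: float = 0.05,
        mi_bins: Optional[int] = None,
        random_state: int = 0,
    ):
        self.reference_seq = reference_seq
        self.n_iterations = n_iterations
        self.n_burnin = n_burnin
        self.proposal_sd = proposal_sd
        self.mi_bins = mi_bins
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "reference_seq": self.reference_seq,
            "n_iterations": self.n_iterations,
            "n_burnin": self.n_burnin,
            "proposal_sd": self.proposal_sd,
            "mi_bins": self.mi_bins,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "EnergyMatrixMCMC":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- core chain --------------------------------------------------------

    def fit(self, X, y, sample_weight=None) -> "EnergyMatrixMCMC":
        codes = _as_codes(X)
        bins = np.asarray(y, dtype=np.int64).ravel()
        counts = (np.ones_like(bins) if sample_weight is None
                  else np.asarray(sample_weight, dtype=np.int64).ravel())
        n, L = codes.shape
        if bins.size != n or counts.size != n:
            raise ValueError("X, y and sample_weight must agree in length")
        if self.reference_seq is None:
            raise ValueError("reference_seq is required (reference-gauge inference)")
        ref_codes = encode(self.reference_seq)
        if ref_codes.size != L:
            raise ValueError(f"reference length {ref_codes.size} != sequence length {L}")
        rng = np.random.default_rng(self.random_state)

        # seeded shuffle of record order: the stable sort inside rank binning
        # then breaks prediction ties deterministically but without bias
        perm = rng.permutation(n)
        codes, bins, counts = codes[perm], bins[perm], counts[perm]

        # mutational diversity per position; undiversified columns are not sampled
        free = np.ones((L, 4), dtype=bool)
        free[np.arange(L), ref_codes] = False
        flagged: list[int] = []
        for i in range(L):
            observed = np.unique(codes[:, i])
            if observed.size < 2:
                flagged.append(i)
                free[i, :] = False
            else:
                absent = np.setdiff1d(np.arange(4), observed)
                free[i, absent] = False
        if not free.any():
            raise ValueError("no mutational diversity at any position")
        if flagged:
            warnings.warn(
                f"positions with no mutational diversity (0-based): {flagged}; "
                "their columns are zeroed", stacklevel=2)

        N = int(counts.sum())
        mi_bins = self.mi_bins if self.mi_bins is not None else default_mi_bins(n)
        n_expr = int(bins.max()) + 1
        pos_idx = np.arange(L)[None, :]

        def mi_of_preds(preds: np.ndarray) -> float:
            e_idx = rank_bin(preds, counts, mi_bins)
            joint = np.zeros((mi_bins, n_expr))
            np.add.at(joint, (e_idx, bins), counts)
            return _joint_entropy_mi(joint)

        def mi_of(M: np.ndarray) -> float:
            return mi_of_preds(M[pos_idx, codes].sum(axis=1))

        # one iteration = a Metropolis update of one randomly chosen free
        # cell; predictions are updated incrementally on the records that
        # carry that base at that position
        fi, fb = np.nonzero(free)
        cell_records = [np.flatnonzero(codes[:, i] == b) for i, b in zip(fi, fb)]
        n_free = fi.size

        # least-squares warm start: regress the bin index on one-hot mutation
        # indicators. This seeds a globally consistent orientation, which
        # single-cell moves cannot repair once positions lock in conflicting
        # signs (the MI target is invariant under a global flip but heavily
        # penalizes mixed ones).
        X = np.zeros((n, n_free))
        for j, idx in enumerate(cell_records):
            X[idx, j] = 1.0
        w = np.sqrt(counts.astype(float))
        beta, *_ = np.linalg.lstsq(
            (X * w[:, None]), (bins - bins.mean()) * w, rcond=None)
        M = np.zeros((L, 4))
        M[fi, fb] = beta
        rms0 = math.sqrt(float((M[free] ** 2).mean()))
        if rms0 > 0:
            M /= rms0
        preds = M[pos_idx, codes].sum(axis=1)
        I_cur = mi_of_preds(preds)
        sd = float(self.proposal_sd)
        total = self.n_burnin + self.n_iterations
        accept_post = 0
        window_acc = 0
        window = 200
        mean_acc = np.zeros((L, 4))
        sq_acc = np.zeros((L, 4))
        kept = 0

        for it in range(total):
            k = int(rng.integers(n_free))
            delta = rng.normal(0.0, sd)
            idx = cell_records[k]
            preds[idx] += delta
            I_new = mi_of_preds(preds)
            if math.log(rng.random()) < N * (I_new - I_cur) * _LN2:
                M[fi[k], fb[k]] += delta
                I_cur = I_new
                window_acc += 1
                if it >= self.n_burnin:
                    accept_post += 1
            else:
                preds[idx] -= delta
            # the overall scale is a diffeomorphic (MI-flat) mode: pin it by
            # renormalizing so the free cells have unit rms, which leaves the
            # rank-binned MI unchanged but keeps the chain compact
            if (it + 1) % 50 == 0:
                rms = math.sqrt(float((M[free] ** 2).mean()))
                if rms > 0:
                    M /= rms
                    preds /= rms
            if it < self.n_burnin and (it + 1) % window == 0:
                rate = window_acc / window
                if rate < 0.20:
                    sd = max(sd * 0.8, 1e-3)
                elif rate > 0.40:
                    sd = min(sd * 1.25, 1.0)
                window_acc = 0
            elif it == self.n_burnin - 1:
                window_acc = 0
            if it >= self.n_burnin:
                mean_acc += M
                sq_acc += M * M
                kept += 1

        mean = mean_acc / kept
        var = np.maximum(sq_acc / kept - mean**2, 0.0)
        cell_sd = np.sqrt(var)

        # orient (reference near-optimal) and unit-normalize (mean mutant entry = 1)
        free_mean = mean[free].mean()
        if free_mean < 0:
            mean, free_mean = -mean, -free_mean
        if free_mean > 0:
            mean = mean / free_mean
            cell_sd = cell_sd / free_mean

        self.matrix_ = EnergyMatrix(
            mean, units="arbitrary", gauge="reference",
            reference_seq=self.reference_seq,
        ).fix_gauge("reference")
        self.matrix_sd_ = cell_sd
        self.acceptance_rate_ = accept_post / max(kept, 1)
        self.mutual_information_ = mi_of(self.matrix_.values)
        self.flagged_positions_ = flagged
        self.n_features_in_ = L
        return self

    def predict(self, X) -> np.ndarray:
        """ε_mat scores (arbitrary units) of sequences under the posterior mean."""
        if not hasattr(self, "matrix_"):
            raise RuntimeError("fit() has not been called")
        return self.matrix_.score_many(_as_codes(X))

    def score(self, X, y, sample_weight=None) -> float:
        """Mutual information (bits) of the fitted matrix on the given data."""
        return estimate_mutual_information(
            self.predict(X), y, counts=sample_weight,
            mi_bins=self.mi_bins, strategy="rank")

    def posterior_(self) -> MatrixPosterior:
        return MatrixPosterior(
            mean_matrix=self.matrix_,
            sd=self.matrix_sd_,
            acceptance_rate=self.acceptance_rate_,
            mutual_information=self.mutual_information_,
            flagged_positions=self.flagged_positions_,
            seed=self.random_state,
        )


def mcmc_infer_matrix(ds: SortSeqDataset, cfg: MCMCConfig = MCMCConfig()) -> MatrixPosterior:
    """Infer an energy matrix from a Sort-Seq dataset (functional wrapper)."""
    est = EnergyMatrixMCMC(
        reference_seq=ds.reference_seq,
        n_iterations=cfg.n_iterations,
        n_burnin=cfg.n_burnin,
        proposal_sd=cfg.proposal_sd,
        mi_bins=cfg.mi_bins,
        random_state=cfg.seed,
    ).fit(ds.codes, ds.bins, sample_weight=ds.counts)
    return est.posterior_()


# -- scaling-factor inference ----------------------------------------------


class ScalingFactorMCMC:
    """Single-parameter chain for the matrix scaling factor α.

    Holding an arbitrary-unit, reference-gauge matrix and an effective
    occupancy model fixed, the chain samples α (in log-space, reflective
    bounds) with acceptance min(1, 2^(N·ΔI)) where I = I(p_bound; μ) is
    computed with equal-width value binning — value binning is essential:
    rank binning is monotone-invariant and would make α unidentifiable.

    Fitted attributes: ``alpha_`` (posterior mean), ``alpha_sd_``,
    ``identifiable_`` (False when the posterior is as wide as the prior).
    """

    LOG_BOUNDS = (math.log(1e-3), math.log(1e3))

    def __init__(
        self,
        matrix: EnergyMatrix = None,
        thermo: ThermoParams = None,
        offset_wt: float = -15.3,
        n_iterations: int = 3000,
        n_burnin: int = 1000,
        proposal_sd: float = 0.15,
        mi_bins: Optional[int] = None,
        random_state: int = 0,
    ):
        self.matrix = matrix
        self.thermo = thermo
        self.offset_wt = offset_wt
        self.n_iterations = n_iterations
        self.n_burnin = n_burnin
        self.proposal_sd = proposal_sd
        self.mi_bins = mi_bins
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "matrix": self.matrix, "thermo": self.thermo, "offset_wt": self.offset_wt,
            "n_iterations": self.n_iterations, "n_burnin": self.n_burnin,
            "proposal_sd": self.proposal_sd, "mi_bins": self.mi_bins,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "ScalingFactorMCMC":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, sample_weight=None) -> "ScalingFactorMCMC":
        if self.matrix is None or self.thermo is None:
            raise ValueError("matrix and thermo must be set before fit()")
        if self.matrix.units != "arbitrary":
            raise ValueError("scaling inference expects an arbitrary-unit matrix")
        codes = _as_codes(X)
        bins = np.asarray(y, dtype=np.int64).ravel()
        counts = (np.ones_like(bins) if sample_weight is None
                  else np.asarray(sample_weight, dtype=np.int64).ravel())
        n = codes.shape[0]
        rng = np.random.default_rng(self.random_state)

        eps_mat = self.matrix.score_many(codes)
        tp = self.thermo
        pol = (tp.P / tp.N_NS) * math.exp(-tp.eps_P)
        rep0 = tp.heads_per_repressor * tp.R / tp.N_NS
        N = int(counts.sum())
        mi_bins = self.mi_bins if self.mi_bins is not None else default_mi_bins(n)
        n_expr = int(bins.max()) + 1

        n_shift = 8

        def mi_of(log_alpha: float) -> float:
            # MI with equal-width value bins on p_bound, averaged over
            # shifted bin grids (the N·I exponent magnifies even tiny
            # discretization wiggles, so the grid is de-aliased) and
            # Miller–Madow corrected (the number of occupied bins varies
            # with alpha, so the raw plug-in bias would itself be an
            # alpha-dependent, spurious signal).
            eps_R = math.exp(log_alpha) * eps_mat + self.offset_wt
            with np.errstate(over="ignore"):
                pb = pol / (1.0 + pol + rep0 * np.exp(-eps_R))
            lo, hi = pb.min(), pb.max()
            if hi == lo:
                return 0.0
            width = (hi - lo) / mi_bins
            acc = 0.0
            for s in range(n_shift):
                origin = lo - width * s / n_shift
                idx = np.clip(((pb - origin) / (hi - lo + width)
                               * (mi_bins + 1)).astype(np.int64), 0, mi_bins)
                joint = np.zeros((mi_bins + 1, n_expr))
                np.add.at(joint, (idx, bins), counts)
                acc += _joint_entropy_mi(joint, bias_correction=True)
            return acc / n_shift

        lo, hi = self.LOG_BOUNDS
        la = 0.0
        I_cur = mi_of(la)
        samples = []
        accepted = 0
        for it in range(self.n_burnin + self.n_iterations):
            prop = la + rng.normal(0.0, self.proposal_sd)
            # reflect at the prior bounds
            while prop < lo or prop > hi:
                prop = lo + (lo - prop) if prop < lo else hi - (prop - hi)
            I_new = mi_of(prop)
            if math.log(rng.random()) < N * (I_new - I_cur) * _LN2:
                la, I_cur = prop, I_new
                if it >= self.n_burnin:
                    accepted += 1
            if it >= self.n_burnin:
                samples.append(la)

        log_samples = np.array(samples)
        alphas = np.exp(log_samples)
        self.alpha_ = float(alphas.mean())
        self.alpha_sd_ = float(alphas.std())
        self.log_alpha_sd_ = float(log_samples.std())
        self.acceptance_rate_ = accepted / max(len(samples), 1)
        self.mutual_information_ = mi_of(math.log(self.alpha_))
        # two failure signatures of a dataset without energy-dependent signal:
        # the posterior stays prior-wide, or the chain pins itself to noise —
        # detectable because the achieved MI never rises above the
        # finite-sample noise floor of the histogram estimator
        prior_sd = (hi - lo) / math.sqrt(12.0)
        noise_floor = (mi_bins * (n_expr - 1)) / (2.0 * N * _LN2)
        self.identifiable_ = (self.log_alpha_sd_ < 0.5 * prior_sd
                              and self.mutual_information_ > 5.0 * noise_floor)
        return self


def infer_scaling_factor(
    ds: SortSeqDataset,
    m: EnergyMatrix,
    fixed: ThermoParams,
    cfg: MCMCConfig = MCMCConfig(n_iterations=3000, n_burnin=1000),
    offset_wt: float = -15.3,
) -> tuple[float, float]:
    """Posterior mean and sd of α from a Sort-Seq dataset (functional wrapper)."""
    est = ScalingFactorMCMC(
        matrix=m, thermo=fixed, offset_wt=offset_wt,
        n_iterations=cfg.n_iterations, n_burnin=cfg.n_burnin,
        proposal_sd=max(cfg.proposal_sd, 0.05), mi_bins=cfg.mi_bins,
        random_state=cfg.seed,
    ).fit(ds.codes, ds.bins, sample_weight=ds.counts)
    if not est.identifiable_:
        warnings.warn("scaling factor poorly identified: posterior is prior-wide",
                      stacklevel=2)
    return est.alpha_, est.alpha_sd_


# -- alternative scaling routes --------------------------------------------


def scale_by_least_squares(m: EnergyMatrix, anchors: Sequence[tuple[str, float]]
                           ) -> tuple[float, float]:
    """OLS fit of known binding energies against matrix scores.

    ``anchors`` are (sequence, Δε_R in kBT) pairs; returns (α, Δε_wt) so that
    Δε_R ≈ α·ε_mat + Δε_wt.
    """
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchor sequences")
    scores = np.array([m.score(seq) for seq, _ in anchors])
    energies = np.array([e for _, e in anchors], dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("all anchors share one matrix score: slope is singular")
    A = np.vstack([scores, np.ones_like(scores)]).T
    (alpha, offset), *_ = np.linalg.lstsq(A, energies, rcond=None)
    return float(alpha), float(offset)


def scale_by_theoretical_penalty(m: EnergyMatrix, target_mean_penalty: float) -> float:
    """α chosen so the mean single-mutant entry equals a theoretical penalty (kBT)."""
    if m.gauge != "reference" or m.reference_seq is None:
        raise ValueError("matrix must be in reference gauge")
    ref = encode(m.reference_seq)
    mask = np.ones_like(m.values, dtype=bool)
    mask[np.arange(len(m)), ref] = False
    mean_penalty = m.values[mask].mean()
    if mean_penalty == 0:
        raise ValueError("mean single-mutant score is 0: scaling undefined")
    return float(target_mean_penalty / mean_penalty)


# -- base-preference statistics --------------------------------------------


@dataclass
class BasePreferenceResult:
    anova_p: float
    pairwise: pd.DataFrame  # columns A, B, pval
    preferred_base: Optional[str]
    probabilities: pd.DataFrame  # replicate × base probabilities at the position


def base_preference_test(replicate_matrices: Sequence[EnergyMatrix], position: int
                         ) -> BasePreferenceResult:
    """Is one base significantly preferred at a position, across replicates?

    Per replicate matrix, Boltzmann base probabilities are computed at the
    position; a one-way Welch ANOVA across the four bases gates (p < 0.01)
    a Games–Howell post-hoc comparison, and a base is declared preferred only
    if it is the most probable and beats every other base pairwise (p < 0.05).
    """
    import pingouin as pg

    if len(replicate_matrices) < 3:
        raise ValueError("need at least 3 replicate matrices")
    probs = np.array([
        base_probabilities(m).probs[position] for m in replicate_matrices
    ])  # (k, 4)
    k = probs.shape[0]
    df = pd.DataFrame({
        "prob": probs.ravel(),
        "base": np.tile(list(ALPHABET), k),
    })
    prob_table = pd.DataFrame(probs, columns=list(ALPHABET))

    group_vars = probs.var(axis=0, ddof=1)
    group_means = probs.mean(axis=0)
    if np.allclose(group_vars, 0.0):
        # degenerate: identical replicates; decide on the means alone
        if np.allclose(group_means, group_means[0]):
            pairwise = pd.DataFrame({"A": [], "B": [], "pval": []})
            return BasePreferenceResult(1.0, pairwise, None, prob_table)
        top = int(np.argmax(group_means))
        rows = [{"A": ALPHABET[top], "B": b, "pval": 0.0}
                for j, b in enumerate(ALPHABET) if j != top]
        return BasePreferenceResult(0.0, pd.DataFrame(rows), ALPHABET[top], prob_table)

    anova = pg.welch_anova(data=df, dv="prob", between="base")
    p_col = "p_unc" if "p_unc" in anova.columns else "p-unc"
    anova_p = float(anova[p_col].iloc[0])
    gh = pg.pairwise_gameshowell(data=df, dv="prob", between="base")
    pairwise = gh[["A", "B", "pval"]].copy()

    preferred = None
    if anova_p < 0.01:
        top = ALPHABET[int(np.argmax(group_means))]
        beats_all = True
        for _, row in pairwise.iterrows():
            if top in (row["A"], row["B"]) and row["pval"] >= 0.05:
                beats_all = False
                break
        if beats_all:
            preferred = top
    return BasePreferenceResult(anova_p, pairwise, preferred, prob_table)
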