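"""Synthetic Sort-Seq data with the statistical structure the inference assumes.

The generator emulates the experimental workflow end to end: a wild-type
operator is mutagenized at ~10% per base, each variant's expression is set
proportional to the RNAP occupancy p_bound (with the variant's repressor
binding energy read off a ground-truth additive matrix), multiplicative
log-normal noise mimics cell-to-cell fluorescence variability, and cells are
sorted into four FACS gates placed at quantiles of the pooled expression
histogram, each gate covering ~15% of cells with the inter-gate cells
discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import SortSeqDataset
from .energy_matrix import EnergyMatrix
from .sequences import O1, encode, encode_many, validate_sequence
from .thermo import ThermoParams, fold_change_simple


@dataclass
class SimulationConfig:
    """Study conditions for a simulated Sort-Seq experiment.

    Defaults mirror the experimental protocol: a 21-bp operator (O1)
    mutagenized at 10% per base, 10^4 library variants, four sorting gates
    each covering 15% of the expression histogram, and multiplicative
    log-normal expression noise with CV 0.3 (a stand-in for unquantified
    cell-to-cell variability).
    """

    reference_seq: str = O1
    mutation_rate: float = 0.10
    n_variants: int = 10_000
    n_bins: int = 4
    gate_fraction: float = 0.15
    noise_cv: float = 0.3
    thermo: ThermoParams = field(default_factory=ThermoParams)
    mean_penalty: float = 2.0
    true_alpha: float = 1.5
    offset_wt: float = -15.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must lie in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_bins * self.gate_fraction > 1.0 + 1e-12:
            raise ValueError("total gate coverage exceeds the histogram")
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        self.reference_seq = validate_sequence(self.reference_seq)


def make_ground_truth_matrix(L: int, mean_penalty: float = 2.0, seed: int = 0,
                             reference_seq: Optional[str] = None,
                             beneficial_fraction: float = 0.10) -> EnergyMatrix:
    """Reference-gauge truth matrix with mostly penalizing single mutants.

    Non-reference entries are gamma-distributed penalties (positive kBT), a
    random ~10% of which are flipped to beneficial (negative), mirroring a
    strong operator where the majority of available mutations weaken binding.
    The realized mean of the non-reference entries equals ``mean_penalty`` in
    expectation.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    if reference_seq is None:
        ref_codes = rng.integers(0, 4, size=L)
    else:
        ref_codes = encode(reference_seq)
        if ref_codes.size != L:
            raise ValueError("reference_seq length != L")
    sign = np.where(rng.random((L, 4)) < beneficial_fraction, -1.0, 1.0)
    # scale chosen so E[entry] = mean_penalty given the sign flips
    magnitude_mean = mean_penalty / (1.0 - 2.0 * beneficial_fraction)
    shape = 2.0
    mags = rng.gamma(shape, magnitude_mean / shape, size=(L, 4))
    values = sign * mags
    values[np.arange(L), ref_codes] = 0.0
    ref = reference_seq if reference_seq is not None else "".join(
        "ACGT"[c] for c in ref_codes)
    return EnergyMatrix(values, units="kBT", gauge="reference", reference_seq=ref)


def mutagenize(ref: str, rate: float, n_variants: int, seed: int = 0) -> np.ndarray:
    """Integer-coded library: each base independently substituted with
    probability ``rate``, uniformly among the three alternatives."""
    if not 0 < rate < 1:
        raise ValueError("rate must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ref_codes = encode(ref)
    L = ref_codes.size
    codes = np.tile(ref_codes, (n_variants, 1))
    hit = rng.random((n_variants, L)) < rate
    # offset 1..3 from the reference base, mod 4, is uniform over alternatives
    offsets = rng.integers(1, 4, size=(n_variants, L))
    codes[hit] = (codes[hit] + offsets[hit]) % 4
    return codes.astype(np.int8)


def gate_windows(n_bins: int, gate_fraction: float) -> list[tuple[float, float]]:
    """Quantile windows of the sorting gates, spread evenly over [0.05, 0.95]."""
    span = 0.90
    covered = n_bins * gate_fraction
    gap = (span - covered) / (n_bins - 1) if n_bins > 1 else 0.0
    if gap < 0:
        span, gap = covered, 0.0
    start = 0.5 - span / 2
    return [(start + i * (gate_fraction + gap),
             start + i * (gate_fraction + gap) + gate_fraction)
            for i in range(n_bins)]


def simulate_sorting(
    variants: np.ndarray,
    truth: EnergyMatrix,
    tp: ThermoParams,
    noise_cv: float = 0.3,
    gates: Optional[Sequence[tuple[float, float]]] = None,
    seed: int = 0,
    n_bins: int = 4,
    gate_fraction: float = 0.15,
    offset_wt: float = -15.3,
) -> SortSeqDataset:
    """Sort a library into expression bins under the occupancy model.

    Per variant: Δε_R = truth score + Δε_wt; expression = p_bound × LogNormal
    noise with the given CV; gate boundaries are quantiles of the pooled
    expression histogram; cells falling between gates are discarded.
    """
    if truth.units != "kBT":
        raise ValueError("truth matrix must be in kBT units")
    rng = np.random.default_rng(seed)
    eps_R = truth.score_many(variants) + offset_wt
    pol = (tp.P / tp.N_NS) * math.exp(-tp.eps_P)
    rep = (tp.heads_per_repressor * tp.R / tp.N_NS) * np.exp(-eps_R)
    pb = pol / (1.0 + pol + rep)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=pb.size)
    else:
        noise = 1.0
    expr = pb * noise
    if np.ptp(expr) == 0:
        raise ValueError("degenerate expression distribution: gates undefined")
    if gates is None:
        gates = gate_windows(n_bins, gate_fraction)
    edges = [(np.quantile(expr, lo), np.quantile(expr, hi)) for lo, hi in gates]
    bins = np.full(expr.size, -1, dtype=np.int64)
    for b, (lo_e, hi_e) in enumerate(edges):
        inside = (expr >= lo_e) & (expr <= hi_e) & (bins == -1)
        bins[inside] = b
    keep = bins >= 0
    return SortSeqDataset(
        codes=variants[keep],
        bins=bins[keep],
        counts=np.ones(int(keep.sum()), dtype=np.int64),
        n_bins=len(gates),
        reference_seq=truth.reference_seq,
    )


def simulate_experiment(cfg: SimulationConfig) -> tuple[SortSeqDataset, EnergyMatrix]:
    """Full pipeline: truth matrix → library → sorted dataset.

    Returns the dataset and the kBT ground-truth matrix. The matching
    arbitrary-unit matrix is ``truth.values / cfg.true_alpha``.
    """
    rng = np.random.default_rng(cfg.seed)
    s_matrix, s_lib, s_sort = rng.integers(0, 2**31 - 1, size=3)
    truth = make_ground_truth_matrix(
        len(cfg.reference_seq), mean_penalty=cfg.mean_penalty,
        seed=int(s_matrix), reference_seq=cfg.reference_seq)
    lib = mutagenize(cfg.reference_seq, cfg.mutation_rate, cfg.n_variants,
                     seed=int(s_lib))
    ds = simulate_sorting(
        lib, truth, cfg.thermo, noise_cv=cfg.noise_cv, seed=int(s_sort),
        n_bins=cfg.n_bins, gate_fraction=cfg.gate_fraction,
        offset_wt=cfg.offset_wt)
    return ds, truth


def make_titration(
    eps_R: float,
    R_values: Sequence[float],
    noise_cv: float = 0.1,
    n_reps: int = 1,
    seed: int = 0,
    N_NS: float = 4.6e6,
) -> list[tuple[float, float]]:
    """Simulated repressor titration: (R, fold-change) points around the
    thermodynamic curve with multiplicative log-normal noise."""
    R_values = list(R_values)
    if not R_values:
        raise ValueError("R_values must be nonempty")
    if any(r <= 0 for r in R_values):
        raise ValueError("R = 0 is the fold-change normalizer, not a data point")
    rng = np.random.default_rng(seed)
    out: list[tuple[float, float]] = []
    for _ in range(n_reps):
        for r in R_values:
            fc = fold_change_simple(r, eps_R, N_NS)
            if noise_cv > 0:
                sigma = math.sqrt(math.log(1.0 + noise_cv**2))
                fc *= rng.lognormal(-0.5 * sigma**2, sigma)
            out.append((float(r), float(fc)))
    return out
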