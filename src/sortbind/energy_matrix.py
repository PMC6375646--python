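"""Linear sequence-to-energy matrices.

An :class:`EnergyMatrix` assigns an additive energy contribution to each base
at each position of a fixed-length binding site; the energy of a sequence is
the sum of its L indexed cells. A linear model is only defined up to an
additive constant per position (and, when inferred from ranked data alone, an
overall scale), so matrices carry a *gauge*:

``reference``
    cells of the reference (wild-type) sequence are pinned to 0, so every
    entry reads as the energetic effect of a single point mutation;
``position_mean``
    each position's four entries sum to zero — the convention used when
    comparing matrices from different reference sequences.

Arbitrary-unit matrices become absolute-energy matrices through the affine
map Δε = α·ε_mat + Δε_wt, with α in kBT per arbitrary unit and Δε_wt the
binding energy of the reference sequence in kBT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .sequences import ALPHABET, encode, encode_many, validate_sequence

_GAUGES = ("reference", "position_mean", "none")
_UNITS = ("arbitrary", "kBT")


@dataclass
class EnergyMatrix:
    """L×4 additive energy model (columns A, C, G, T).

    Parameters
    ----------
    values : (L, 4) float array
    units : "arbitrary" or "kBT"
    gauge : "reference", "position_mean" or "none"
    reference_seq : wild-type sequence the matrix entries are relative to
    alpha : scaling factor to kBT per arbitrary unit, if known
    offset_wt : binding energy of the reference sequence in kBT, if known
    """

    values: np.ndarray
    units: str = "arbitrary"
    gauge: str = "none"
    reference_seq: Optional[str] = None
    alpha: Optional[float] = None
    offset_wt: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError(f"matrix must be L x 4, got shape {self.values.shape}")
        if self.units not in _UNITS:
            raise ValueError(f"units must be one of {_UNITS}, got {self.units!r}")
        if self.gauge not in _GAUGES:
            raise ValueError(f"gauge must be one of {_GAUGES}, got {self.gauge!r}")
        if self.reference_seq is not None:
            self.reference_seq = validate_sequence(self.reference_seq)
            if len(self.reference_seq) != len(self):
                raise ValueError(
                    f"reference sequence length {len(self.reference_seq)} != matrix length {len(self)}"
                )

    def __len__(self) -> int:
        return self.values.shape[0]

    # -- scoring -----------------------------------------------------------

    def score(self, seq: str) -> float:
        """ε_mat: sum of the matrix cells indexed by ``seq`` (matrix units)."""
        codes = encode(seq)
        if codes.size != len(self):
            raise ValueError(f"sequence length {codes.size} != matrix length {len(self)}")
        return float(self.values[np.arange(len(self)), codes].sum())

    def score_many(self, seqs) -> np.ndarray:
        """Vectorized :meth:`score` for a list of sequences or an (n, L) code array."""
        codes = seqs if isinstance(seqs, np.ndarray) else encode_many(seqs)
        if codes.shape[1] != len(self):
            raise ValueError(f"sequence length {codes.shape[1]} != matrix length {len(self)}")
        return self.values[np.arange(len(self))[None, :], codes].sum(axis=1)

    def predict_binding_energy(self, seq: str) -> float:
        """Absolute binding energy Δε = α·ε_mat + Δε_wt in kBT.

        A kBT matrix's values already include the scale α, so only the
        reference offset Δε_wt is added; a matrix constructed directly in
        absolute kBT (offset_wt unset) scores as-is. A reference-gauge matrix
        therefore assigns its own reference sequence exactly Δε_wt.
        """
        if self.units == "kBT":
            return self.score(seq) + (self.offset_wt or 0.0)
        if self.alpha is None or self.offset_wt is None:
            raise ValueError("matrix lacks alpha/offset_wt; scale it first (see to_kbt)")
        return self.alpha * self.score(seq) + self.offset_wt

    # -- gauge and units ---------------------------------------------------

    def fix_gauge(self, mode: str) -> "EnergyMatrix":
        """Return a gauge-fixed copy; pairwise score differences are preserved."""
        if mode == "reference":
            if self.reference_seq is None:
                raise ValueError("reference gauge requires reference_seq")
            ref_codes = encode(self.reference_seq)
            shift = self.values[np.arange(len(self)), ref_codes]
        elif mode == "position_mean":
            shift = self.values.mean(axis=1)
        else:
            raise ValueError(f"unknown gauge mode {mode!r}")
        return replace(self, values=self.values - shift[:, None], gauge=mode)

    def to_kbt(self, alpha: float, offset_wt: float) -> "EnergyMatrix":
        """Scale an arbitrary-unit matrix into kBT via Δε = α·ε_mat + Δε_wt."""
        if self.units != "arbitrary":
            raise ValueError("matrix is already in kBT units")
        if alpha == 0:
            raise ValueError("alpha must be nonzero (degenerate scaling)")
        return replace(
            self,
            values=self.values * alpha,
            units="kBT",
            alpha=float(alpha),
            offset_wt=float(offset_wt),
        )

    def check_gauge(self, atol: float = 1e-9) -> bool:
        """Whether the stored values satisfy the declared gauge invariant."""
        if self.gauge == "reference":
            if self.reference_seq is None:
                return False
            ref_codes = encode(self.reference_seq)
            return bool(np.allclose(self.values[np.arange(len(self)), ref_codes], 0.0, atol=atol))
        if self.gauge == "position_mean":
            return bool(np.allclose(self.values.sum(axis=1), 0.0, atol=atol))
        return True


# -- base probabilities and logos ------------------------------------------


@dataclass
class BaseProbabilities:
    """Boltzmann base probabilities per position plus information content (bits)."""

    probs: np.ndarray  # (L, 4), rows sum to 1
    information: np.ndarray = field(default=None)  # (L,), bits

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.information is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(self.probs > 0, self.probs * np.log2(self.probs), 0.0)
            self.information = 2.0 + plogp.sum(axis=1)

    @property
    def letter_heights(self) -> np.ndarray:
        """(L, 4) heights for an information logo: p_N × information(bits)."""
        return self.probs * self.information[:, None]


def base_probabilities(m: EnergyMatrix) -> BaseProbabilities:
    """Boltzmann weights per position: prob_N = e^(−ε_N) / Σ_M e^(−ε_M).

    Invariant under per-position additive shifts, hence gauge-independent.
    The per-position minimum is subtracted before exponentiating to guard
    against overflow.
    """
    v = m.values - m.values.min(axis=1, keepdims=True)
    w = np.exp(-v)
    return BaseProbabilities(probs=w / w.sum(axis=1, keepdims=True))


def information_logo(p: BaseProbabilities) -> np.ndarray:
    """Per-position letter heights in bits (Schneider-style, no small-sample correction)."""
    return p.letter_heights


# -- comparison ------------------------------------------------------------


def compare_matrices(m1: EnergyMatrix, m2: EnergyMatrix) -> float:
    """Pearson r between two matrices over all L×4 cells.

    Both matrices are first put in position-mean gauge so the comparison is
    convention-free. A constant matrix has no defined correlation: NaN is
    returned with a warning.
    """
    if m1.values.shape != m2.values.shape:
        raise ValueError(f"shape mismatch: {m1.values.shape} vs {m2.values.shape}")
    a = m1.fix_gauge("position_mean").values.ravel()
    b = m2.fix_gauge("position_mean").values.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant matrix: Pearson correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def mean_matrix(matrices: Iterable[EnergyMatrix], gauge: str = "position_mean") -> EnergyMatrix:
    """Cell-wise mean of replicate matrices, in a common gauge."""
    ms = [m.fix_gauge(gauge) if gauge != "none" else m for m in matrices]
    if not ms:
        raise ValueError("no matrices given")
    vals = np.mean([m.values for m in ms], axis=0)
    first = ms[0]
    return EnergyMatrix(
        vals, units=first.units, gauge=gauge, reference_seq=first.reference_seq
    )


# -- TSV round-trip --------------------------------------------------------


def write_matrix_tsv(path, m: EnergyMatrix) -> None:
    """Write ``# key=value`` metadata lines, a ``pos A C G T`` header, then rows."""
    lines = [f"# units={m.units}", f"# gauge={m.gauge}"]
    if m.reference_seq is not None:
        lines.append(f"# reference={m.reference_seq}")
    if m.alpha is not None:
        lines.append(f"# alpha={m.alpha!r}")
    if m.offset_wt is not None:
        lines.append(f"# offset_wt={m.offset_wt!r}")
    lines.append("pos\t" + "\t".join(ALPHABET))
    for i, row in enumerate(m.values, start=1):
        lines.append(f"{i}\t" + "\t".join(repr(float(x)) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix_tsv(path) -> EnergyMatrix:
    """Read a matrix TSV written by :func:`write_matrix_tsv`.

    The explicit ``pos A C G T`` header is required; files with a permuted
    column order are re-ordered to A,C,G,T on read.
    """
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split("\t")
        if header is None:
            header = [p.strip() for p in parts]
            if header[0].lower() != "pos" or sorted(header[1:]) != sorted(ALPHABET):
                raise ValueError(
                    f"{path}: line {lineno}: expected header 'pos A C G T', got {header}"
                )
            continue
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: malformed row: {raw!r}") from exc
    if header is None or not rows:
        raise ValueError(f"{path}: no matrix rows found")
    order = [header[1:].index(b) for b in ALPHABET]
    values = np.asarray(rows, dtype=float)[:, order]
    return EnergyMatrix(
        values,
        units=meta.get("units", "arbitrary"),
        gauge=meta.get("gauge", "none"),
        reference_seq=meta.get("reference"),
        alpha=float(meta["alpha"]) if "alpha" in meta else None,
        offset_wt=float(meta["offset_wt"]) if "offset_wt" in meta else None,
    )


# module-level functional aliases matching the rest of the API
def score_sequence(m: EnergyMatrix, seq: str) -> float:
    return m.score(seq)


def fix_gauge(m: EnergyMatrix, mode: str) -> EnergyMatrix:
    return m.fix_gauge(mode)


def to_kbt(m: EnergyMatrix, alpha: float, offset_wt: float) -> EnergyMatrix:
    return m.to_kbt(alpha, offset_wt)
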