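"""Prediction evaluation: mutant binding energies, error by mutation count.

Predictions come from replicate kBT-scaled matrices: each replicate yields
Δε_R = α·ε_mat + Δε_wt for a mutant, and the replicate spread gives the
prediction uncertainty. Errors against measured energies are stratified by
the number of mutations relative to the matrix's reference sequence.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .energy_matrix import EnergyMatrix
from .sequences import O1, hamming_distance

_BENCHMARK_FILE = "lac_o1_mutant_energies.tsv"
_BENCHMARK_SHA256 = "091a5ed93a0e73b42e03d1dcd7668b13a0dc9e6e521ef71036342e5dee8c9e49"


@dataclass
class PredictionRecord:
    """One mutant's predicted vs measured binding energy (kBT)."""

    sequence: str
    n_mut: int
    predicted: float
    predicted_sd: Optional[float] = None
    measured: Optional[float] = None
    measured_ci: Optional[tuple[float, float]] = None

    @property
    def abs_error(self) -> float:
        if self.measured is None:
            raise ValueError("no measured energy for this record")
        return abs(self.predicted - self.measured)


def predict_energy(replicates: Sequence[EnergyMatrix], seq: str
                   ) -> tuple[float, Optional[float]]:
    """Mean and sample sd of Δε_R predictions over replicate kBT matrices.

    With a single replicate the sd is reported as ``None`` (absent), not 0.
    """
    if not replicates:
        raise ValueError("no replicate matrices given")
    vals = np.array([m.predict_binding_energy(seq) for m in replicates])
    sd = float(vals.std(ddof=1)) if vals.size > 1 else None
    return float(vals.mean()), sd


def predict_records(replicates: Sequence[EnergyMatrix], seqs: Sequence[str],
                    reference: Optional[str] = None) -> list[PredictionRecord]:
    ref = reference or replicates[0].reference_seq
    out = []
    for s in seqs:
        mean, sd = predict_energy(replicates, s)
        out.append(PredictionRecord(s, hamming_distance(s, ref), mean, sd))
    return out


def error_by_mutation_count(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Median/quartile absolute prediction error per mutation count.

    Returns a DataFrame indexed by n_mut with columns median, q1, q3, n.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame({
        "n_mut": [r.n_mut for r in records],
        "abs_error": [r.abs_error for r in records],
    })
    g = df.groupby("n_mut")["abs_error"]
    return pd.DataFrame({
        "median": g.median(),
        "q1": g.quantile(0.25),
        "q3": g.quantile(0.75),
        "n": g.size(),
    })


def load_lac_mutant_benchmark() -> list[PredictionRecord]:
    """The packaged 26-mutant lac operator benchmark (predicted vs measured Δε_R).

    The fixture is checksummed, and each row's mutation count is recomputed
    from the sequence against O1 and validated against the stored 1/2/3-bp
    class; any discrepancy raises.
    """
    data = resources.files("sortbind.data").joinpath(_BENCHMARK_FILE).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _BENCHMARK_SHA256:
        raise ValueError(
            f"benchmark fixture checksum mismatch: {digest} != {_BENCHMARK_SHA256}")
    from io import StringIO

    df = pd.read_csv(StringIO(data.decode()), sep="\t", comment="#")
    records = []
    for row in df.itertuples(index=False):
        n_mut = hamming_distance(row.sequence, O1)
        if n_mut != int(row.n_mut_class):
            raise ValueError(
                f"{row.sequence}: computed {n_mut} mutations but fixture "
                f"class says {row.n_mut_class}")
        records.append(PredictionRecord(
            sequence=row.sequence, n_mut=n_mut,
            predicted=float(row.predicted_kbt), measured=float(row.measured_kbt)))
    if len(records) != 26:
        raise ValueError(f"expected 26 benchmark rows, got {len(records)}")
    return records


def write_prediction_report(path_tsv, path_json, records: Sequence[PredictionRecord]) -> None:
    """TSV of per-record predictions plus a JSON summary of per-class medians."""
    rows = []
    for r in records:
        rows.append({
            "sequence": r.sequence, "n_mut": r.n_mut,
            "predicted_kbt": r.predicted,
            "predicted_sd": "" if r.predicted_sd is None else r.predicted_sd,
            "measured_kbt": "" if r.measured is None else r.measured,
        })
    pd.DataFrame(rows).to_csv(path_tsv, sep="\t", index=False)
    measured = [r for r in records if r.measured is not None]
    summary = {}
    if measured:
        table = error_by_mutation_count(measured)
        summary = {
            "overall_median_abs_error_kbt": float(np.median([r.abs_error for r in measured])),
            "per_class_median_abs_error_kbt": {
                str(k): float(v) for k, v in table["median"].items()},
        }
    Path(path_json).write_text(json.dumps(summary, indent=2) + "\n")
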