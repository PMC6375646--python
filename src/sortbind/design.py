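"""Design of operator mutants targeting induction phenotypes.

Enumerates point mutants of a reference operator, predicts each mutant's
binding energy from a kBT-scaled matrix, computes the induction phenotypes
(leakiness, saturation, dynamic range, EC50) under the allosteric model, and
ranks mutants by distance to a requested phenotype target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

from .energy_matrix import EnergyMatrix
from .sequences import ALPHABET, validate_sequence
from .thermo import AllosteryParams, InductionPhenotypes, N_NS_ECOLI, phenotypes


def enumerate_mutants(reference: str, max_mutations: int = 1) -> list[str]:
    """All sequences within ``max_mutations`` substitutions of the reference
    (excluding the reference itself). A 21-bp site has 63 single mutants."""
    ref = validate_sequence(reference)
    L = len(ref)
    out: list[str] = []
    for k in range(1, max_mutations + 1):
        for pos in combinations(range(L), k):
            alts = [[b for b in ALPHABET if b != ref[i]] for i in pos]
            stack = [[]]
            for choices in alts:
                stack = [prefix + [c] for prefix in stack for c in choices]
            for picks in stack:
                s = list(ref)
                for i, c in zip(pos, picks):
                    s[i] = c
                out.append("".join(s))
    return out


@dataclass
class DesignCandidate:
    sequence: str
    eps_R: float
    phenotypes: InductionPhenotypes
    distance: float


def design_induction(
    matrix: EnergyMatrix,
    targets: dict,
    ap: Optional[AllosteryParams] = None,
    R: float = 130.0,
    N_NS: float = N_NS_ECOLI,
    max_mutations: int = 1,
    top: int = 10,
) -> list[DesignCandidate]:
    """Rank operator mutants by distance to requested induction phenotypes.

    ``targets`` maps any of {"leakiness", "saturation", "dynamic_range",
    "ec50"} to desired values; distance is the root-mean-square of the
    per-phenotype deviations (EC50 compared on a log10 scale).
    """
    if matrix.units != "kBT":
        raise ValueError("matrix is in arbitrary units: scale it to kBT first")
    known = {"leakiness", "saturation", "dynamic_range", "ec50"}
    bad = set(targets) - known
    if bad:
        raise ValueError(f"unknown phenotype targets: {sorted(bad)}")
    ap = ap or AllosteryParams()
    candidates = []
    for seq in enumerate_mutants(matrix.reference_seq, max_mutations):
        eps = matrix.predict_binding_energy(seq)
        ph = phenotypes(ap, R, eps, N_NS)
        total = 0.0
        for key, want in targets.items():
            have = getattr(ph, key)
            if key == "ec50":
                if math.isnan(have):
                    total += 100.0
                else:
                    total += (math.log10(have) - math.log10(want)) ** 2
            else:
                total += (have - want) ** 2
        candidates.append(DesignCandidate(seq, eps, ph, math.sqrt(total / len(targets))))
    candidates.sort(key=lambda c: (c.distance, c.sequence))
    return candidates[:top]
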