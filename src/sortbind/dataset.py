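"""Sort-Seq dataset container and TSV round-trip.

A dataset is a table of (sequence, expression bin, count) records from a
FACS-sorted, sequenced reporter library, together with the number of sorting
bins and the reference (wild-type) operator the library was mutagenized from.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .sequences import decode, encode_many, validate_sequence


@dataclass
class SortSeqDataset:
    """(sequence, bin, count) records with bin count B and a reference sequence.

    ``codes`` is the (n, L) integer-encoded sequence array (A=0..T=3);
    ``bins`` the per-record expression bin in [0, n_bins); ``counts`` the
    number of sorted cells (or reads) carrying that sequence in that bin.
    """

    codes: np.ndarray
    bins: np.ndarray
    counts: np.ndarray
    n_bins: int
    reference_seq: Optional[str] = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.bins = np.asarray(self.bins, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if not (len(self.codes) == len(self.bins) == len(self.counts)):
            raise ValueError("codes, bins and counts must have equal length")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if len(self.bins) and (self.bins.min() < 0 or self.bins.max() >= self.n_bins):
            raise ValueError(f"bin index out of range [0, {self.n_bins})")
        if np.any(self.counts <= 0):
            raise ValueError("counts must be positive")
        if self.reference_seq is not None:
            self.reference_seq = validate_sequence(self.reference_seq)

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.codes]

    @classmethod
    def from_records(cls, records, n_bins: int, reference_seq: Optional[str] = None
                     ) -> "SortSeqDataset":
        """Build from an iterable of (sequence, bin, count) triples."""
        records = list(records)
        seqs = [r[0] for r in records]
        bins = [r[1] for r in records]
        counts = [r[2] for r in records]
        return cls(encode_many(seqs), np.array(bins), np.array(counts), n_bins, reference_seq)

    def split_replicates(self, k: int = 3, seed: int = 0) -> list["SortSeqDataset"]:
        """Randomly partition the records into k disjoint, equal-size (±1) groups.

        The union of the groups is the input dataset; the partition is
        deterministic given the seed.
        """
        n = len(self)
        if n < k:
            raise ValueError(f"cannot split {n} records into {k} groups")
        perm = np.random.default_rng(seed).permutation(n)
        groups = np.array_split(perm, k)
        return [
            replace(self, codes=self.codes[idx], bins=self.bins[idx], counts=self.counts[idx])
            for idx in groups
        ]


def split_replicates(ds: SortSeqDataset, k: int = 3, seed: int = 0) -> list[SortSeqDataset]:
    return ds.split_replicates(k=k, seed=seed)


# -- TSV I/O ---------------------------------------------------------------


def write_dataset_tsv(path, ds: SortSeqDataset) -> None:
    lines = [f"# n_bins={ds.n_bins}"]
    if ds.reference_seq is not None:
        lines.append(f"# reference={ds.reference_seq}")
    lines.append("sequence\tbin\tcount")
    for row, b, c in zip(ds.codes, ds.bins, ds.counts):
        lines.append(f"{decode(row)}\t{int(b)}\t{int(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dataset_tsv(path) -> SortSeqDataset:
    meta: dict[str, str] = {}
    seqs: list[str] = []
    bins: list[int] = []
    counts: list[int] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        parts = line.split("\t")
        if not header_seen:
            if [p.lower() for p in parts[:3]] != ["sequence", "bin", "count"]:
                raise ValueError(f"{path}: line {lineno}: expected header 'sequence bin count'")
            header_seen = True
            continue
        if len(parts) != 3:
            raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
        try:
            seqs.append(parts[0])
            bins.append(int(parts[1]))
            counts.append(int(parts[2]))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: malformed row {raw!r}") from exc
    n_bins = int(meta.get("n_bins", 4))
    return SortSeqDataset.from_records(
        zip(seqs, bins, counts), n_bins=n_bins, reference_seq=meta.get("reference")
    )


def write_dataset_fastq(path, ds: SortSeqDataset) -> None:
    """Dump records as FASTQ (constant quality 'I'); bin and count in the read id."""
    with open(path, "w") as fh:
        for i, (row, b, c) in enumerate(zip(ds.codes, ds.bins, ds.counts)):
            seq = decode(row)
            fh.write(f"@record_{i}_bin{int(b)}_count{int(c)}\n{seq}\n+\n{'I' * len(seq)}\n")
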