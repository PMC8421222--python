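"""PCR-free barcode quantification of the standards pool.

The first 20 bases of each quantification read are mapped against a
barcode reference with a tolerance of at most two mismatches; the
resulting percent abundances are the "expected" denominator of the
observed/expected editing metric. With a barcode set at pairwise Hamming
distance >= 5 this threshold can never assign a read carrying <= 2 errors
to the wrong barcode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .schemes import hamming
from .simulate import AbundanceTable, FastqRecord

#: Assignment sentinels.
UNASSIGNED = "__unassigned__"
AMBIGUOUS = "__ambiguous__"


class BarcodeError(ValueError):
    pass


@dataclass
class BarcodeRef:
    """Barcode sequence -> construct id, all barcodes of equal length."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise BarcodeError("empty barcode reference")
        lengths = {len(b) for b in self.mapping}
        if len(lengths) != 1:
            raise BarcodeError(f"barcodes of unequal lengths: {sorted(lengths)}")
        ids = list(self.mapping.values())
        if len(set(ids)) != len(ids):
            raise BarcodeError("construct ids are not unique")
        if len(self.mapping) > 1 and self.min_distance() < 5:
            warnings.warn(
                f"minimum barcode distance {self.min_distance()} < 5; "
                "assignment at <=2 mismatches may be ambiguous",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.mapping)))

    def min_distance(self) -> int:
        codes = list(self.mapping)
        return min(
            hamming(a, b) for i, a in enumerate(codes) for b in codes[i + 1 :]
        )

    @classmethod
    def from_fasta(cls, path: str | Path, barcode_length: int = 20) -> "BarcodeRef":
        """Read a barcode reference FASTA; the first ``barcode_length``
        bases of each record are the barcode, the record id the construct."""
        from Bio import SeqIO

        mapping = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            barcode = str(rec.seq)[:barcode_length].upper()
            if len(barcode) < barcode_length:
                raise BarcodeError(
                    f"record {rec.id} shorter than barcode length {barcode_length}"
                )
            if barcode in mapping:
                raise BarcodeError(f"duplicate barcode for {rec.id}")
            mapping[barcode] = rec.id
        return cls(mapping)


@dataclass
class BarcodeCounts:
    """Assignment tallies; assigned + unassigned + ambiguous + truncated
    equals the number of reads processed."""

    counts: dict[str, int]
    unassigned: int = 0
    ambiguous: int = 0
    truncated: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned + self.ambiguous + self.truncated

    def to_frame(self) -> pd.DataFrame:
        total = self.assigned
        df = pd.DataFrame(
            {
                "construct_id": list(self.counts),
                "count": list(self.counts.values()),
            }
        )
        df["proportion"] = df["count"] / total if total else 0.0
        df["percent"] = 100.0 * df["proportion"]
        return df

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": ["assigned", "unassigned", "ambiguous", "truncated"],
                "count": [self.assigned, self.unassigned, self.ambiguous, self.truncated],
            }
        )


def assign_barcode(
    prefix: str, ref: BarcodeRef, max_mm: int = 2
) -> str:
    """Assign a read prefix to the unique barcode within ``max_mm``
    mismatches (N bases count as mismatches).

    Returns the construct id, or the :data:`UNASSIGNED` / :data:`AMBIGUOUS`
    sentinel. A tie at the minimal distance <= ``max_mm`` is ambiguous.
    """
    if len(prefix) != ref.length:
        raise BarcodeError(
            f"prefix length {len(prefix)} != barcode length {ref.length}"
        )
    prefix = prefix.upper()
    best, best_d, tie = None, max_mm + 1, False
    for barcode, cid in ref.mapping.items():
        d = hamming(prefix, barcode)
        if d < best_d:
            best, best_d, tie = cid, d, False
        elif d == best_d:
            tie = True
    if best is None:
        return UNASSIGNED
    return AMBIGUOUS if tie else best


def _encode(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def quantify_barcodes(
    reads: Union[Iterable[FastqRecord], str, Path],
    ref: BarcodeRef,
    max_mm: int = 2,
) -> tuple[BarcodeCounts, AbundanceTable]:
    """Count reads per barcode and derive the pool abundance table.

    ``reads`` is an iterable of (id, seq, qual) records or a FASTQ path.
    Reads shorter than the barcode are tallied as truncated; proportions
    are over assigned reads only.
    """
    if isinstance(reads, (str, Path)):
        from .simulate import read_fastq

        reads = read_fastq(reads)

    bc_len = ref.length
    barcodes = list(ref.mapping)
    ids = [ref.mapping[b] for b in barcodes]

    prefixes, truncated = [], 0
    for _, seq, _ in reads:
        if len(seq) < bc_len:
            truncated += 1
        else:
            prefixes.append(seq[:bc_len].upper())

    counts = {cid: 0 for cid in ids}
    unassigned = ambiguous = 0
    if prefixes:
        # vectorized Hamming distances: (n_reads, n_barcodes)
        read_mat = _encode(prefixes)
        ref_mat = _encode(barcodes)
        dists = (read_mat[:, None, :] != ref_mat[None, :, :]).sum(axis=2)
        best_d = dists.min(axis=1)
        n_at_best = (dists == best_d[:, None]).sum(axis=1)
        best_idx = dists.argmin(axis=1)
        for d, nb, bi in zip(best_d, n_at_best, best_idx):
            if d > max_mm:
                unassigned += 1
            elif nb > 1:
                ambiguous += 1
            else:
                counts[ids[bi]] += 1

    result = BarcodeCounts(
        counts=counts, unassigned=unassigned, ambiguous=ambiguous, truncated=truncated
    )
    if result.total == 0:
        raise BarcodeError("no reads processed")
    if result.assigned == 0:
        raise BarcodeError("no reads assigned; cannot form an abundance table")
    abundance = AbundanceTable.from_counts(counts)
    return result, abundance
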