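"""Per-position primer-edit profiling of amplicon reads.

Pipeline: 3'-adapter read-through is trimmed, pairs are merged by ungapped
overlap consensus, and the first L bases of each merged read (L = length of
the locus-specific primer, 19 for the V4 forward primer) are compared
position-by-position to the reference primer. Reads with more than three
mismatches over the primer region are excluded — a guard against indels,
which would otherwise smear a single event across many positions under
positional (Hamming) comparison. Passing reads contribute per-position,
per-base counts, from which two report tables are derived:

* observed/expected edits — the proportion of non-reference bases at each
  position divided by the proportion of pool templates carrying a variant
  there; ~1 means editing at that position is essentially complete, ~0
  means none.
* fold-of-expected amplification penalty — for the reciprocal
  variant-primer experiment, how far each variant primer's read share
  falls below its pool share.

Positions are reported by 3'-distance (1 = the primer's 3'-terminal base).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .schemes import BASES, IUPAC_CODES, PrimerScheme, base_matches, revcomp
from .simulate import AbundanceTable, FastqRecord
from .standards import ConstructSet, enumerate_variants


class ProfileError(ValueError):
    pass


# --------------------------------------------------------------------------
# adapter trimming


_SEED_LEN = 8
_TAIL_SCAN = 16


def trim_read_3prime(
    seq: str,
    qual: str,
    adapter: str,
    min_overlap: int = 3,
    max_error_frac: float = 0.1,
) -> tuple[str, str]:
    """Remove 3' adapter read-through from a single read.

    The adapter is given 5'->3' as it appears when the sequencer reads
    through the fragment end. The earliest position whose suffix matches
    the adapter prefix with >= ``min_overlap`` overlap and a mismatch
    fraction <= ``max_error_frac`` is trimmed; reads without a match pass
    unchanged. Candidate positions come from exact 8-mer seed hits of the
    adapter (two seed frames, so one mismatch in the first frame cannot
    hide a hit) plus an exhaustive scan of the last few bases for short
    partial read-through.
    """
    n, m = len(seq), len(adapter)
    if n < min_overlap or m < min_overlap:
        return seq, qual

    candidates: set[int] = set()
    if m >= _SEED_LEN:
        for seed_off in (0, _SEED_LEN):
            if seed_off + _SEED_LEN > m:
                break
            seed = adapter[seed_off : seed_off + _SEED_LEN]
            idx = seq.find(seed)
            while idx != -1:
                if idx - seed_off >= 0:
                    candidates.add(idx - seed_off)
                idx = seq.find(seed, idx + 1)
    else:
        idx = seq.find(adapter)
        while idx != -1:
            candidates.add(idx)
            idx = seq.find(adapter, idx + 1)
    # short suffix overlaps near the read end
    candidates.update(range(max(0, n - _TAIL_SCAN), n - min_overlap + 1))

    for start in sorted(candidates):
        if start > n - min_overlap:
            continue
        olen = min(n - start, m)
        mismatches = sum(
            1 for a, b in zip(seq[start : start + olen], adapter[:olen]) if a != b
        )
        if mismatches <= max_error_frac * olen:
            return seq[:start], qual[:start]
    return seq, qual


def trim_adapters(
    r1: Iterable[FastqRecord],
    r2: Iterable[FastqRecord],
    scheme: PrimerScheme,
    min_overlap: int = 3,
    max_error_frac: float = 0.1,
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Trim adapter read-through from both mates of each pair.

    Read-through on R1 runs into the reverse complement of the reverse
    adapter tail; on R2 into the reverse complement of the forward tail.
    """
    ad1, ad2 = revcomp(scheme.rev_tail), revcomp(scheme.fwd_tail)
    out1, out2 = [], []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1, r2):
        s1, q1 = trim_read_3prime(s1, q1, ad1, min_overlap, max_error_frac)
        s2, q2 = trim_read_3prime(s2, q2, ad2, min_overlap, max_error_frac)
        out1.append((id1, s1, q1))
        out2.append((id2, s2, q2))
    return out1, out2


# --------------------------------------------------------------------------
# pair merging


def merge_pair(
    r1: FastqRecord,
    r2: FastqRecord,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> Optional[FastqRecord]:
    """Merge one read pair by best ungapped overlap; None when no
    admissible overlap exists.

    R2 is reverse-complemented, the overlap with the minimal mismatch
    fraction is chosen (ties to the longest overlap), and conflicting
    bases take the higher-quality call. Merged length is
    ``len1 + len2 - overlap``.
    """
    id1, s1, q1 = r1
    _, s2, q2 = r2
    s2rc = revcomp(s2)
    q2rc = q2[::-1]
    n1, n2 = len(s1), len(s2rc)
    max_o = min(n1, n2)
    if max_o < min_overlap:
        return None

    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2rc.encode(), dtype=np.uint8)
    best_o, best_frac = None, None
    for o in range(max_o, min_overlap - 1, -1):
        mism = int(np.count_nonzero(a1[n1 - o :] != a2[:o]))
        frac = mism / o
        if best_frac is None or frac < best_frac:
            best_o, best_frac = o, frac
            if frac == 0.0:
                break  # cannot improve; longest zero-mismatch overlap wins
    if best_frac is None or best_frac > max_mismatch_frac:
        return None

    o = best_o
    left_s, left_q = s1[: n1 - o], q1[: n1 - o]
    right_s, right_q = s2rc[o:], q2rc[o:]
    ov_s, ov_q = [], []
    for i in range(o):
        b1, c1 = s1[n1 - o + i], q1[n1 - o + i]
        b2, c2 = s2rc[i], q2rc[i]
        if b1 == b2:
            ov_s.append(b1)
            ov_q.append(max(c1, c2))
        elif c1 >= c2:
            ov_s.append(b1)
            ov_q.append(c1)
        else:
            ov_s.append(b2)
            ov_q.append(c2)
    return (id1, left_s + "".join(ov_s) + right_s, left_q + "".join(ov_q) + right_q)


def merge_pairs(
    r1: Iterable[FastqRecord],
    r2: Iterable[FastqRecord],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[FastqRecord], int]:
    """Merge all pairs; returns (merged records, number unmerged)."""
    merged, unmerged = [], 0
    for rec1, rec2 in zip(r1, r2):
        m = merge_pair(rec1, rec2, min_overlap, max_mismatch_frac)
        if m is None:
            unmerged += 1
        else:
            merged.append(m)
    return merged, unmerged


# --------------------------------------------------------------------------
# edit matrix

_BASE_COLS = ["A", "C", "G", "T", "N"]
_BASE_TO_COL = {b: i for i, b in enumerate(_BASE_COLS)}


@dataclass
class EditMatrix:
    """Per-position, per-base counts over the primer region of passing
    reads. Rows are 5'-based positions 1..L; every row sums to
    ``reads_pass_filter``."""

    reference: str
    counts: np.ndarray  # (L, 5) int
    reads_pass_filter: int
    reads_failed_filter: int
    reads_short: int

    @property
    def length(self) -> int:
        return len(self.reference)

    @property
    def reads_evaluated(self) -> int:
        return self.reads_pass_filter + self.reads_failed_filter + self.reads_short

    def nonref_proportions(self) -> np.ndarray:
        """Proportion of non-reference bases per 5'-position; NaN at
        degenerate reference positions (no single reference base) and when
        no reads pass."""
        out = np.full(self.length, np.nan)
        if self.reads_pass_filter == 0:
            return out
        for i, ref in enumerate(self.reference):
            if ref not in BASES:
                continue
            ref_count = self.counts[i, _BASE_TO_COL[ref]]
            out[i] = 1.0 - ref_count / self.reads_pass_filter
        return out

    def nonref_at_3prime_distance(self, pos: int) -> float:
        """Non-reference proportion at 3'-distance ``pos`` (1 = terminal)."""
        return float(self.nonref_proportions()[self.length - pos])

    def to_frame(self) -> pd.DataFrame:
        nonref = self.nonref_proportions()
        df = pd.DataFrame(self.counts, columns=_BASE_COLS)
        df.insert(0, "position", np.arange(1, self.length + 1))
        df.insert(1, "distance_from_3prime", self.length - df["position"] + 1)
        df.insert(2, "ref_base", list(self.reference))
        df["nonref_prop"] = nonref
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def profile_primer_region(
    merged_reads: Iterable[Union[FastqRecord, str]],
    reference_primer: str,
    max_mm: int = 3,
) -> EditMatrix:
    """Count bases at each primer position over reads passing the mismatch
    filter.

    Each merged read must begin at the primer's 5' end. Reads with more
    than ``max_mm`` positional mismatches over the first L bases are
    excluded (indel guard); shorter reads are skipped. Degenerate reference
    positions match any compatible base and never count as mismatches.
    """
    ref = reference_primer.upper()
    L = len(ref)
    ref_sets = [IUPAC_CODES.get(b, frozenset()) for b in ref]
    counts = np.zeros((L, 5), dtype=np.int64)
    n_pass = n_fail = n_short = 0
    for rec in merged_reads:
        seq = rec[1] if isinstance(rec, tuple) else rec
        if len(seq) < L:
            n_short += 1
            continue
        region = seq[:L].upper()
        mism = sum(1 for i in range(L) if region[i] not in ref_sets[i])
        if mism > max_mm:
            n_fail += 1
            continue
        n_pass += 1
        for i, b in enumerate(region):
            counts[i, _BASE_TO_COL.get(b, 4)] += 1
    return EditMatrix(
        reference=ref,
        counts=counts,
        reads_pass_filter=n_pass,
        reads_failed_filter=n_fail,
        reads_short=n_short,
    )


# --------------------------------------------------------------------------
# observed / expected


def expected_edit_proportions(
    abundance: AbundanceTable, constructs: ConstructSet
) -> dict[int, float]:
    """Expected per-position variant proportion of the template pool:
    the summed abundance of constructs carrying a variant at each
    3'-distance."""
    out: dict[int, float] = {}
    for c in constructs:
        if not c.is_wild_type:
            out[c.variant_pos] = out.get(c.variant_pos, 0.0) + abundance[c.id]
    return out


def observed_over_expected(
    matrix: EditMatrix,
    expected: Mapping[int, float],
) -> pd.DataFrame:
    """The observed/expected edits table.

    ``expected`` maps 3'-distance to the pool's variant proportion there
    (positions absent are expected 0). Ratios at expected-0 positions are
    NaN (undefined), never 0.
    """
    L = matrix.length
    if expected and max(expected) > L:
        raise ProfileError(
            f"expected proportions extend to position {max(expected)} but "
            f"the primer region has only {L} positions"
        )
    nonref = matrix.nonref_proportions()
    rows = []
    for pos in range(1, L + 1):  # 3'-distance
        obs = nonref[L - pos]
        exp = float(expected.get(pos, 0.0))
        ratio = obs / exp if exp > 0 and not np.isnan(obs) else np.nan
        rows.append((pos, obs, exp, ratio))
    return pd.DataFrame(
        rows, columns=["distance_from_3prime", "observed", "expected", "ratio"]
    )


def error_floor(matrix: EditMatrix, window: int) -> float:
    """Sequencing-error floor: mean non-reference proportion at positions
    outside the mutagenized window (3'-distance > window). Reported
    alongside the metric, never subtracted from it."""
    nonref = matrix.nonref_proportions()
    outside = [
        nonref[matrix.length - pos]
        for pos in range(window + 1, matrix.length + 1)
    ]
    outside = [v for v in outside if not np.isnan(v)]
    return float(np.mean(outside)) if outside else float("nan")


# --------------------------------------------------------------------------
# variant-primer penalty analysis


@dataclass
class PenaltyResult:
    """Fold-of-expected recovery of variant primers on a wild-type
    template."""

    per_variant: pd.DataFrame  # position, base, count, expected, fold
    per_position: pd.DataFrame  # position, count, expected, fold
    n_wild_type: int
    n_other: int
    n_short: int
    anchor: str

    @property
    def n_classified(self) -> int:
        return self.n_wild_type + int(self.per_variant["count"].sum())

    def fold_at(self, pos: int) -> float:
        row = self.per_position.loc[self.per_position["position"] == pos, "fold"]
        return float(row.iloc[0]) if len(row) else float("nan")

    def write(self, path: str | Path) -> None:
        pv = self.per_variant.copy()
        pv["base"] = pv["base"].fillna("-")
        pp = self.per_position.copy()
        pp.insert(1, "base", "all")
        pd.concat([pv, pp], ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def penalty_analysis(
    merged_reads: Iterable[Union[FastqRecord, str]],
    scheme: PrimerScheme,
    window: int,
    expected: Optional[AbundanceTable] = None,
    anchor: str = "wild_type",
) -> PenaltyResult:
    """Classify each read's primer region as wild type, one of the
    3*window single-base variants, or other, and compute each variant's
    fold-of-expected abundance.

    ``anchor='wild_type'`` computes ``(count_v / count_WT) /
    (expected_v / expected_WT)`` — under the generative model this equals
    the variant's relative amplification efficiency independent of the
    pool-mean yield. ``anchor='whole_pool'`` computes
    ``observed_proportion / expected_proportion`` over classified reads.
    """
    if anchor not in ("wild_type", "whole_pool"):
        raise ProfileError(f"unknown anchor {anchor!r}")
    variants = enumerate_variants(scheme.fwd_locus, window)
    primer_ids = {}
    for pos, base, _site in variants:
        if pos > 0:
            primer_ids[(pos, base)] = 0  # counts
    ref = scheme.fwd_locus
    L = len(ref)

    n_wt = n_other = n_short = 0
    for rec in merged_reads:
        seq = rec[1] if isinstance(rec, tuple) else rec
        if len(seq) < L:
            n_short += 1
            continue
        region = seq[:L].upper()
        mism = [i for i in range(L) if region[i] != ref[i]]
        if not mism:
            n_wt += 1
        elif len(mism) == 1:
            pos = L - mism[0]  # 3'-distance
            key = (pos, region[mism[0]])
            if key in primer_ids:
                primer_ids[key] += 1
            else:
                n_other += 1  # variant outside the pool window
        else:
            n_other += 1

    if expected is None:
        ids = ["WT"] + [f"pos{p}{b}" for (p, b) in primer_ids]
        expected = AbundanceTable.even(ids)
    exp_wt = expected["WT"]

    if anchor == "wild_type" and n_wt == 0:
        warnings.warn("zero wild-type reads; folds undefined", stacklevel=2)

    total_classified = n_wt + sum(primer_ids.values())
    var_rows = []
    for (pos, base), count in sorted(primer_ids.items()):
        exp_v = expected[f"pos{pos}{base}"]
        if anchor == "wild_type":
            fold = (
                (count / n_wt) / (exp_v / exp_wt) if n_wt > 0 else np.nan
            )
        else:
            fold = (
                (count / total_classified) / exp_v if total_classified else np.nan
            )
        var_rows.append((pos, base, count, exp_v, fold))
    per_variant = pd.DataFrame(
        var_rows, columns=["position", "base", "count", "expected", "fold"]
    )

    pos_rows = []
    for pos, grp in per_variant.groupby("position"):
        count = int(grp["count"].sum())
        exp_p = float(grp["expected"].sum())
        if anchor == "wild_type":
            fold = (count / n_wt) / (exp_p / exp_wt) if n_wt > 0 else np.nan
        else:
            fold = (count / total_classified) / exp_p if total_classified else np.nan
        pos_rows.append((int(pos), count, exp_p, fold))
    per_position = pd.DataFrame(
        pos_rows, columns=["position", "count", "expected", "fold"]
    )

    return PenaltyResult(
        per_variant=per_variant,
        per_position=per_position,
        n_wild_type=n_wt,
        n_other=n_other,
        n_short=n_short,
        anchor=anchor,
    )
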