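"""Primer schemes and nucleotide utilities.

A primer scheme is the pair of locus-specific primer sequences used to
amplify a marker-gene region, plus the sequencing-adapter tails that are
appended 5' of each locus-specific portion. The package ships the
non-degenerate E. coli-specific 16S rRNA V4 scheme (515F/806R with Nextera
tails) used throughout the primer-editing experiments.

Positions in a primer are reported by *3'-distance*: position 1 is the
3'-terminal base, position 2 the next one in, and so on. This is the
convention used for editing efficiencies, amplification penalties and all
per-position report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# IUPAC nucleotide ambiguity codes -> the set of concrete bases matched.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES = "ACGT"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "ACGTRYSWKMBDHVN".lower(),
    "TGCAYRSWMKVHDBN" + "TGCAYRSWMKVHDBN".lower(),
)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac(seq: str) -> bool:
    return all(b in IUPAC_CODES for b in seq.upper())


def base_matches(ref: str, obs: str) -> bool:
    """Whether an observed base is compatible with a (possibly degenerate)
    reference base. ``N`` observations match nothing concrete and are treated
    as mismatches by callers that count them."""
    return obs in IUPAC_CODES.get(ref, frozenset())


def hamming(a: str, b: str) -> int:
    """Positional mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class PrimerScheme:
    """Forward/reverse locus-specific primers plus adapter tails.

    ``fwd_locus``/``rev_locus`` are written 5'->3' as synthesized. The
    reverse primer binds the template as the reverse complement of
    ``rev_locus`` on the top strand.
    """

    fwd_locus: str
    rev_locus: str
    fwd_tail: str = ""
    rev_tail: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        for label, seq in (("fwd_locus", self.fwd_locus), ("rev_locus", self.rev_locus)):
            if not seq:
                raise ValueError(f"{label} must be non-empty")
            if not is_iupac(seq):
                raise ValueError(f"{label} contains non-IUPAC characters: {seq!r}")
        for label, seq in (("fwd_tail", self.fwd_tail), ("rev_tail", self.rev_tail)):
            if seq and not is_iupac(seq):
                raise ValueError(f"{label} contains non-IUPAC characters: {seq!r}")
        object.__setattr__(self, "fwd_locus", self.fwd_locus.upper())
        object.__setattr__(self, "rev_locus", self.rev_locus.upper())
        object.__setattr__(self, "fwd_tail", self.fwd_tail.upper())
        object.__setattr__(self, "rev_tail", self.rev_tail.upper())

    @property
    def fwd_len(self) -> int:
        return len(self.fwd_locus)

    @property
    def rev_len(self) -> int:
        return len(self.rev_locus)

    def fwd_base_at_3prime_distance(self, pos: int) -> str:
        """Reference base of the forward primer at 3'-distance ``pos``
        (1 = terminal base)."""
        if not 1 <= pos <= self.fwd_len:
            raise ValueError(f"position {pos} outside primer of length {self.fwd_len}")
        return self.fwd_locus[self.fwd_len - pos]


# Nextera-tailed E. coli-specific V4 scheme (no degenerate bases): the
# locus-specific portions are 19 nt (515F) and 20 nt (806R).
ECOLI_V4 = PrimerScheme(
    fwd_locus="GTGCCAGCAGCCGCGGTAA",
    rev_locus="GGACTACCAGGGTATCTAAT",
    fwd_tail="TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG",
    rev_tail="GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG",
    name="E_coli_V4_515F/806R",
)
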