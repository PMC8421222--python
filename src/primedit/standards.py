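"""Design of the synthetic primer-editing standards.

The standard set reports on editing of the forward amplification primer: it
contains the wild-type forward primer binding site plus every possible
single-base substitution within a 3'-terminal window of that site (window 10
for the canonical 31-member pool: 1 wild type + 10 positions x 3 alternative
bases). Each construct carries the marker-gene insert with its (possibly
mutated) primer binding sites, flanking sequence, and a unique 20-base
quantification barcode read out PCR-free to measure pool composition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .schemes import BASES, PrimerScheme, hamming, revcomp


class DesignError(ValueError):
    """Invalid design request."""


class CapacityError(DesignError):
    """Barcode set of the requested size/distance cannot be constructed."""


class AmbiguousTemplateError(DesignError):
    """Template lacks a unique occurrence of a primer binding site."""


def enumerate_variants(
    primer_site: str, window: int
) -> list[tuple[int, Optional[str], str]]:
    """Enumerate the wild-type primer site and all single-base substitutions
    within the last ``window`` positions.

    Returns ``(variant_pos, variant_base, mutated_site)`` tuples where
    ``variant_pos`` is the 3'-distance of the substitution (1 = terminal
    base) and the wild type is ``(0, None, primer_site)``. Ordering is
    deterministic: wild type first, then positions walking inward from the
    3' end, alternative bases alphabetical. For a non-degenerate site the
    result has ``3 * window + 1`` entries.
    """
    primer_site = primer_site.upper()
    if window < 0:
        raise DesignError(f"window must be >= 0, got {window}")
    if window > len(primer_site):
        raise DesignError(
            f"window {window} exceeds primer length {len(primer_site)}"
        )
    site_window = primer_site[len(primer_site) - window :] if window else ""
    bad = [b for b in site_window if b not in BASES]
    if bad:
        raise DesignError(
            f"degenerate base(s) {bad} inside the mutagenesis window; "
            "standards require a non-degenerate primer site"
        )
    out: list[tuple[int, Optional[str], str]] = [(0, None, primer_site)]
    for pos in range(1, window + 1):
        idx = len(primer_site) - pos
        ref = primer_site[idx]
        for alt in BASES:
            if alt == ref:
                continue
            mutated = primer_site[:idx] + alt + primer_site[idx + 1 :]
            out.append((pos, alt, mutated))
    return out


def generate_barcodes(
    n: int,
    length: int = 20,
    min_dist: int = 5,
    seed: int = 0,
    max_attempts_per_code: int = 10_000,
) -> list[str]:
    """Generate ``n`` random DNA barcodes with pairwise Hamming distance
    >= ``min_dist`` by seeded greedy rejection sampling.

    Deterministic for a fixed seed. Raises :class:`CapacityError` when a
    code cannot be placed within the attempt budget (e.g. distance 5
    requested at length 1).
    """
    if n < 1:
        raise DesignError(f"n must be >= 1, got {n}")
    if min_dist > length:
        raise CapacityError(
            f"min_dist {min_dist} impossible at barcode length {length}"
        )
    rng = random.Random(seed)
    codes: list[str] = []
    while len(codes) < n:
        for _ in range(max_attempts_per_code):
            cand = "".join(rng.choice(BASES) for _ in range(length))
            if all(hamming(cand, c) >= min_dist for c in codes):
                codes.append(cand)
                break
        else:
            raise CapacityError(
                f"could not place barcode {len(codes) + 1}/{n} at length "
                f"{length}, min_dist {min_dist}"
            )
    return codes


def synthetic_template(
    scheme: PrimerScheme, length: int = 332, seed: int = 20
) -> str:
    """Synthetic stand-in for the real marker-gene template region.

    Builds a ``length``-base template whose first bases are the forward
    primer binding site and whose last bases are the reverse-complemented
    reverse primer binding site, with a seeded random interior. The true
    E. coli V4 insert sequence plays no computational role beyond its primer
    binding sites, so a synthetic interior is sufficient for every analysis
    in this package.
    """
    interior_len = length - scheme.fwd_len - scheme.rev_len
    if interior_len < 0:
        raise DesignError(
            f"template length {length} shorter than the two primer sites"
        )
    rng = random.Random(seed)
    interior = "".join(rng.choice(BASES) for _ in range(interior_len))
    template = scheme.fwd_locus + interior + revcomp(scheme.rev_locus)
    # interior drawn again if it accidentally duplicates a primer site
    attempts = 0
    while (
        template.count(scheme.fwd_locus) != 1
        or template.count(revcomp(scheme.rev_locus)) != 1
    ):
        attempts += 1
        if attempts > 100:  # pragma: no cover - astronomically unlikely
            raise DesignError("could not build a template with unique sites")
        interior = "".join(rng.choice(BASES) for _ in range(interior_len))
        template = scheme.fwd_locus + interior + revcomp(scheme.rev_locus)
    return template


@dataclass(frozen=True)
class Construct:
    """One standard: a marker-gene insert with zero or one substitution in
    the forward primer binding site, plus its quantification barcode.

    ``variant_pos`` is the 3'-distance of the substitution within the
    forward primer site (0 = wild type, ``variant_base`` None).
    """

    id: str
    variant_pos: int
    variant_base: Optional[str]
    insert_seq: str
    barcode: str
    flank_len: int

    @property
    def is_wild_type(self) -> bool:
        return self.variant_pos == 0


@dataclass
class ConstructSet:
    """The ordered standards pool with its design parameters."""

    constructs: list[Construct]
    window: int
    scheme: PrimerScheme
    template: str

    def __post_init__(self) -> None:
        barcodes = [c.barcode for c in self.constructs]
        if len(set(barcodes)) != len(barcodes):
            raise DesignError("barcodes are not unique within the set")

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self):
        return iter(self.constructs)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.constructs]

    @property
    def wild_type(self) -> Construct:
        return next(c for c in self.constructs if c.is_wild_type)

    def by_id(self, construct_id: str) -> Construct:
        for c in self.constructs:
            if c.id == construct_id:
                return c
        raise KeyError(construct_id)

    def min_barcode_distance(self) -> int:
        codes = [c.barcode for c in self.constructs]
        if len(codes) < 2:
            return len(codes[0]) if codes else 0
        return min(
            hamming(a, b)
            for i, a in enumerate(codes)
            for b in codes[i + 1 :]
        )

    def variant_positions(self) -> dict[int, list[Construct]]:
        """Constructs grouped by 3'-distance of their variant (wild type
        excluded)."""
        groups: dict[int, list[Construct]] = {}
        for c in self.constructs:
            if not c.is_wild_type:
                groups.setdefault(c.variant_pos, []).append(c)
        return groups

    # ---- serialization -------------------------------------------------

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "construct_id": [c.id for c in self.constructs],
                "variant_pos": [c.variant_pos for c in self.constructs],
                "variant_base": [c.variant_base or "-" for c in self.constructs],
                "barcode": [c.barcode for c in self.constructs],
                "insert_length": [len(c.insert_seq) for c in self.constructs],
            }
        )

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in self.constructs:
                fh.write(f">{c.id}\n{c.insert_seq}\n")

    def write_barcode_fasta(self, path: str | Path) -> None:
        """Barcode reference: the first 20 bp of each record is the barcode,
        matching the convention of the quantification analysis."""
        with open(path, "w") as fh:
            for c in self.constructs:
                fh.write(f">{c.id}\n{c.barcode}\n")

    def write_metadata(self, path: str | Path) -> None:
        self.metadata_frame().to_csv(path, sep="\t", index=False)


def _construct_id(pos: int, base: Optional[str]) -> str:
    return "WT" if pos == 0 else f"pos{pos}{base}"


def build_construct_set(
    template_region: str,
    scheme: PrimerScheme,
    window: int = 10,
    flank_len: int = 20,
    seed: int = 0,
    barcode_length: int = 20,
    barcode_min_dist: int = 5,
) -> ConstructSet:
    """Build the full standards pool for a template region.

    The template must contain the forward primer binding site (as given)
    and the reverse site (as its reverse complement) exactly once each.
    Each insert is ``flank + mutated template + flank`` with the single
    substitution applied inside the forward primer binding site; flanks are
    seeded-random and shared across constructs.
    """
    template_region = template_region.upper()
    if template_region.count(scheme.fwd_locus) != 1:
        raise AmbiguousTemplateError(
            f"forward primer site occurs "
            f"{template_region.count(scheme.fwd_locus)} times in template"
        )
    rev_site = revcomp(scheme.rev_locus)
    if template_region.count(rev_site) != 1:
        raise AmbiguousTemplateError(
            f"reverse primer site occurs "
            f"{template_region.count(rev_site)} times in template"
        )

    variants = enumerate_variants(scheme.fwd_locus, window)
    barcodes = generate_barcodes(
        len(variants), barcode_length, barcode_min_dist, seed=seed
    )
    rng = random.Random(seed + 1)
    flank5 = "".join(rng.choice(BASES) for _ in range(flank_len))
    flank3 = "".join(rng.choice(BASES) for _ in range(flank_len))

    site_start = template_region.index(scheme.fwd_locus)
    constructs = []
    for (pos, base, mutated_site), barcode in zip(variants, barcodes):
        mutated_template = (
            template_region[:site_start]
            + mutated_site
            + template_region[site_start + scheme.fwd_len :]
        )
        constructs.append(
            Construct(
                id=_construct_id(pos, base),
                variant_pos=pos,
                variant_base=base,
                insert_seq=flank5 + mutated_template + flank3,
                barcode=barcode,
                flank_len=flank_len,
            )
        )
    return ConstructSet(
        constructs=constructs, window=window, scheme=scheme,
        template=template_region,
    )
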