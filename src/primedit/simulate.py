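"""Generative simulator of primer-editing amplicon experiments.

The aggregate model has two per-position parameters, both indexed by
3'-distance within the forward primer:

* ``e_p`` — editing efficiency: the probability that the proofreading
  polymerase's 3'->5' exonuclease corrects a template:primer mismatch at
  position ``p``, so the amplicon carries the template base.
* ``a_p`` — amplification penalty: the relative yield of an *unedited*
  mismatched primer:template pair at position ``p`` (1 = no penalty).

For a standards construct with its single variant at position ``p`` the
expected relative yield is ``y = e_p + (1 - e_p) * a_p`` (an edited primer
amplifies at full efficiency; an unedited one at ``a_p``); a wild-type
construct has yield 1. Reads are sampled with probability proportional to
``abundance * yield`` and, conditional on coming from that construct, show
the template (variant) base at ``p`` with probability ``e_p / y`` and the
primer (reference) base otherwise. The reciprocal experiment — a pool of
variant primers on a wild-type template — uses the mirrored model: a
variant primer is edited *back* to the template base with probability
``e_p`` and otherwise amplifies at ``a_p``.

Phosphorothioate protection truncates the editable window: a block leaving
``b`` 3'-terminal bases editable forces the effective efficiency to zero at
every position beyond ``b``. Annealing temperature is accepted in the
config and deliberately ignored: across the 50-60 C range it has no effect
on editing in this system.

Sequencing errors are uniform substitutions applied after the model, with
a single constant quality symbol; no indels by default.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .schemes import BASES, PrimerScheme, revcomp
from .standards import ConstructSet, enumerate_variants


class SimulationError(ValueError):
    """Inconsistent simulator inputs."""


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class EditingProfile:
    """Per-position editing efficiencies with optional exonuclease block.

    ``efficiencies`` maps 3'-distance (1 = terminal base) to ``e_p`` in
    [0, 1]; unlisted positions default to 0. ``block_after`` models a
    phosphorothioate bond: the number of 3'-terminal bases that remain
    editable (``None`` = no block; 3 corresponds to a bond between the
    4th- and 3rd-to-last bases). Positions beyond the block have effective
    efficiency 0 regardless of ``e_p``.
    """

    efficiencies: Mapping[int, float]
    block_after: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        for pos, e in self.efficiencies.items():
            if pos < 1:
                raise SimulationError(f"position {pos} must be >= 1")
            if not 0.0 <= e <= 1.0:
                raise SimulationError(f"e_{pos} = {e} outside [0, 1]")
        if self.block_after is not None and self.block_after < 0:
            raise SimulationError("block_after must be >= 0 or None")

    def effective(self, pos: int) -> float:
        """Efficiency at ``pos`` after applying the block."""
        if self.block_after is not None and pos > self.block_after:
            return 0.0
        return float(self.efficiencies.get(pos, 0.0))

    @classmethod
    def complete(cls, window: int = 6, label: str = "complete") -> "EditingProfile":
        """Complete editing of the last ``window`` positions (KAPA-HiFi-like
        behaviour over its near-complete range)."""
        return cls({p: 1.0 for p in range(1, window + 1)}, label=label)

    @classmethod
    def none(cls, label: str = "no-editing") -> "EditingProfile":
        """No editing anywhere (Taq-class behaviour)."""
        return cls({}, label=label)


@dataclass(frozen=True)
class PenaltyProfile:
    """Relative amplification efficiency ``a_p`` of an unedited mismatch at
    each 3'-distance; positions not listed have no penalty (``a_p = 1``)."""

    penalties: Mapping[int, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        for pos, a in self.penalties.items():
            if pos < 1:
                raise SimulationError(f"position {pos} must be >= 1")
            if not 0.0 <= a <= 1.0:
                raise SimulationError(f"a_{pos} = {a} outside [0, 1]")

    def at(self, pos: int) -> float:
        return float(self.penalties.get(pos, 1.0))

    @classmethod
    def none(cls) -> "PenaltyProfile":
        return cls({}, label="no-penalty")

    @classmethod
    def taq_v4(cls) -> "PenaltyProfile":
        """Per-position penalties of unedited mismatches observed with a
        non-proofreading Taq polymerase on the V4 forward primer: fold-of-
        expected read recovery for variants at the last five positions
        (terminal position most deleterious)."""
        return cls(
            {1: 0.189, 2: 0.318, 3: 0.404, 4: 0.774, 5: 0.922},
            label="Taq-V4",
        )


class AbundanceTable(dict):
    """Construct (or primer) id -> proportion; proportions sum to 1."""

    TOL = 1e-9

    def __init__(self, proportions: Mapping[str, float]):
        super().__init__({k: float(v) for k, v in proportions.items()})
        if any(v < 0 for v in self.values()):
            raise SimulationError("proportions must be non-negative")
        total = sum(self.values())
        if abs(total - 1.0) > self.TOL:
            raise SimulationError(f"proportions sum to {total}, expected 1")

    @classmethod
    def even(cls, ids: Sequence[str]) -> "AbundanceTable":
        n = len(ids)
        return cls({i: 1.0 / n for i in ids})

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "AbundanceTable":
        total = sum(counts.values())
        if total == 0:
            raise SimulationError("no counts to normalize")
        return cls({k: v / total for k, v in counts.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df.iloc[:, 0], df["proportion"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"construct_id": list(self), "proportion": list(self.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SimConfig:
    """Run-level simulator settings.

    ``read_length`` of ``None`` means each mate covers the amplicon
    end-to-end (fully overlapping pairs, so merging is exercised); longer
    reads run through into the opposite adapter tail. ``annealing_temp_c``
    is accepted for provenance and has no effect on the model.
    """

    n_reads: int
    error_rate: float = 0.0
    read_length: Optional[int] = None
    seed: int = 0
    quality_char: str = "I"
    annealing_temp_c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise SimulationError("n_reads must be >= 1")
        if not 0.0 <= self.error_rate <= 0.25:
            raise SimulationError("error_rate must be in [0, 0.25]")
        if len(self.quality_char) != 1:
            raise SimulationError("quality_char must be a single character")


# --------------------------------------------------------------------------
# output container

FastqRecord = tuple[str, str, str]  # (id, sequence, quality)


@dataclass
class SimResult:
    """Reads plus per-read ground truth and the config that produced them."""

    r1: list[FastqRecord]
    r2: Optional[list[FastqRecord]]
    truth: pd.DataFrame
    config: dict

    def write(self, outdir: str | Path, prefix: str, gzipped: bool = False) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        suffix = ".fastq.gz" if gzipped else ".fastq"
        paths = {}
        r1_path = outdir / f"{prefix}_R1{suffix}"
        write_fastq(self.r1, r1_path)
        paths["r1"] = r1_path
        if self.r2 is not None:
            r2_path = outdir / f"{prefix}_R2{suffix}"
            write_fastq(self.r2, r2_path)
            paths["r2"] = r2_path
        truth_path = outdir / f"{prefix}_truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        cfg_path = outdir / f"{prefix}_config.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)
        paths["config"] = cfg_path
        return paths


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[FastqRecord]:
    """Load a (possibly gzipped) FASTQ file as (id, seq, qual) tuples."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rid.split()[0], seq, qual) for rid, seq, qual in FastqGeneralIterator(fh)]


# --------------------------------------------------------------------------
# error injection

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def _apply_errors(
    seq: str, n_err: int, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Substitute ``n_err`` random positions with a different random base."""
    if n_err == 0:
        return seq, []
    positions = sorted(rng.choice(len(seq), size=min(n_err, len(seq)), replace=False).tolist())
    chars = list(seq)
    for pos in positions:
        orig = chars[pos]
        alts = [b for b in BASES if b != orig]
        chars[pos] = alts[rng.integers(len(alts))]
    return "".join(chars), positions


def _make_pair(
    amplicon: str,
    cfg: SimConfig,
    scheme: PrimerScheme,
    n_err1: int,
    n_err2: int,
    rng: np.random.Generator,
) -> tuple[str, str, list[int], list[int]]:
    read_len = cfg.read_length or len(amplicon)
    src1 = amplicon + revcomp(scheme.rev_tail)
    src2 = revcomp(amplicon) + revcomp(scheme.fwd_tail)
    r1 = src1[:read_len] if read_len <= len(src1) else src1
    r2 = src2[:read_len] if read_len <= len(src2) else src2
    r1, err1 = _apply_errors(r1, n_err1, rng)
    r2, err2 = _apply_errors(r2, n_err2, rng)
    return r1, r2, err1, err2


# --------------------------------------------------------------------------
# simulations


def simulate_standards_run(
    constructs: ConstructSet,
    abundance: AbundanceTable,
    editing: EditingProfile,
    penalty: PenaltyProfile,
    cfg: SimConfig,
) -> SimResult:
    """Amplify the standards pool with wild-type primers.

    Each read pair is drawn from one construct with probability
    proportional to ``abundance * yield``; its forward primer region shows
    the construct's variant base when the primer was edited and the
    reference base otherwise. The reverse primer region always matches its
    reference (the standards are wild type there) before sequencing error.
    """
    missing = set(c.id for c in constructs) - set(abundance)
    extra = set(abundance) - set(c.id for c in constructs)
    if missing or extra:
        raise SimulationError(
            f"abundance/construct mismatch (missing {sorted(missing)}, "
            f"extra {sorted(extra)})"
        )

    scheme = constructs.scheme
    rng = np.random.default_rng(cfg.seed)

    # amplicon spans the forward site through the end of the reverse site
    template = constructs.template
    site_start = template.index(scheme.fwd_locus)
    rev_site = revcomp(scheme.rev_locus)
    after_fwd = template[site_start + scheme.fwd_len :]
    interior = after_fwd[: after_fwd.index(rev_site) + len(rev_site)]

    ids, yields, cond_edit, amplicons_ed, amplicons_un = [], [], [], [], []
    for c in constructs:
        ids.append(c.id)
        if c.is_wild_type:
            y, pe = 1.0, 0.0
            primer_region_ed = primer_region_un = scheme.fwd_locus
        else:
            e = editing.effective(c.variant_pos)
            a = penalty.at(c.variant_pos)
            y = e + (1.0 - e) * a
            pe = e / y if y > 0 else 0.0
            idx = scheme.fwd_len - c.variant_pos
            primer_region_ed = (
                scheme.fwd_locus[:idx] + c.variant_base + scheme.fwd_locus[idx + 1 :]
            )
            primer_region_un = scheme.fwd_locus
        yields.append(y)
        cond_edit.append(pe)
        amplicons_ed.append(primer_region_ed + interior)
        amplicons_un.append(primer_region_un + interior)

    weights = np.array([abundance[i] for i in ids]) * np.array(yields)
    if weights.sum() <= 0:
        raise SimulationError("all constructs have zero sampling weight")
    probs = weights / weights.sum()

    which = rng.choice(len(ids), size=cfg.n_reads, p=probs)
    edited = rng.random(cfg.n_reads) < np.array(cond_edit)[which]
    amp_len = len(amplicons_ed[0])
    read_len = cfg.read_length or amp_len
    n_err1 = rng.binomial(read_len, cfg.error_rate, cfg.n_reads)
    n_err2 = rng.binomial(read_len, cfg.error_rate, cfg.n_reads)

    r1_out: list[FastqRecord] = []
    r2_out: list[FastqRecord] = []
    rows = []
    qual = cfg.quality_char * read_len
    for i in range(cfg.n_reads):
        ci = which[i]
        amplicon = amplicons_ed[ci] if edited[i] else amplicons_un[ci]
        r1, r2, err1, err2 = _make_pair(
            amplicon, cfg, scheme, int(n_err1[i]), int(n_err2[i]), rng
        )
        rid = f"std_{i}"
        r1_out.append((rid, r1, qual[: len(r1)]))
        r2_out.append((rid, r2, qual[: len(r2)]))
        rows.append(
            (
                rid,
                ids[ci],
                bool(edited[i]),
                ",".join(map(str, err1)),
                ",".join(map(str, err2)),
            )
        )

    truth = pd.DataFrame(
        rows, columns=["read_id", "construct_id", "edited", "error_pos_r1", "error_pos_r2"]
    )
    config = {
        "mode": "standards_run",
        "editing": {"efficiencies": dict(editing.efficiencies),
                    "block_after": editing.block_after, "label": editing.label},
        "penalty": {"penalties": dict(penalty.penalties), "label": penalty.label},
        "abundance": dict(abundance),
        "sim": asdict(cfg),
    }
    return SimResult(r1_out, r2_out, truth, config)


def simulate_variant_primer_run(
    wt_template: str,
    scheme: PrimerScheme,
    window: int,
    editing: EditingProfile,
    penalty: PenaltyProfile,
    cfg: SimConfig,
    pool: Optional[AbundanceTable] = None,
) -> SimResult:
    """Reciprocal experiment: a pool of variant primers on a wild-type
    template.

    A primer with its variant at position ``p`` is edited back to the
    template (wild-type) base with probability ``e_p``; unedited variant
    primers amplify at relative efficiency ``a_p``. The read's primer
    region records the final primer sequence.
    """
    wt_template = wt_template.upper()
    if wt_template.count(scheme.fwd_locus) != 1:
        raise SimulationError("template must contain the forward site exactly once")
    rev_site = revcomp(scheme.rev_locus)
    if wt_template.count(rev_site) != 1:
        raise SimulationError("template must contain the reverse site exactly once")

    variants = enumerate_variants(scheme.fwd_locus, window)
    primer_ids = ["WT" if p == 0 else f"pos{p}{b}" for p, b, _ in variants]
    if pool is None:
        pool = AbundanceTable.even(primer_ids)
    if set(pool) != set(primer_ids):
        raise SimulationError("pool ids do not match the primer pool")

    site_start = wt_template.index(scheme.fwd_locus)
    amplicon_tail = wt_template[site_start + scheme.fwd_len :]
    end = amplicon_tail.index(rev_site) + len(rev_site)
    interior = amplicon_tail[:end]

    rng = np.random.default_rng(cfg.seed)
    yields, cond_edit, amp_edited, amp_unedited = [], [], [], []
    for (pos, base, mutated_site), pid in zip(variants, primer_ids):
        if pos == 0:
            y, pe = 1.0, 0.0
            amp_un = scheme.fwd_locus + interior
            amp_ed = amp_un
        else:
            e = editing.effective(pos)
            a = penalty.at(pos)
            y = e + (1.0 - e) * a
            pe = e / y if y > 0 else 0.0
            amp_ed = scheme.fwd_locus + interior          # edited back to WT
            amp_un = mutated_site + interior              # variant primer kept
        yields.append(y)
        cond_edit.append(pe)
        amp_edited.append(amp_ed)
        amp_unedited.append(amp_un)

    weights = np.array([pool[i] for i in primer_ids]) * np.array(yields)
    if weights.sum() <= 0:
        raise SimulationError("all primers have zero sampling weight")
    probs = weights / weights.sum()

    which = rng.choice(len(primer_ids), size=cfg.n_reads, p=probs)
    edited = rng.random(cfg.n_reads) < np.array(cond_edit)[which]
    amp_len = len(amp_edited[0])
    read_len = cfg.read_length or amp_len
    n_err1 = rng.binomial(read_len, cfg.error_rate, cfg.n_reads)
    n_err2 = rng.binomial(read_len, cfg.error_rate, cfg.n_reads)

    r1_out: list[FastqRecord] = []
    r2_out: list[FastqRecord] = []
    rows = []
    qual = cfg.quality_char * read_len
    for i in range(cfg.n_reads):
        pi = which[i]
        amplicon = amp_edited[pi] if edited[i] else amp_unedited[pi]
        r1, r2, err1, err2 = _make_pair(
            amplicon, cfg, scheme, int(n_err1[i]), int(n_err2[i]), rng
        )
        rid = f"vp_{i}"
        r1_out.append((rid, r1, qual[: len(r1)]))
        r2_out.append((rid, r2, qual[: len(r2)]))
        rows.append(
            (
                rid,
                primer_ids[pi],
                bool(edited[i]),
                ",".join(map(str, err1)),
                ",".join(map(str, err2)),
            )
        )

    truth = pd.DataFrame(
        rows, columns=["read_id", "primer_id", "edited", "error_pos_r1", "error_pos_r2"]
    )
    config = {
        "mode": "variant_primer_run",
        "window": window,
        "editing": {"efficiencies": dict(editing.efficiencies),
                    "block_after": editing.block_after, "label": editing.label},
        "penalty": {"penalties": dict(penalty.penalties), "label": penalty.label},
        "pool": dict(pool),
        "sim": asdict(cfg),
    }
    return SimResult(r1_out, r2_out, truth, config)


def simulate_barcode_reads(
    constructs: ConstructSet,
    abundance: AbundanceTable,
    cfg: SimConfig,
) -> SimResult:
    """PCR-free quantification reads: each read begins with a construct's
    20-base barcode (restriction digest liberates the barcode cassette, so
    no amplification bias applies); counts are multinomial by abundance."""
    missing = set(c.id for c in constructs) - set(abundance)
    if missing:
        raise SimulationError(f"abundance missing constructs: {sorted(missing)}")

    rng = np.random.default_rng(cfg.seed)
    ids = [c.id for c in constructs]
    barcodes = {c.id: c.barcode for c in constructs}
    downstream = {c.id: c.insert_seq for c in constructs}
    probs = np.array([abundance[i] for i in ids])
    probs = probs / probs.sum()

    bc_len = len(next(iter(barcodes.values())))
    read_len = cfg.read_length or bc_len
    which = rng.choice(len(ids), size=cfg.n_reads, p=probs)
    n_err = rng.binomial(read_len, cfg.error_rate, cfg.n_reads)

    reads: list[FastqRecord] = []
    rows = []
    qual = cfg.quality_char * read_len
    for i in range(cfg.n_reads):
        cid = ids[which[i]]
        src = barcodes[cid] + downstream[cid]
        seq = src[:read_len]
        seq, err = _apply_errors(seq, int(n_err[i]), rng)
        rid = f"bc_{i}"
        reads.append((rid, seq, qual[: len(seq)]))
        rows.append((rid, cid, ",".join(map(str, err))))

    truth = pd.DataFrame(rows, columns=["read_id", "construct_id", "error_pos"])
    config = {
        "mode": "barcode_reads",
        "abundance": dict(abundance),
        "sim": asdict(cfg),
    }
    return SimResult(reads, None, truth, config)
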