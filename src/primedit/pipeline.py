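"""End-to-end runs and plain-text reporting.

A pipeline run goes design -> simulate -> quantify -> analyze and drops a
fixed set of artifacts into a run directory: the construct/barcode FASTA
and metadata, simulated FASTQ pairs with ground truth, barcode counts, the
edit matrix, the observed/expected table, optionally the variant-primer
penalty table, a summary JSON of read tallies, and an echo of the exact
configuration. All randomness flows from the single top-level seed via
fixed per-stage offsets, so identical configurations reproduce identical
bytes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .barcodes import BarcodeRef, quantify_barcodes
from .profiling import (
    error_floor,
    expected_edit_proportions,
    merge_pairs,
    observed_over_expected,
    penalty_analysis,
    profile_primer_region,
    trim_adapters,
)
from .schemes import ECOLI_V4, PrimerScheme
from .simulate import (
    AbundanceTable,
    EditingProfile,
    PenaltyProfile,
    SimConfig,
    simulate_barcode_reads,
    simulate_standards_run,
    simulate_variant_primer_run,
)
from .standards import build_construct_set, synthetic_template


class PipelineError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "design": {"window": 10, "flank_len": 20, "template_length": 332},
    "simulate": {
        "n_reads": 50_000,
        "n_barcode_reads": 31_000,
        "error_rate": 0.0,
        "read_length": None,
        "editing": {"efficiencies": {p: 1.0 for p in range(1, 7)},
                    "block_after": None, "label": "complete-6"},
        "penalty": {},
        "variant_primer": False,
    },
    "analysis": {"max_mismatches": 3, "anchor": "wild_type"},
}


def _merge_config(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_config(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Optional[str | Path] = None, **overrides) -> dict:
    """Default config, optionally updated from a YAML file and keyword
    overrides (nested dicts merge key-wise)."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge_config(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge_config(cfg, overrides)
    return cfg


def _editing_from_config(spec: dict) -> EditingProfile:
    effs = {int(k): float(v) for k, v in (spec.get("efficiencies") or {}).items()}
    return EditingProfile(
        efficiencies=effs,
        block_after=spec.get("block_after"),
        label=spec.get("label", ""),
    )


def _penalty_from_config(spec) -> PenaltyProfile:
    if spec == "taq":
        return PenaltyProfile.taq_v4()
    return PenaltyProfile({int(k): float(v) for k, v in (spec or {}).items()})


def run_pipeline(
    config: dict, outdir: str | Path, scheme: PrimerScheme = ECOLI_V4
) -> dict:
    """Execute a full run into ``outdir``; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 1))
    dcfg = config["design"]
    scfg = config["simulate"]
    acfg = config["analysis"]

    window = int(dcfg["window"])
    if not 0 <= window <= scheme.fwd_len:
        raise PipelineError(
            f"window {window} invalid for a {scheme.fwd_len}-base primer"
        )

    # fixed per-stage substreams derived from the one seed
    s_design, s_bc, s_std, s_vp = (
        (seed * 8 + k) % (2**31) for k in range(4)
    )

    # ---- design ----------------------------------------------------------
    template = synthetic_template(
        scheme, length=int(dcfg["template_length"]), seed=s_design
    )
    constructs = build_construct_set(
        template, scheme, window=window,
        flank_len=int(dcfg["flank_len"]), seed=s_design,
    )
    constructs.write_fasta(outdir / "constructs.fasta")
    constructs.write_barcode_fasta(outdir / "barcodes.fasta")
    constructs.write_metadata(outdir / "metadata.tsv")

    # ---- barcode quantification -----------------------------------------
    bc_sim = simulate_barcode_reads(
        constructs,
        AbundanceTable.even(constructs.ids),
        SimConfig(n_reads=int(scfg["n_barcode_reads"]), seed=s_bc,
                  error_rate=float(scfg["error_rate"])),
    )
    bc_sim.write(outdir, "barcode")
    ref = BarcodeRef({c.barcode: c.id for c in constructs})
    counts, measured_abundance = quantify_barcodes(bc_sim.r1, ref)
    counts.to_frame().to_csv(outdir / "barcode_counts.tsv", sep="\t",
                             index=False, float_format="%.6g")
    counts.summary_frame().to_csv(outdir / "barcode_summary.tsv", sep="\t",
                                  index=False)

    # ---- standards run ---------------------------------------------------
    editing = _editing_from_config(scfg["editing"])
    penalty = _penalty_from_config(scfg["penalty"])
    sim_cfg = SimConfig(
        n_reads=int(scfg["n_reads"]),
        error_rate=float(scfg["error_rate"]),
        read_length=scfg.get("read_length"),
        seed=s_std,
    )
    std = simulate_standards_run(
        constructs, AbundanceTable.even(constructs.ids), editing, penalty, sim_cfg
    )
    std.write(outdir, "standards")

    r1, r2 = trim_adapters(std.r1, std.r2, scheme)
    merged, unmerged = merge_pairs(r1, r2)
    matrix = profile_primer_region(
        merged, scheme.fwd_locus, max_mm=int(acfg["max_mismatches"])
    )
    matrix.write(outdir / "edit_matrix.tsv")
    expected = expected_edit_proportions(measured_abundance, constructs)
    obs_exp = observed_over_expected(matrix, expected)
    obs_exp.to_csv(outdir / "obs_exp.tsv", sep="\t", index=False,
                   float_format="%.6g")

    summary = {
        "seed": seed,
        "n_constructs": len(constructs),
        "barcode": {
            "assigned": counts.assigned,
            "unassigned": counts.unassigned,
            "ambiguous": counts.ambiguous,
            "truncated": counts.truncated,
        },
        "standards": {
            "n_pairs": len(std.r1),
            "merged": len(merged),
            "unmerged": unmerged,
            "pass_filter": matrix.reads_pass_filter,
            "failed_filter": matrix.reads_failed_filter,
            "short": matrix.reads_short,
            "error_floor": error_floor(matrix, window),
        },
    }

    # ---- optional reciprocal variant-primer run --------------------------
    if scfg.get("variant_primer"):
        vp_cfg = SimConfig(
            n_reads=int(scfg["n_reads"]),
            error_rate=float(scfg["error_rate"]),
            read_length=scfg.get("read_length"),
            seed=s_vp,
        )
        vp = simulate_variant_primer_run(
            template, scheme, window, editing, penalty, vp_cfg
        )
        vp.write(outdir, "variant_primer")
        v1, v2 = trim_adapters(vp.r1, vp.r2, scheme)
        vmerged, vunmerged = merge_pairs(v1, v2)
        pen = penalty_analysis(
            vmerged, scheme, window, anchor=acfg.get("anchor", "wild_type")
        )
        pen.write(outdir / "penalty.tsv")
        summary["variant_primer"] = {
            "n_pairs": len(vp.r1),
            "merged": len(vmerged),
            "unmerged": vunmerged,
            "wild_type": pen.n_wild_type,
            "other": pen.n_other,
            "short": pen.n_short,
            "anchor": pen.anchor,
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return summary


# --------------------------------------------------------------------------
# reporting

EDITED_RATIO_THRESHOLD = 0.5


def render_report(rundir: str | Path) -> str:
    """Markdown summary of a run directory: a per-position edits table
    (3'-distance vs observed/expected ratio) and, when present, the
    reciprocal penalty table. Missing tables are listed and skipped."""
    rundir = Path(rundir)
    lines: list[str] = []
    found = False

    obs_exp_path = rundir / "obs_exp.tsv"
    if obs_exp_path.exists():
        found = True
        df = pd.read_csv(obs_exp_path, sep="\t")
        lines.append("## Observed/expected edits by distance from the 3' end")
        lines.append("")
        lines.append("| position | observed | expected | ratio | call |")
        lines.append("|---|---|---|---|---|")
        for _, row in df.iterrows():
            if pd.isna(row["ratio"]):
                call, ratio = "n/a", "-"
            else:
                ratio = f"{row['ratio']:.3f}"
                call = (
                    "edited" if row["ratio"] >= EDITED_RATIO_THRESHOLD
                    else "not edited"
                )
            lines.append(
                f"| {int(row['distance_from_3prime'])} | {row['observed']:.4f} "
                f"| {row['expected']:.4f} | {ratio} | {call} |"
            )
        lines.append("")
    else:
        lines.append(f"missing: {obs_exp_path.name}")

    penalty_path = rundir / "penalty.tsv"
    if penalty_path.exists():
        found = True
        df = pd.read_csv(penalty_path, sep="\t")
        agg = df[df["base"] == "all"]
        lines.append("## Variant-primer fold of expected by position")
        lines.append("")
        lines.append("| position | count | fold of expected |")
        lines.append("|---|---|---|")
        for _, row in agg.iterrows():
            lines.append(
                f"| {int(row['position'])} | {int(row['count'])} "
                f"| {row['fold']:.3f} |"
            )
        lines.append("")

    if not found:
        return "no analyses found\n"
    return "\n".join(lines) + "\n"
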