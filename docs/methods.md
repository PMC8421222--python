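# Methods

## The measurement

Primer editing is the correction of template:primer mismatches by the
3'→5' exonuclease of a proofreading polymerase during PCR, leaving the
amplicon with the template base instead of the primer base. `primedit`
measures it the way it is measured at the bench with synthetic standards:
a pool of constructs carrying every single-base substitution in the
3'-terminal window of the forward primer binding site is amplified with
the wild-type primer, and the per-position frequency of non-reference
bases in the primer region of the reads — normalized by the pool's known
per-position variant share — reports how completely the primer was edited
at each distance from its 3' end. The package implements the in-silico
design of that pool, a generative simulator of the experiments, the
PCR-free barcode quantification of pool composition, and the read-level
analysis.

Positions are indexed by **3'-distance** throughout reporting: position 1
is the primer's 3'-terminal base. Internally the edit matrix is stored
5'-based with a companion 3'-distance column.

## Generative model

Per read, with the variant at 3'-distance *p*:

- editing efficiency `e_p ∈ [0, 1]`: probability the mismatch is edited;
- amplification penalty `a_p ∈ [0, 1]`: relative yield of the unedited
  mismatched duplex (wild type ≡ 1).

Relative yield of a variant construct: `y_p = e_p + (1 − e_p)·a_p`. A read
is drawn from construct *c* with probability ∝ `abundance_c · y_c`, and
conditional on *c* shows the template (variant) base with probability
`e_p / y_p`. The reciprocal variant-primer experiment mirrors this: a
variant primer is edited *back* to the template base with probability
`e_p`, otherwise amplifies at `a_p`, and the read records the final primer
sequence.

This is deliberately an aggregate, cycle-free model — the simplest one
that reproduces both limiting behaviours: near-complete editing drives the
observed/expected ratio to 1 while decoupling it from the penalties, and
zero editing exposes the penalties as fold-of-expected read recovery. It
makes two identification statements exact under the model:

- with `a_p = 1`, the observed/expected ratio equals `e_p`;
- with `e_p = 0` and wild-type anchoring, the fold-of-expected equals
  `a_p`, independent of the pool-mean yield.

Editing is treated as all-or-none at the single variant position
(the standards carry single mismatches only; stepwise excision of
multi-base mismatches is outside what the pool can report).

Phosphorothioate protection is modelled as a hard block: `block_after=b`
means the *b* 3'-terminal bases remain editable and the effective
efficiency is zero beyond them (a bond between the 4th- and 3rd-to-last
bases maps to `b = 3`). `block_after=None` means no block; `b = 0` models
a fully protected primer. Annealing temperature is accepted in the
configuration for provenance and deliberately has no effect: across the
50–60 °C range it does not change editing in this system.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| window | 10 | 3'-terminal positions mutagenized → 3·10 + 1 = 31 constructs |
| flank_len | 20 | flanking bases on each side of the 332-bp insert |
| barcode length / min distance | 20 / 5 | distance ≥ 5 makes ≤ 2-mismatch assignment provably unambiguous |
| barcode max mismatches | 2 | assignment threshold; ties → ambiguous, excluded from proportions |
| primer region length | 19 (fwd), 20 (rev) | locus-specific primer portions of the V4 515F/806R scheme |
| read filter max mismatches | 3 | per-read cap over the primer region; an indel guard under positional comparison |
| merge min overlap / max mismatch | 20 / 10% | ungapped overlap consensus; conflicts take the higher-quality base |
| trim min overlap / max error | 3 / 10% | 3' adapter read-through removal |
| error_rate | 0 (sim default) | uniform per-base substitution probability, constant quality symbol |
| Taq penalty profile | 0.189, 0.318, 0.404, 0.774, 0.922 at positions 1–5 | per-position `a_p` of unedited mismatches with a non-proofreading enzyme; 1.0 beyond |
| complete-editing profile | `e_p = 1` at positions 1–6 | the near-complete editing range of a strong proofreading enzyme |

The editing-efficiency and penalty profiles are the simulator's study
conditions, not free dials: the even 31-pool, the complete-editing window
of 6, and the Taq penalty values above define the scenarios the analyses
are validated against.

## Synthetic data: what it emulates and what it does not

The simulator emulates: pool composition (any abundance table), yield
weighting by editing and penalties, per-position conditional editing,
fully-overlapping paired reads (each mate covers the amplicon end-to-end
by default, so merging is exercised; longer reads run through into the
opposite adapter tail, exercising trimming), uniform substitution
sequencing error, and barcode-first quantification reads free of
amplification bias. The template interior is a seeded-random stand-in for
the real 332-bp *E. coli* V4 region: only the primer binding sites play a
computational role, and the real insert is not bundled.

It does **not** emulate: cycle-by-cycle PCR kinetics, chimeras, indel
sequencing errors (the ≤ 3-mismatch filter is therefore exercised by
substitution pile-ups, not true indels), quality-score variation,
polymerase-specific substitution spectra, or primer-dimer formation.
Passing tests therefore demonstrate correctness of the analysis under the
stated generative model, not robustness to every artefact of real
sequencing runs.

## Numerical and design choices

- **Variant enumeration order**: wild type first, then positions walking
  inward from the 3' terminus, alternative bases alphabetical;
  deterministic so construct ids are stable.
- **Barcodes** are seeded greedy rejection samples; a capacity error is
  raised after a bounded attempt budget rather than looping forever.
- **Barcode ties** (two references at the same minimal distance ≤ 2) are
  counted ambiguous and excluded from proportions — assigning arbitrarily
  would bias composition estimates. Proportion denominators use assigned
  reads only; unassigned/ambiguous/truncated are reported separately.
- **Merging** scans ungapped overlaps longest-first for the minimal
  mismatch fraction (ties to the longest); a zero-mismatch overlap stops
  the scan early since it cannot be beaten. Base conflicts take the
  higher-quality call; equal qualities keep the forward mate's base.
- **Degenerate reference positions** (IUPAC codes in mock-community
  primers) match any compatible base, never count as mismatches, and have
  no defined non-reference proportion (reported as NaN).
- **Observed/expected at expected-0 positions** is undefined (NaN), never
  0 — a position nobody varied carries no information about editing.
- **Penalty anchoring** defaults to `wild_type` because it identifies
  `a_p` exactly under the model; `whole_pool` normalization is provided
  for comparison. Note the wild-type anchor is only meaningful in
  zero-editing runs: with editing active, edited variant primers are
  (correctly) indistinguishable from wild-type reads and inflate the
  anchor.
- **Sequencing-error floor** is estimated from primer positions outside
  the mutagenized window and reported alongside the metric; it is never
  subtracted from the metric itself.
- **Determinism**: every stage consumes a `numpy` Generator seeded from a
  single configuration seed (per-stage fixed offsets), and reruns are
  byte-identical.

## Problem sizes

Simulated checks use 10,000–50,000 reads for editing-efficiency recovery
and 100,000 reads for the penalty recovery — sizes at which three binomial
standard errors of a ~10% proportion are a fraction of a percentage point,
comfortably resolving the effects of interest while keeping a full test
run to a couple of minutes on one core.

## Known limitations

- The analyzer handles indels only via the mismatch-count proxy, exactly
  as the positional-comparison design dictates; gapped alignment is out of
  scope.
- Wild-type-anchored penalties are undefined when no wild-type reads are
  observed (warned, NaN).
- The barcode reference format assumes fixed-length barcodes at the read
  start (restriction-liberated cassettes); mixed-length or internal
  barcodes are not supported.
- The simulator's uniform error model makes the error floor flat across
  positions; real runs show position- and context-dependent error.
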