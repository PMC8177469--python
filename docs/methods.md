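# Methods

This note documents the models, parameters and numerical choices behind
`mirsnv`, and what the synthetic-data generator does and does not emulate.

## Cohort filtering model

Variant identity is the exact tuple (chrom, pos, ref, alt); multiallelic VCF
records are split per ALT, and no further normalization (left-alignment,
decomposition) is applied because all downstream analysis is restricted to
SNVs. Indels are parsed and counted in the consequence report but excluded
from the window/target/folding stages.

Per-sample QC keeps calls with **DP ≥ 100** and **MQ > 30**, using the INFO
fields. The depth rule is stated in two ways by the motivating analyses —
as a strict inequality and as a minimum ("Dpmin") — and we adopt the
inclusive floor, exposed as `dp_min`; MQ has only one phrasing and stays
strict. Calls missing DP or MQ are dropped at this stage (a call whose
evidence cannot be checked is not evidence).

Two cohort modes are implemented, selected by `mode`:

* `dual_caller` (default): per sample, the intersection of the two
  per-mapper call sets (DP/MQ become the per-caller minimum), then a
  recurrence screen keeping variants carried by ≥ `k_min` patients
  (default 10).
* `strict_all`: the second mapper's calls alone, required in every patient.

In `control_mode="strict"` (default) a variant observed in **any** control
sample is removed outright, independent of patient recurrence; whether the
recurrence rule of the source analysis also enforced control absence is not
documented for the dual-caller mode, so the strict behaviour is the default
and `ignore` is available.

## Consequence classification

Single-transcript gene models (exons + one CDS span, 1-based inclusive,
GFF3 convention) define five categories: missense, 3'-UTR, 5'-UTR, intronic,
other. Positions are lifted strand-awarely into spliced transcript
coordinates; coding changes are translated with the standard genetic code,
with synonymous changes, near-gene (±5 kb) and intergenic positions folded
into *other* (subtype kept in a detail field, matching reports that collapse
these). Start/stop-disrupting substitutions are reported as missense with a
stop_gained/stop_lost detail rather than as separate categories. When a
variant hits several transcripts the most severe category is reported
(missense > UTR > intronic > other); the generator emits one transcript per
gene, so this path is exercised only by user-supplied annotations.

## Windows and queries

Each 3'-UTR SNV gets a 71-nt window with the variant base at position 36
(the structure unit) and an 11-nt query with it at position 6 (the
candidate-site unit). Windows are cut from the spliced transcript and
transcribed T→U; a variant closer than 35 nt (resp. 5 nt) to a transcript
end is skipped and logged rather than padded — truncated windows would not
be comparable across variants. Adjacent co-occurring SNVs are by default
folded one at a time, each window pair carrying only its own alternate
allele; `phase_adjacent=True` writes all co-occurring recurrent SNVs of the
transcript into both windows of each pair (the pair still differs only at
its own position 36). Both behaviours are provided because multi-SNV loci
(e.g. adjacent doublets) can plausibly be analysed either way and the
choice changes the folding substrate.

## miRNA site model

Canonical seed sites are defined from the miRNA seed span (default
positions 2–8): the target core is the reverse complement of seed positions
2–7, extended to 7mer-m8/8mer by a match opposite position 8 and to
7mer-A1/8mer by an adenosine opposite position 1. Seed matching is strict
Watson–Crick; G:U is not accepted in the seed. Only the maximal site type
is reported per locus. The seed span is configurable (some conventions use
2–9), but 2–8 is the default because the 8mer/7mer/6mer taxonomy is defined
on it.

The second predictor is a hybridization-energy dynamic program over
antiparallel inter-molecular pairings (no intramolecular structure):

| term | value |
|---|---|
| G:C pair | −3.0 kcal/mol |
| A:U pair | −2.0 kcal/mol |
| G:U pair | −1.0 kcal/mol |
| stack (contiguous pairs) | −1.0 kcal/mol |
| bulge/internal loop opening | +2.0 kcal/mol |
| loop extension | +0.5 kcal/mol per unpaired residue |

Dangling ends are free and the empty pairing scores 0, so reported energies
are ≤ 0. The DP is exact for this model; the test suite checks it against
exhaustive enumeration of all pairings for lengths ≤ 8.

**Consensus rule**: a miRNA is reported for a window iff a canonical seed
site overlaps the SNV position *and* the duplex energy of the miRNA against
the site ±10 nt of context is ≤ `energy_threshold` (default −8.0 kcal/mol).
The threshold was set so that any planted exact 8mer passes (a 7-pair
Watson–Crick seed helix scores ≤ −20 even when AU-only) while isolated
low-complementarity 6mers in weak context mostly fail; it is exposed as a
flag, and lowering it can only remove sites (monotonicity is tested).
Gains/losses are the set differences of reference-window and
variant-window consensus miRNA sets; a miRNA present on both windows is
neither.

## Folding engine

`fold_mfe` is a Nussinov-style minimum-energy dynamic program with the same
pair scores as the duplex model, a −1.0 stacking bonus for directly nested
pairs, hairpin loops of at least 3 unpaired residues, and no pseudoknots.
Three tables (any structure / endpoints paired / endpoints not mutually
paired) make the stacking bonus exact; the traceback is deterministic,
pairing the smallest available 5' index with its smallest admissible
partner among optimal choices. Correctness is checked against exhaustive
enumeration for lengths ≤ 12.

This is intentionally **not** a Turner nearest-neighbour model: no
parameter tables, no temperature, no ensemble. Absolute energies are
therefore not comparable to published folding-server values, and the
engine's role is comparative — reference vs variant window under one
self-consistent score, summarized as Δ energy and base-pair distance (the
symmetric difference of the two pair sets). ΔG carries no expected sign;
on both synthetic and published data, SNVs stabilize some segments and
destabilize others.

One symmetry subtlety: folding energy under this model is *not* invariant
under reverse complement in general, because a G:U wobble maps to an
inadmissible A:C (GAAAU folds at −1.0, its reverse complement AUUUC at
0.0). The invariance holds exactly when only Watson–Crick pairs are
available, and the tests assert that restricted form.

## Synthetic cohort generator

Defaults mirror the motivating study design: **35 patients, 3 controls**,
two call sets per sample, **30 planted gains + 30 planted losses** at
recurrence uniform in **[10, 35]**, DP in [120, 400], MQ in [40, 60],
caller overlap 0.8 for background calls, 96 genes (one planted variant per
gene), 60 miRNAs with pairwise-distinct seeds (rejection sampling),
transcripts of 700–1,100 nt with non-empty 5'-UTR (≥60), CDS (90–300,
multiple of 3) and 3'-UTR (≥240), 1–3 exons, both strands, one contig per
gene. Gene/transcript/intron sizes are compact stand-ins chosen so a 71-nt
window always fits in the 3'-UTR; they are not drawn from human genome
statistics.

A planted gain writes an exact 8mer site (reverse complement of the target
miRNA's seed 2–8 plus A) into the transcript so that the site interval
contains the variant position, then breaks one core position in the
*reference* allele; a loss is the mirror case. Placements are validated
with the seed scanner (site present with type 8mer on exactly one window,
absent on the other) and retried on collision, failing with a diagnostic
after 80 attempts. Five decoy classes (each ~10% of the planted count) give
every filter a test surface: sub-recurrence (k_min−1 carriers), sub-DP
(DP < 100), sub-MQ (MQ ≤ 30), single-caller, and control-shared. All
outputs (FASTA, GFF3, VCFv4.2 with DP/MQ INFO fields, truth/decoy TSVs) are
byte-identical for a fixed seed.

What the generator does **not** emulate: read-level noise and mapping
artefacts (calls appear atomically, not from pileups), allele frequency
and zygosity (presence/absence only, as the downstream analysis uses),
indels, linkage between variants, overlapping genes, multiple transcripts
per gene, and realistic human UTR length/composition distributions.
Passing the planted-truth suite therefore demonstrates that the *pipeline
logic* (filters, coordinate lifting, scanning, consensus, diffing) is
correct under the stated study design — not that the predictors are
accurate on real human 3'-UTRs.

## Packaged reference table

`mirsnv/data/gainloss_table.tsv` transcribes a published MTLE cohort's
per-gene summary of miRNA binding sites gained and lost through recurrent
3'-UTR SNVs (26 gene rows). Each cell of the source table prints a count
followed by a parenthesized miRNA list; the fixture keeps both
(`n_gained`/`n_lost` and the id lists), with blank and "Nil" cells as empty
sets. The printed table is internally inconsistent in one place: the
ATP1A2 lost cell counts 14 but enumerates 13 ids, so the per-row lost
counts sum to 68 while the accompanying prose states 69. Totals computed
by this package use the printed per-row counts (68); the gain-side numbers
(51 sites over 18 genes) and the 19 genes with losses are consistent
across counts, lists and prose. Genes with both gains and losses are
flagged `mixed` and excluded from the gain-only/loss-only lists, matching
the source analysis, which did not analyse such genes further.

## Problem sizes used in verification

The acceptance script and test suite verify: the fixture aggregation
(26 rows); the folding engine against enumeration on 500 random sequences
of length ≤ 12 and the duplex engine on 500 random pairs of lengths ≤ 8
(exhaustive enumeration above these lengths is wasteful, and every DP
recursion case is already exercised well below them); and planted-truth
recovery on the full default cohort (35+3 samples, 60 planted variants, 30
decoys, ~76 VCFs round-tripped through disk). These sizes were chosen as
the smallest that cover the design; the whole verification runs in seconds.

## Known limitations

* Both target predictors are deliberately minimal: no conservation,
  context features, 3'-supplementary pairing or AGO-footprint evidence;
  expect many incidental 6mer/7mer calls on real sequences relative to
  dedicated target predictors.
* The folding model ignores loop-size penalties and coaxial stacking;
  structures are single optima, not ensembles, so bp_distance between two
  near-degenerate optima can overstate the structural effect of a variant.
* One transcript per gene is assumed wherever the generator's data is
  used; isoform-aware analysis requires supplying per-transcript models.
* The VCF reader trusts INFO DP/MQ; FORMAT-level per-sample depths are not
  consulted (the expected inputs are single-sample VCFs).
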