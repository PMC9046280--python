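# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want written down.

## Interval model and the overlap rule

Intervals are 0-based half-open (BED convention); every reader converts into
this and every writer converts out of it. The *peak center* is the summit
(narrowPeak column 10) when one is called and the floor midpoint otherwise —
summits carry the signal maximum, midpoints are the only option for plain
BED.

Two peaks overlap when `overlap_length > min_frac · length` holds for **at
least one** of the two peaks (`min_frac` = 0.5 by default, strict
inequality). The phrase "either peak" admits a reciprocal reading too, so
`mode="both"` implements the stricter variant; the inclusive reading is the
default because it matches the common bedtools-style
"fraction-of-either" usage. Partitioning is per interval: an interval of A
is *shared* iff it overlaps ≥ 1 interval of B. The implementation indexes
intervals with an interval tree; tests compare it against a vectorized
all-pairs oracle, which is also re-run by the acceptance script.

All interval outputs are sorted (chromosome lexicographic, then start, then
end) so every run is deterministic.

## Peak annotation

Classification is by peak center, not whole-interval overlap — that is how
HOMER's annotatePeaks behaves and it guarantees the categories partition the
peak set. Priority: promoter > TTS > exon > intron > intergenic, evaluated
across all genes on the chromosome. Windows (config-exposed, defaults
HOMER-like since upstream tools rarely print theirs):

| parameter           | default | meaning                                   |
|---------------------|---------|-------------------------------------------|
| promoter_upstream   | 1000 bp | upstream of the TSS, strand-aware         |
| promoter_downstream | 100 bp  | downstream of the TSS                     |
| tts_window          | 100 bp  | each side of the transcript end           |

The nearest gene minimizes |center − TSS| (ties: lexicographically smallest
gene_id); the signed TSS distance is negative upstream in the gene's own
orientation. Gene models are gene-level: duplicate gene_ids are rejected,
multiple exon rows are merged, and when exon rows extend past the stated
span the extreme span wins. UTRs are not distinguished from exons.
"Enhancer" means exactly intronic or intergenic.

## Motif model and enrichment

A motif is an IUPAC consensus (exact degenerate matching, implemented as a
regex with a lookahead so overlapping occurrences are all found) or a
4 × width probability matrix scored as log2 likelihood ratio against a
uniform 0.25 background, pseudocount 0.001 per cell, with a per-motif bit
threshold supplied in the motif file (thresholds are inputs, not constants).
Both strands are scanned; `N` in the sequence matches nothing concrete and
scores −∞ in matrix mode. A peak *carries* a motif when its ±50 bp
center window has ≥ 1 hit — presence/absence, not hit count.

Enrichment of a target peak set against an explicit background peak set
(the comparison set of the figure at hand, not GC-matched random draws — GC
matching is out of scope) is the upper-tail cumulative hypergeometric
probability with the population being the union of both sets. The kernel is
implemented once, in log space (log-gamma binomial terms combined with
logsumexp), and shared by motif enrichment and pathway ORA; `k = 0` returns
exactly p = 1. Tests check it against exact rational enumeration for every
population size up to 30 at 1e−10 relative error.

Motifs are ranked by natural-log p (ties: motif name, so ranking is total
and reproducible); two ranked conditions are compared by
`shift = rank_A − rank_B`, positive = climbed in B. Both tables must cover
the same motif universe; anything else is an error, not a silent join.

## Expression

Median-of-ratios size factors: reference = per-gene geometric mean over
genes with all-positive rows (genes with any zero are excluded, the standard
behavior); a sample's factor is the median ratio to the reference. Factors
are then divided by their geometric mean. This centering fixes the overall
scale — only relative factors are identified — and makes normalization
exactly idempotent (re-estimating on a normalized matrix returns factors 1);
uncentered factors return their geometric mean instead, which on finite data
is close to but not exactly 1.

log transform is log2(x + pseudocount), pseudocount 1 by default
(config-exposed). Z-transformation is per gene with the **population**
(n-denominator) SD — the transform feeds visualization and scoring, not
inference — and zero-variance rows become all-zero with a logged warning.
Group fold change is log2((mean_B + 1)/(mean_A + 1)). No differential-
expression testing is implemented; externally computed log2FC tables are
accepted everywhere one is consumed.

## Integration

A peak links to every gene with |peak center − TSS| ≤ 50 kb (inclusive
boundary; distance to the TSS rather than the gene body, for
strand-awareness and consistency with annotation — the gene-body variant
would only grow link sets). Activated: ≥ 1 gained-peak link and
log2FC > +1 strict; repressed: ≥ 1 lost-peak link and log2FC < −1 strict. A
gene meeting both rules at once (possible only with unusual thresholds) is
reported unchanged with a conflict flag. "Newly accessible" is defined
set-theoretically through the unique regions of a two-condition partition,
not by differential signal testing. No significance filter is applied on
top of the fold-change thresholds.

## Signatures

Scores are raw sums over the signature genes found in the matrix —
z-score-sum for cohort-style matrices, log2(x+1)-sum for FPKM/TPM cell-line
matrices — matching the printed formulas of the scores they reproduce;
missing genes are skipped and counted, and the found-gene count is always
reported because scores are comparable across matrices only at equal
coverage. Derivation: strict intersection of ≥ 2 cistrome gene sets, then
log2FC > 2 strict ("significantly higher" is operationalized as the printed
fold-change cut alone; no p-filter is printed anywhere for it). ORA
intersects each pathway with the stated universe, rejects queries outside
the universe, and adjusts with Benjamini–Hochberg (the adjustment procedure
is not named upstream; BH is the field default for FDR panels).

## Synthetic-data generator

The generator emulates the *structure* of a two-(or more-)condition
accessibility study: uniform-background genome (default 2 × 250 kb),
non-overlapping 2–4-exon genes, peak loci of width 200–600 bp that are
either shared by all conditions or unique to one, realized per condition
with jitter bounded by a tenth of the width (so same-locus realizations
always satisfy the overlap rule and different loci, kept ≥ 200 bp apart,
never do), negative-binomial counts (variance = mean + dispersion·mean²,
dispersion 0.05 by default; 0 gives Poisson) with per-sample size factors,
and planted activated/repressed genes (log2FC ±2) whose gained/lost peaks
sit within linking distance of their TSS. The last condition is the
perturbed state. Defaults mirror the scale of the validation experiments:
e.g. the planted-motif study uses 200 target windows at carrier rate 0.6
against 2,000 background windows at 0.05, and the classification study
plants 50 activated + 50 repressed genes among 1,000.

Motif truth is exact by construction: carried instances are written into
the genome inside the window, and chance occurrences of non-carried motifs
inside any window are re-randomized away (planted positions are protected;
a 2 bp spacing between planted slots guarantees a rewritable position for
any hit spanning two slots; if a planted instance of one motif embeds
another motif the whole window is re-drawn, up to 25 attempts). Carrier
rates are keyed per design group (`shared`, `unique_<condition>`, with a
`default` fallback) so a shared locus carries one consistent flag across
conditions. For the rank-differential experiment, decoy motifs are planted
at elevated rate in the baseline-unique peaks — without a competing motif
structure in the baseline the "largest positive shift" readout is not
identifiable, since the focal motif may already rank first there by chance.

Randomness: a single integer seed drives one named substream per artifact
kind (genome, gene classes, peaks, expression, scoring matrix), so text
outputs are bytewise reproducible and regenerating one artifact does not
perturb the others.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level noise and peak-calling uncertainty,
GC/dinucleotide sequence composition (background is uniform), correlated
fragment-size or signal-strength structure, overlapping genes and isoform
complexity, motif position-weight degeneracy beyond IUPAC codes, and
library-level expression covariation beyond size factors. Results on real
studies depend on the upstream alignment/peak-calling choices that are
explicitly out of scope here.

## Problem sizes and runtime

The test suite and the acceptance script size their simulations to the
documented validation experiments: 100 random instances of 1,000 intervals
for the partition oracle, all populations ≤ 30 for the hypergeometric sweep,
2,200 peak windows for motif recovery, 1,000 genes for classification, and
2,000-gene count matrices over 5 seeds for size-factor recovery. The whole
suite runs in about half a minute and the acceptance script in about twenty
seconds on one CPU.

## Known limitations

* The GTF reader covers the gene/exon subset with `gene_id` attributes that
  the package writes and consumes; it is not a general GFF3/GTF parser.
* Consensus matching is exact (a single mismatch is a non-hit); matrix mode
  exists for graded matching but default simulations use consensus motifs.
* Enrichment backgrounds are user-supplied peak sets; no GC-matched random
  background generation.
* `rank_differential` requires identical motif universes; partial overlaps
  must be reconciled by the caller.
* Multi-condition designs share one "shared" group across all conditions;
  arbitrary overlap topologies (e.g. a locus shared by conditions 1–2 only)
  are not expressible in the generator config.
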