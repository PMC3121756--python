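# Methods

## Scope and model of the system

The package analyses pairs of haplotypes of a tandemly amplified gene
family locus (the motivating system is the maize α-zein family: clusters of
19- and 22-kDa storage-protein genes at six loci, compared between two
inbreds). The observable events are (i) tandem gene duplications, (ii)
LTR-retroelement insertions — shared between haplotypes, specific to one,
or nested inside older elements — and (iii) the downstream consequences for
expression and promoter methylation of individual gene copies.

## Divergence estimation and the molecular clock

**K2P.** Transition (P) and transversion (Q) proportions are counted over
aligned columns after *pairwise deletion*: any column containing `-` or `N`
in either sequence is removed. The distance is
`K = -½ ln((1-2P-Q)√(1-2Q))`, with the delta-method variance
`[c₁²P + c₃²Q − (c₁P + c₃Q)²]/n`, `c₁ = 1/(1-2P-Q)`, `c₂ = 1/(1-2Q)`,
`c₃ = (c₁+c₂)/2`. Arguments ≤ 0 raise a saturation error rather than
returning a number. Unaligned pairs are first globally aligned with affine
gaps (match +1, mismatch −1, gap open 5, extend 1); the `prealigned` flag
bypasses this.

**Ks (NG86).** For in-frame coding pairs, synonymous sites per codon are
the fraction of the three possible changes per position that preserve the
amino acid (changes to stops count as non-synonymous); S is averaged over
the two sequences. Synonymous differences average over all minimal
mutational pathways between differing codons, excluding pathways through
stop codons whenever a stop-free pathway exists. Codon pairs containing a
stop, gap or ambiguity are excluded from the site counts. `ps = Sd/S` is
Jukes–Cantor corrected: `Ks = -¾ ln(1 - 4ps/3)`; `ps ≥ 0.75` saturates.
LTR divergence is deliberately computed as plain K2P (LTRs are non-coding);
NG86 is reserved for coding sequence. Both are exposed, so gene pairs can
also be dated with K2P on the whole gene if preferred.

**Clock.** `age = K / (2r)`: both copies of the duplicated state accumulate
substitutions independently after the event. Defaults: `gene_rate
6.5×10⁻⁹`, `ltr_rate 1.3×10⁻⁸` substitutions/site/year (the LTR compartment
evolves twice as fast as genes), `kappa 2`. The rate used is recorded in
every dated event; a clock whose LTR/gene ratio is not 2 is accepted with a
warning. Ages are reported in mya with the SE propagated from the distance
variance.

## Trees

NJ follows the Saitou–Nei Q-criterion, `Q(i,j) = (n-2)d(i,j) - Σd(i,·) -
Σd(j,·)`, and is exact on additive matrices; UPGMA is average linkage with
node height = merge distance / 2, exact on ultrametric matrices. Negative
NJ branch lengths are clamped to zero with the deficit shifted to the
sibling branch. All argmin tie-breaks take the lowest (row, column) index
pair, making topologies platform-deterministic. Bootstrap resamples
alignment columns with replacement; support is the percentage of successful
replicates containing each internal bipartition of the full-data tree;
replicates with a saturated pair are skipped, counted and warned about, and
the support denominator is the number of successful replicates.

## Synthetic data generator

The generator's substitution process is K2P with the *exact* sojourn
probabilities: for divergence d and ratio κ, `βt = d/(κ+2)`,
`αt = κ·βt`, `P = ¼ + ¼e^{-4βt} - ½e^{-2(α+β)t}`, `Q = ½ - ½e^{-4βt}`.
Because the K2P estimator is the method-of-moments inverse of these
expressions, distances estimated between an input and its evolved output
converge to the configured divergence — the estimator/generator closure the
recovery tests rely on. (The first-order scheme `P ≈ κd/(κ+2)` would bias
the estimate upward by ~14% at d ≈ 0.17 and was rejected for that reason.)

A locus pair is built from an ancestral backbone (flank, then
promoter + CDS + intergenic spacer per copy). Each gene copy and its
promoter are evolved from family ancestors by `age × gene_rate`; a pair of
copies with ages t₁, t₂ therefore shows divergence `(t₁+t₂)·r`, and dating
the pair recovers the mean of the two ages. Retroelements are
`LTR + body + LTR` with both LTRs independently evolved from one ancestral
LTR by `age × ltr_rate` (expected LTR–LTR divergence `2·age·ltr_rate`), and
every element is flanked by an identical target-site duplication (default
5 bp — a typical LTR-element TSD; the annotations this emulates do not state
lengths). Haplotype-specific elements appear only in their carrier; nested
elements are placed inside the host body (never inside an LTR) and must be
younger than the host. Coordinates are produced by a single linearization
sweep over backbone events, so shared-element coordinates never depend on
haplotype-specific ones. Shared sequence is byte-identical between the two
haplotypes: inter-haplotype SNP divergence, indel evolution, recombination
and solo-LTR formation are *not* simulated, so a green recovery test
establishes estimator correctness under the model, not robustness to
alignment error.

Default stated world: five copies with ages (11.9, 2.2, 1.4, 0.6, 0.5) mya;
retroelements (6.2 shared, 2.04 shared, 1.19 nested in the 2.04 element,
0.12 haplotype-specific, 0.0 nested + specific with identical LTRs); one
copy carrying 90% of transcripts and one silent (fractions 0.02, 0.03,
0.05, 0.90, 0.0); 288 clones (three 96-well plates) at 0.5% per-base error;
96 bisulfite reads per tissue at 0.5% conversion failure; default promoter
methylation: five 90%-methylated CG peaks over a 5% background, mirroring
the five highly methylated cytosines reported for the z1A promoters.

Clone libraries draw source copies multinomially and apply uniform per-base
substitution error; bisulfite reads are generated from the top strand only,
retaining each C with probability `p + (1-p)·fail`. All randomness flows
from one integer seed through named `SeedSequence` child streams (ancestor,
per-copy, per-element, placement, methylation), so outputs are byte-stable.

## Expression attribution

Assignment is by best *local* alignment score (match +1, mismatch −2, gap
open 5, extend 2) against every reference copy — a deterministic,
platform-stable stand-in for a BLAST best-hit search. `score_min` defaults
to 80% of the clone's self-alignment score; a best-vs-runner-up margin
< 2 score units is *ambiguous*. Ambiguous and unassigned clones are
excluded from the percent denominator but reported, rather than split
fractionally — conservative and auditable. Profile comparison classifies
each copy: reactivated (zero reference clones, alternate percent at or
above the alternate library's detection threshold), silenced (reverse), and
enhanced/reduced only when fold-change ≥ 2 *and* a two-sided Fisher exact
test on the 2×2 clone-count table gives p < 0.05; otherwise unchanged.
Reciprocal-cross samples are ordinary samples distinguished by label; no
imprinting statistics are computed.

## Bisulfite methylation

Analysis is top-strand only (one primer pair per locus amplicon);
bottom-strand symmetric-CG methylation is not inferred. Context is assigned
from the reference alone: CG, then CHG (H = A/C/T), then CHH; trailing Cs
with fewer than two 3′ bases default to CHH and are flagged. Reads align to
the reference with conversion-aware matching (reference C matches read C or
T); reads under 90% conversion-aware identity are dropped and counted. At
each reference C, read C counts methylated, T unmethylated; any other base
is treated as sequencing error and excluded from that site's coverage. No
conversion-efficiency correction is applied (no spike-in exists in this
design); the overall converted fraction is reported as a QC note. Tissue
comparisons mask sites with coverage < 10 in either profile.

## Annotation summaries

Copy status precedence is `re_disrupted > start_loss > truncated >
premature_stop > intact`: a physical insertion dominates point defects.
This arbitration and the truncation threshold (length < 0.8 × intact model
length, or no in-frame stop) are this package's choices — the source
descriptions list the categories without ordering them — and both are
configurable. Motif offsets are measured from the A of ATG to the motif's
5′-most (farthest) base in the window, so an 8-bp prolamin box spanning
300–293 bp upstream reports offset 300; the O2 motif ships as the
consensus `TCCACGTAGA`, a stand-in since no consensus is printed in the
motivating work, and is replaceable. Composition paints every base with
precedence RE > DNA-TE > genic > intergenic (nested elements counted
once); the four percentages sum to 100 ± rounding. Conserved coverage uses
exact 50-mer seeds grouped by alignment diagonal, chained within 200 bp,
verified base-by-base, and retained at ≥ 95% identity and ≥ min_block
length — invented plumbing standing in for a BLAST comparison, adequate for
indel-structured haplotype pairs but not a general aligner. The helitron
check requires 5′-TC, CTAG-3′, and a hairpin (≥ 8-bp self-complementary
stem, loop ≤ 12 bp) within 100 bp of the 3′ end.

## Pipeline

`validate_config` fills defaults and reports all violations at once;
`run_pipeline` executes generate → date → tree → annotate → express →
methylate → report and writes fixed-name TSV/Newick/JSON artifacts plus a
manifest (versions, seed, clock, per-stage record counts). Synthetic-mode
bundles are byte-identical for identical (config, seed). The pipeline's
tissue-culture comparison reactivates the first silent copy with 20% of the
pool taken from the dominant copy, and raises every methylation probability
by 0.25 in the cultured tissue — fixed, documented stand-ins for the
"epigenetic resetting" contrast, not fitted quantities.

## Numerical conventions and degenerate inputs

Internal coordinates are 0-based half-open; GFF3 I/O converts at the
boundary. Minus-strand features are returned reverse-complemented. `N`
bases are allowed in contigs but excluded from all distance and site
counts. Zero comparable sites, zero assigned clones and zero usable reads
raise typed degenerate-input errors instead of returning NaN. `-0.0`
values from log/clamp arithmetic are normalised to `0.0`. TSD features are
children of their retroelement but lie outside its span by nature; GFF3
validation therefore requires `tsd` children to abut (not nest within)
their parent, while `ltr` and nested children must be contained.

## Known limitations

- No indel evolution, recombination, gene conversion, solo-LTR formation
  or rate heterogeneity in the generator; no ML/Bayesian trees; no
  codon-model (GY94) Ks.
- NG86 with κ > 1 is known to be slightly biased for synonymous sites;
  gene-age recovery tests therefore use the generator's truth ledger
  semantics (pair age = mean of the two copies' ages) rather than asserting
  unbiasedness of Ks itself.
- The delta-method ±2 SE interval undercovers at very small expected
  substitution counts (~82% coverage at ~3 expected substitutions on a 1-kb
  LTR pair, vs ~95% for older elements) — an intrinsic small-count Wald
  property, visible in the recovery tests' pooled coverage assertion.
- Per-locus composition percentages depend on annotation completeness; the
  conserved-coverage definition (window, seeding, counting) is one of many
  reasonable ones and is stated above rather than matching any external
  tool exactly.
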