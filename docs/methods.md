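# Methods

This note records the models implemented in `refforge`, the parameter
choices that matter, what the synthetic benchmark does and does not
emulate, and the numerical conventions a user should know before relying
on the outputs.

## Identity search

Short reads are aligned to full-length references with an end-gap-free
("semi-global") affine-gap alignment via Biopython's `PairwiseAligner`:
global mode with zero-cost end gaps, so a 450 bp read sits inside a 1.5 kb
reference without overhang penalty. Scoring defaults are megablast-like —
match +2, mismatch −3, gap open −5, gap extend −2 — with the convention
that a gap of length L costs `gap_open + L·gap_extend`. Note the standard
semi-global semantics: an overhang of *one* sequence past the other's end
is free at each alignment end; a read and reference that share only an
internal patch flanked by dual overhangs are penalized as in a global
alignment. For the intended geometry (read contained in reference) this
never binds.

Percent identity is `100 · matches / columns`, where columns counts every
alignment column — including internal gaps — between the first and last
aligned pair (the BLAST `pident` convention). Strata are formed after
rounding identity to one decimal, so ≥97 % admits 96.95. Queries are
searched on both strands and the better hit wins; ties break by higher
identity, then lexicographically smaller reference id. A k-mer prefilter
(word size 11, minimum one shared word) selects alignment candidates; at
these settings the acceptance suite verifies the prefilter loses nothing
relative to exhaustive alignment. Hits below 75 % identity are reported
as no-hit.

The identity-gap augmentation rule selects a candidate ASV when at least
one query reaches ≥97 % identity against the candidate database while
scoring <97 % (or unaligned) against the base database; selected ASVs are
merged into the base with candidate taxonomy, suffixing `+pac` on id
collisions.

## Trees and trimming

Pairwise distances are Jukes–Cantor corrected mismatch fractions over
aligned non-gap columns, `d = −(3/4)·ln(1 − 4p/3)`, raising a saturation
error at p ≥ 0.75. Trees come from scikit-bio's neighbor joining with
negative branch lengths clamped to zero; externally built newick trees
are accepted anywhere a tree is consumed.

Trimming iterates over "cherries" — sister-tip pairs whose pendant edges
are both shorter than the threshold — always collapsing the pair with the
smallest pendant sum first. The tip with lower sample prevalence is
dropped (ties: shorter sequence, then lexicographically larger id); when
the collapse leaves a unary node, the survivor absorbs the parent edge.
Because rooted representations of an unrooted tree can hide sister
relations (an NJ root placed inside a tight cluster turns it into a
caterpillar), a degree-2 root is suppressed onto its internal child
before each pass. Sub-threshold singleton tips without a qualifying
sister are retained, so every clade keeps at least one representative.
The default threshold sweep is {0.0005, 0.001, 0.002} substitutions/site,
and the pipeline's optimizer keeps the largest threshold whose ≥97 %
identity fraction stays within a tolerance (default 2 percentage points)
of the untrimmed database.

The exact tip-drop policy inside a sub-threshold group is a genuinely
open design point (iterative vs one-shot, which tip survives); the
prevalence-first rule was adopted because the whole point of trimming is
to keep the representative most supported by samples, and it is the only
rule under which the planted-redundancy benchmark has a well-defined
expected outcome (the original, which carries the prevalence).

## Classifier

The classifier is an RDP-style bootstrap naive Bayes over 8-mers. Each
reference contributes the set of words occurring in it or its reverse
complement, so read orientation never matters. With N references and
n(w) of them containing word w, the prior is `P(w) = (n(w)+0.5)/(N+1)`
and the per-reference conditional `P(w|ref) = (m(w)+P(w))/(M+1)` with
m(w) ∈ {0,1} and M = 1. A query is scored by `Σ log P(w|ref)` over its
words; the full-word argmax fixes the reported lineage, and 100
bootstraps over `⌊W/8⌋` words drawn with replacement vote on it. Per-rank
confidence is the fraction of votes agreeing with the reported lineage up
to that rank (hence non-increasing with depth), and the lineage is
truncated at the deepest rank with confidence ≥ 0.8. Word size,
bootstrap count, subsample fraction and cutoff are the published defaults
of this classifier family; all are exposed as parameters. Vote
aggregation is per-reference then lineage-lifted rather than pooled per
taxon — simpler, and it preserves species-level resolution between
near-identical references.

Rank-collapsed abundance tables place a read truncated above rank r into
an `<assigned prefix>;unassigned` bin at r, so per-sample relative
abundances sum to 1 at every rank while the species-resolution deficit of
a coarse database stays visible.

## Diversity

Chao1 is always the bias-corrected form `S + f₁(f₁−1)/(2(f₂+1))` (finite
at f₂ = 0); Shannon uses natural logs with zero counts skipped;
Bray–Curtis is `Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)`; PCoA is classical Gower-centered
eigendecomposition (scikit-bio), with non-positive-eigenvalue axes
dropped from the coordinates but the full spectrum reported. Counts are
not rarefied before diversity — depth normalization is the caller's
choice.

## LEfSe

Feature tables are total-sum scaled to 10⁶ per sample. Stage one screens
each feature with a tie-corrected Kruskal–Wallis test at α = 0.05
(all-identical input degenerates to H = 0, p = 1 rather than erroring).
Stage two computes, over 30 bootstraps that subsample two-thirds of each
class (≥2 samples per class, redrawing up to 10 times), a Fisher LDA on
the survivors; with more than two classes, one-vs-rest is fitted and the
per-feature maximum taken. A feature's per-bootstrap effect is
`(|w_f|·Δ + |μ₁,f − μ₂,f|)/2` with w the unit-normalized discriminant and
Δ the projected class-mean separation; the reported score is
`log10(1 + mean effect)` and significance requires both the screen and
score > 3. The subclass (pairwise Wilcoxon) stage of the original
procedure is deliberately omitted: the package models flat class
structure only. The Fisher solve uses a small ridge
(10⁻⁶ · tr(S_w)/p) for singular within-class scatter.

Because scaling fixes the per-sample total at 10⁶, effect sizes are
abundance-scale quantities: abundant features need smaller relative
shifts to clear the score-3 cutoff, and a strongly enriched feature
depresses the scaled abundance of everything else (compositional
coupling). Both behaviors are inherited from the procedure being
modeled, not artifacts.

## Synthetic communities

The generator emulates a pooled full-length amplicon study. A Yule
(pure-birth) process produces an ultrametric taxon tree whose root-to-tip
depth is rescaled to 0.15 substitutions/site — a within-domain 16S
divergence scale. Sequences (default 1,500 bp; shorter worlds are used
where only the V3-V4 window matters) evolve along the tree under exact
per-branch Jukes–Cantor transitions, with substitution masked inside two
primer windows (positions 340–360 and 780–805, 0-based half-open) and
four further conserved blocks, mimicking the conserved/variable
architecture of the 16S gene. The V3-V4 amplicon is the primer-to-primer
excision (465 bp, inside the 380–470 bp envelope).

Taxonomy is read off the tree by cutting it at six fixed depths (domain
is constant): phylum through family at 25/40/55/70 % of the tip depth,
genus at depth −0.03 and species at depth −0.012. The last two cuts
guarantee that distinct species labels imply ≥0.024 substitutions/site of
path separation — resolvable in the V3-V4 window — while taxa closer than
that share a label, which is exactly how classification accuracy is
scorable. These labels are a modeling stand-in for real taxonomy; no
biological claim attaches to them.

Samples draw a taxon subset with lognormal relative abundances
(σ = 1 by default). Reads are substitution-only (default error 0.001
full-length, 0.005 V3-V4, emitted on a random strand); an indel-free
error model keeps identity arithmetic exact for the test oracles. The
redundancy generator plants duplicates carrying exactly
`round(p·n_unmasked)` substitutions (minimum 1) rather than a Poisson
draw, so within-group distances are guaranteed below the trim threshold
rather than merely expected to be.

What the generator does **not** emulate: indels and homopolymer errors,
chimeras, PCR and copy-number bias, uneven primer binding, and real
taxonomic label structure. Tests passing on these worlds therefore
demonstrate the correctness of the algorithms under their stated
assumptions, not field performance on real sequencing runs.

## Problem sizes and numerical conventions

The test and acceptance workloads use deliberately compact instances —
reference databases of 10–48 sequences of 0.5–1.5 kb, tens of reads per
evaluation, 20-to-40-taxon worlds — chosen so each property is decisive
while the whole suite runs in minutes on one CPU; all sizes are set in
one place in the tests and scale up without code changes. Seeds propagate
from a single master seed through `numpy.random.default_rng` spawns.
All coordinates are 0-based half-open. FASTA is written 60-column
wrapped; taxonomy is written in the prefixed 7-rank dialect
(`d__...;p__...`) and read in both bare and prefixed forms; newick
round-trips preserve lengths to well beyond 10 significant digits.
Classifier models serialize to a versioned JSON container.

## Known limitations

- The aligner wraps Biopython's `PairwiseAligner`; alignments of two
  essentially unrelated sequences still return a score and identity,
  which the 75 % no-hit floor — not an E-value — filters.
- Trimming decisions depend on the tree; a poor tree (saturated
  distances, non-additive noise) yields defensible but different
  representative choices.
- LEfSe power/type-I figures are Monte-Carlo estimates on exchangeable
  lognormal nulls; heavy-tailed or zero-inflated real tables will differ.
- `compare_dbs` assumes every sample's reads fit in memory; the toolkit
  targets desk-scale curation studies, not production pipelines.
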