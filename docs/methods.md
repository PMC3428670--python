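# Methods

## The subtraction model

A ZZ male genome contains every autosomal and Z-linked sequence of its
species but no W-linked sequence. If male short reads are mapped — uniquely
— to a ZW female assembly, a W-specific contig should therefore receive
essentially no reads, while autosomal/Z contigs receive reads in proportion
to their mappable length. The method turns that contrast into a per-contig
two-feature summary and a classifier. Three assumptions matter:

1. **Uniqueness of mapping.** Any sequence present at two or more places in
   the assembly (or on both strands) attracts ambiguous reads, which are
   discarded; such regions are masked out beforehand so they contribute
   neither targets nor features.
2. **Uniform sampling.** Reads are modeled as uniform over mappable
   positions; with depth d and read length r the expected number of reads
   on a contig with P possible placements is d·P/r up to edge effects, and
   the zero-hit probability is (1 − P/P_total)^N. GC and fragmentation
   biases are not modeled.
3. **Feature independence given class and length.** Coverage and read depth
   are treated as conditionally independent in the naive Bayes rule; they
   are in fact correlated, but NB is robust to this and the two features
   carry complementary information at low depth (read depth counts reads,
   coverage counts distinct bases).

## Features

For a contig with unmasked length U and P = Σ max(0, seg − r + 1) possible
placements over its unmasked segments:

- coverage x₁ = (# unmasked bases under ≥ 1 uniquely mapped read) / U;
- read depth x₂ = (# uniquely mapped reads) / P.

A contig with U = 0 or P = 0 is *ineligible*: it cannot be distinguished
from a W contig by this method and is excluded from classification (and
reported). No cross-library normalization is applied; the method uses a
single read library.

## Reference preparation

External masks (BED intervals, lowercase soft masking) are unioned with the
intrinsic N-mask. Exact duplicate detection then marks every base inside a
maximal exact repeat longer than `min_dup_len` (default 50 bp, strict)
occurring at ≥ 2 locations, forward or reverse complement, within or across
contigs. Implementation: every (min_dup_len + 1)-mer window of unmasked
sequence is hashed with a 64-bit polynomial rolling hash (forward and
reverse-complement); a window whose hash occurs twice, or whose
reverse-complement hash occurs anywhere (palindromes require a second
location), is duplicate-marked; runs of marked bases become mask intervals.
Collisions are theoretically possible (~n²/2⁶⁴) but irrelevant at the
scales involved, and the finder is tested against an exact
substring-dictionary oracle. Only exact repeats are detected — diverged
repeat copies are explicitly out of scope (an external masker's BED can
supply them). Finally, unmasked islands shorter than `min_seg_len` (default
50 bp) are masked, since they cannot anchor informative unique mappings.

## Unique-placement mapping

The built-in mapper is a minimal exact tool for fixed-length short reads,
designed to be provably complete rather than fast on real data (external
aligners can be used through SAM ingestion instead). The read is
partitioned into `max_mismatches + 1` contiguous segments; by pigeonhole,
any placement with ≤ max_mismatches substitutions matches at least one
segment exactly, so exact seed lookup (sorted k-mer index over unmasked
genome positions, k = r // (max_mismatches+1)) followed by vectorized
Hamming verification enumerates *every* qualifying placement on both
strands. A read is placed iff exactly one placement attains its minimum
mismatch count; ties and no-hits are discarded and tallied. Placements must
lie entirely within unmasked sequence, mirroring a reference whose masked
bases were N-ed out before alignment. Defaults: r = 36, max_mismatches = 2
(tolerating strain divergence between read donor and assembly donor).
Reads are deduplicated by exact sequence and filtered for low complexity
(most frequent base > 80% of length) before mapping.

## Length conditioning

Short contigs have few possible placements, so at modest depth they can
receive zero reads by chance: at 0.45× a 500-bp fragment is read-free with
probability ≈ e^(−0.45·465/36) ≈ 0.3%, and a few-read fragment with low
coverage is common. Ignoring this inflates false W calls dramatically (the
package's tests measure a > 3× inflation when a long-fragment-trained model
scores 500-bp fragments). The classifier therefore conditions every feature
distribution on the contig's length bin: lengths are rounded to the nearest
500 bp (ties up, floored at 500; the operative length is the unmasked
length, which is what the features are computed over), and training
material per bin is manufactured by fragmenting labeled contigs into
non-overlapping L-length windows from position 0, dropping partial tails.
Existing placements are re-homed to fragments by read start; reads spanning
a fragment boundary are dropped and counted (re-mapping is available but
unnecessary at these scales).

## Classifier

Per (class, length-bin, feature), the discretized distribution is the
relative frequency of training contigs per equal-width feature bin
(half-open bins [k·w, (k+1)·w); default w = 0.005, the optimum of a
cross-validation sweep over widths 0.0005–0.05), plus ε = 10⁻⁶ on every
bin, added after normalization so unseen bins have probability exactly ε —
this keeps a single unusual feature from zeroing a likelihood. Likelihoods
are computed in log space. Two posterior modes exist: `standard_bayes`
(default), the fully normalized two-class rule with prior π (default: W
share of the training set); and `as_printed`, a variant whose
denominator omits the priors. That variant is bounded above by π —
with π = 0.5 it can never clear τ = 0.95 — so the standard rule is the
recommended and default mode; the variant is retained for comparison.
A contig whose length bin has no trained table is a hard error by default;
harnesses that resample tiny training sets may opt into an explicitly
recorded pooled (length-agnostic) fallback table — there is never a silent
nearest-bin substitution.

## Separation statistics

Bootstrap machinery (B = 1000 by default, percentile intervals, contigs
resampled jointly so the x₁–x₂ dependence is preserved):

- CIs for mean coverage and read depth per class;
- the quantile-separation test: per replicate, diff = min(non-W resample) −
  max(W resample); p = fraction of replicates with diff ≤ 0. Positive diffs
  mean the distributions are disjoint; p = 0 is reported as "< 1/B". The
  extreme quantiles are taken as the resample min/max (empirical quantile
  type is irrelevant at the extremes), and the opposite-order difference is
  retained with flipped sign for comparability;
- the W coverage ceiling: mean over replicates of the resample maximum of W
  coverage, used as the threshold for the false-positive-rate-by-length
  curve (fraction of non-W fragments per length bin with coverage below
  the ceiling).

## Performance experiments

ROC curves are tie-grouped with trapezoidal AUC (equal to the pairwise
concordance statistic with ties counted ½; verified against exhaustive pair
counting). Cross-validation draws n_W W and ratio·n_W non-W training
contigs per iteration, trains per-bin tables on the bins the draw covers,
scores the remainder (pooled fallback for uncovered bins, recorded per
call), and aggregates AUC over iterations; single-class validation folds
are rerolled and logged. The imbalance experiment fixes the validation set
per iteration from a level-independent RNG stream so every ratio level is
scored on identical contigs. The length-transfer experiment compares
single-length-trained models (scoring all validation items with that one
table) against the length-conditioned classifier on a shared validation
set. All grids are reproducible from (config, master seed): every random
draw in the package comes from a stream derived from the master seed and a
stable operation label.

## Synthetic data generator

The generator emulates the data regime the method targets, scaled to a
desktop: a female assembly of W, Z and autosomal contigs with i.i.d.
uniform base composition, and male reads drawn only from non-W sequence.
Defaults (the package's study conditions): 100 W + 100 Z + 900 autosomal
contigs, lengths uniform on 1–5 kb — the short, hard end of an assembly,
where length conditioning matters — 36-bp reads at 0.45× of the unmasked
assembly, substitution errors at 0.002/base, and 2% planted exact repeats
(unit lengths 150/400 bp, 2–4 copies) that the duplicate filter must
remove. Z contigs are sampled at the same per-copy rate as autosomes (a ZZ
male carries two Z), so Z is deliberately not depth-distinguishable from
autosomes. Read count = depth × unmasked assembly length / r; starts are
uniform over read-length windows of eligible source contigs.

Two realistic failure modes can be planted (both default to 0, modeling a
vetted labeled set; tests exercise them explicitly):

- **Gametolog pairs.** A recent W/Z duplication can leave the W copy similar
  enough to male sequence to attract reads. Modeled as: the W contig
  carries a stretch identical to the *male's* copy, while the assembled Z
  partner carries a diverged (default 3%) copy — as when the assembly
  haplotype differs from the read donor's, or the male copy is collapsed or
  unassembled. Male reads from the region then best-map uniquely to the W
  contig, giving true W contigs a positive coverage tail. (Note that an
  *identical* stretch present twice in the assembly would be caught by the
  duplicate filter and attract only ambiguous reads, which is why the
  divergence is essential to the failure mode.)
- **Male-specific deletions.** Autosomal contigs flagged absent from the
  read source; they present the exact (0, 0) W signature and are the
  method's unavoidable false positives, detectable only by follow-up
  (e.g. PCR in both sexes).

What passing tests on this generator do **not** show: robustness to GC and
fragmentation bias, indels, diverged repeat families, quality-score
effects, or paired-end information — none of which the generator models.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; BED I/O follows BED.
- Duplicate threshold is strict (> 50 bp): a 50-bp repeat survives.
- Length-bin rounding: ties (≡ 250 mod 500) round up; minimum bin 500.
- Feature-bin boundaries: half-open with a 10⁻⁹ relative tolerance so
  exact boundary values land in the upper bin despite floating point.
- Log-space likelihoods agree with direct products to ~10⁻¹⁵ relative.
- Degenerate inputs are hard errors, not silent defaults: empty bootstrap
  input, single-class ROC labels, unknown contigs in masks or SAM,
  out-of-bounds intervals, missing length bins in strict mode.
- Problem sizes in the test suite and acceptance script (1.1k contigs,
  ~42k reads at 0.45×, 10–25 experiment iterations, B = 500–1000) were
  chosen so the full pipeline and every experiment re-run from scratch in
  well under a minute each while keeping Monte-Carlo error far from the
  asserted margins.

## Known limitations

- Only unique W sequence is detectable: pseudoautosomal and repeat-rich W
  regions are invisible by construction, and masking removes much of a real
  W chromosome from consideration.
- Exactly-duplicate detection only; diverged duplications need an external
  masker.
- The mapper is substitution-only and fixed-read-length; use an external
  aligner plus SAM ingestion for anything else.
- Male-deletion contigs are irreducible false positives of the subtraction
  idea itself; the truth tables and reports make them measurable, not
  avoidable.
- At very low depth, short non-W contigs overlap the W signature; the
  false-positive-rate curve quantifies exactly how much trust a call at a
  given contig length deserves.
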