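# Methods

This note documents the models, conventions and numerical choices behind
`methexpr`, in the spirit of a model-documentation page: what each
procedure assumes, which knobs matter, and what the synthetic data do and
do not establish about real data.

## Data model and coordinate conventions

All genomic intervals are 0-based half-open internally; BED input is taken
as-is, GTF is converted from 1-based closed. Cell-line names are matched
across files after whitespace trimming and uppercasing; any mismatch
between two inputs is a hard error listing both name sets. The expression
loader rejects missing values outright — there is no defensible imputation
rule for this design, and silent imputation would contaminate the
median-based calls.

A gene is anchored at its strand-aware TSS (leftmost base of exon 1 on
'+', the half-open right boundary on '−'). The profiled window is
TSS ± 10 kb, tiled by 200 bins of 100 bp in transcription orientation;
bin 0 starts at the TSS and negative bins are upstream. Under chromosome
mirroring this anchor maps bin *k* of a forward gene onto bin *k* of the
mirrored reverse gene — the grid follows transcription, so the index is
strand-invariant.

Named regions per gene: `TSS1-1000` and `TSS1001-2000` (the 2 kb promoter
in two 1 kb windows abutting the TSS upstream), `CGI` (islands overlapping
the profiled window; a promoter-only assignment mode exists behind a
flag), `CGIShore` (exactly 2 kb flanks of each assigned island minus any
island overlap — the conventional "~2 kb" resolved to 2000 bp), `Exon1`,
`Intron1`, `Exon2` where the gene model supports them. Windows running off
a chromosome end are truncated with a warning, never an error.

## Methylation quantification

MBDCap-seq read density proxies methylation. A read increments **every**
bin it overlaps (capture fragments routinely span bin boundaries); a
midpoint rule is available behind a flag for comparison. Counts can be
library-size scaled (reads per million) for cross-line comparison;
scaling is a per-line constant, so all rank-based and correlation-based
downstream results are unaffected.

The level of a named region is the **overlap-weighted mean** of bin
densities over the bins the region touches, not the sum, so regions of
different lengths are comparable in one figure or attribute set.

Genes with ≤ 3 total mapped reads over the whole window and all cell
lines are dropped before screening (strict ">3"); the per-gene-total
reading was chosen over per-cell-line filtering (flag available), since a
per-line rule would silently change the panel per gene.

Density summaries truncate levels at 100 (producing the characteristic
mass at the truncation point) and exclude exactly-zero (unmethylated)
regions before histogramming.

## Protocol 1 — normalized entropy

For unit *j*, tᵢ is the summed signal of phenotype *i* and c = Σtᵢ. The
shares pᵢ = tᵢ/c give H = −Σ pᵢ log₂ pᵢ and NH = H/log₂ 3. The pseudo-
signal realizing "no zero shares" is additive and proportional to the unit
total: pᵢ = (tᵢ + ε·c′)/(c + 3ε·c′), ε = 10⁻⁶, c′ = max(c, 1); the log
base cancels in NH. Exactly equal adjusted sums short-circuit to NH = 1
so the maximum is attained exactly, not merely to rounding.

Choices worth knowing:

* The default methylation unit is the gene's **window total** (TSS ± 10 kb);
  a per-region and per-bin mode are exposed, since the aggregation level is
  a genuine design freedom.
* Group sizes (13/7/10) are **not** corrected for: with phenotype-uniform
  per-line signal the shares are (13, 7, 10)/30 and NH ≈ 0.972, not 1.
  A size-normalized variant (shares from per-line means) is provided.
* Expression entropy uses the **uncentered** matrix shifted by its global
  minimum + 10⁻³ — centered values are negative and cannot be shares.
  This is an interpretation choice: shares then measure expression above
  the panel-wide floor.
* Threshold semantics: NH < threshold flags a unit; defaults 0.2
  (methylation) and 0.5 (expression). Note the statistic is conservative
  at these thresholds: with shares (13f, 7, 10)/(13f+17), NH < 0.2
  requires a fold f ≳ 32; an 8-fold effect sits near NH ≈ 0.46 (per-region
  unit) and is cleanly separated from the null (≈ 0.97) but not below 0.2.
  The screen's strength at moderate folds is ranking, not the absolute
  threshold.

## Protocol 2 — down-calls and correlation

Centering is value − column mean per cell line (the sign-flipped literal
alternative is behind a flag; it would invert up/down semantics).
Medians per subtype use the midpoint convention for even groups. A gene
is *down* in subtype *i* iff min over the other subtypes of
(m⁽ᵏ⁾ − m⁽ⁱ⁾) **exceeds** the criterion (1.5 log units); the margin is
that minimum, so at most one subtype can ever be called per direction, and
calls are invariant to adding a constant to a gene's values. The strict
(rather than ≥) comparison at the boundary is deliberate and tested.

Pearson correlations pair a gene's per-bin (or per-region) methylation
with its expression across the panel. Zero-variance vectors yield a masked
(NaN) entry — never a fabricated 0 — so "no data" and "no signal" stay
distinguishable in heatmaps. Promoter heatmaps order columns TSS-proximal
first. Group comparisons of per-gene r values use Welch's t-test per bin,
two-sided, with Benjamini–Hochberg q-values appended for reference only
(selection uses raw p, matching the protocol's design); bins with fewer
than two defined values in either group are masked. An aggregate
(per-gene mean-r) mode exists because the comparison level is ambiguous
in principle.

## Protocol 3 — decision tree

Instances are (down-called gene, cell line) pairs — 30 per gene — with
class *low* iff the line belongs to the called subtype (13 low / 17 high
per Lu-called gene). Attributes are region levels z-scored **globally per
attribute** over all instances ("adjusting the scale" resolved to the one
normalization that keeps attributes comparable across genes). An optional
mode splits promoter/exon attributes into CGI-overlapping and
non-overlapping variants.

Induction is greedy binary splitting by information gain over candidate
thresholds at midpoints of consecutive distinct values, stopped at depth 3
(splits, excluding leaves) or purity. Ties are broken by a canonical
attribute order (TSS1-1000, TSS1001-2000, CGI, CGIShore, Exon1, Intron1,
Exon2), then the smaller threshold, making induction deterministic.
Instances missing the split attribute follow the child with the larger
training mass. Reduced-error pruning holds out a seeded, stratified third
of the instances and collapses any subtree whose leaf replacement does not
increase held-out error; pruning provably never increases error on the
pruning set (property-tested). Accuracy is reported by seeded stratified
10-fold cross-validation. The right branch of every split is the
higher-methylation side, and leaves render as Down (low) / Up (high).

Equivalence with any particular third-party tree implementation is not
claimed — only procedure-level behaviour (exact agreement with exhaustive
depth-1 search, recovery of planted single-attribute and conjunctive
rules, collapse to majority on null data).

## Protocol 4 — TFBS blocking

Per promoter bin (20 bins of the 2 kb promoter) of each down-called gene,
a one-sided two-sample t-test (pooled variance by default, Welch behind a
flag) asks whether methylation is higher in the called subtype; bins with
P < 0.005 qualify. Bins with zero variance in both groups are masked.
No multiple-testing correction is applied across bins (the protocol's
criterion is a raw P); BH q-values are emitted alongside.

Consensus sequences are reference-anchored majority pileups: per position
the majority base over covering reads, ties and uncovered positions
falling back to the reference. De-novo assembly is unnecessary at bin
scale for reads that are already mapped. In the synthetic pipeline the
per-line promoter sequences stand in for assembled consensi directly.

PWM counts are normalized with a 0.01 per-base pseudo-count. Scanning
scores are normalized log-odds, (S − Smin)/(Smax − Smin), against a
background that defaults to the empirical base composition of the scanned
consensi. Per-PWM thresholds are calibrated to an explicit background
false-positive rate (default 10⁻⁴ per position): the exact score
distribution is enumerated for widths ≤ 10 (score classes grouped to 10⁻⁹
to keep summation-order rounding from splitting a class), seeded
Monte-Carlo with 10⁵ draws otherwise; the threshold is the most permissive
score whose exceedance probability still meets the target, falling back to
the maximal score (with a warning) for degenerate matrices. Both strands
are scanned; overlapping same-matrix hits keep the best offset.

TFs whose own expression differs between the called subtype and the rest
(two-sided t-test, p < 0.05) are discarded — their differential expression,
not methylation, could explain the target's downregulation. Note the flip
side: a truly flat TF is discarded with probability ≈ α (5%); the filter
trades recall for interpretability by design. The support rate of a
surviving hit is 100 × (same-phenotype lines whose consensus contains it)
/ (same-phenotype lines with a computable consensus) — the reduced
denominator matters when some lines lack coverage — and candidates below
50% are dropped.

## CpG-island detection

Islands are intervals of length > 500 bp with G+C ≥ 0.55 and
observed/expected CpG ≥ 0.65 (obs/exp = #CpG·L/(#C·#G)); N bases count
toward length but not content, diluting both criteria. The finder returns
**exactly** the maximal qualifying intervals — every qualifying interval
not contained in a longer qualifying one — via a prefix-sum search that
evaluates, for each start, every admissible end. This is exact (verified
against brute-force enumeration) but quadratic; it is intended for
promoter-scale sequences, not chromosomes. Maximal intervals may overlap;
callers wanting disjoint islands should merge them.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the protocols assume:

* the 30-line panel with the 13/7/10 subtype split (the packaged panel
  table supplies the names);
* bin counts ~ negative binomial with var = μ + φμ² (defaults μ = 2
  reads/bin, φ = 0.3 — overdispersed coverage typical of capture data),
  with a multiplicative fold (default 8) planted on the bins of one
  promoter region (default TSS1-1000) for the planted subtype's lines;
* log₂ expression = per-gene baseline (≈ N(8, 1)) + slope × standardized
  planted-region methylation (slope ≤ 0, default −1) + N(0, 0.2) noise,
  so planted genes are both hypermethylated and downregulated in their
  subtype;
* promoter sequences (2 kb, transcription orientation) identical across
  lines, with each planted TF motif's consensus written under a planted
  hypermethylated bin in **all** lines (the motif is genomic; methylation,
  not sequence, differs), plus one phenotype-flat expression row per TF;
* a separate instance generator plants single-attribute, conjunctive
  (two-region AND) and null class rules for the tree learner.

All genes sit on one toy chromosome, forward strand, with non-overlapping
windows; everything is reproducible byte-for-byte from the config seed.

Deliberately not emulated: sequencing error and quality, CpG-density
capture bias, copy-number confounding, strand mixtures, inter-line
sequence variation, overlapping genes, and realistic LD between regions.
Passing recovery tests therefore demonstrates that the implementations
detect the effects they target at realistic effect sizes and noise — not
that the protocols are robust to every artefact of real capture data.

## Problem sizes and numerics

Recovery runs use 200–500 genes × 30 lines × 200 bins and tree runs use
600 instances — sizes at which every planted effect is comfortably
powered while the full suite and the reproduction script each finish in
minutes on one core. Determinism is enforced end to end: seeded
generators, seeded pruning/CV splits, sorted outputs, no timestamps in
any artefact; two runs from one seed are byte-identical (tested).
Floating-point edges handled explicitly: exact NH = 1 at uniform shares,
clipped normalized PWM scores, 10⁻⁹ score-class grouping in threshold
calibration, masked (never zeroed) undefined correlations.

## Known limitations

* The entropy screen's absolute thresholds are only meaningful for very
  large fold effects (see Protocol 1); moderate effects separate from the
  null by rank but not below 0.2.
* The per-gene low-coverage filter and the window-total entropy unit are
  one of several defensible aggregation choices; alternates are exposed
  but not exhaustively cross-validated.
* The CGI finder is exact but quadratic; whole-genome annotation should
  come from a supplied interval file instead.
* TF–gene mapping is one-to-one by matrix id; families sharing a probe
  must be encoded explicitly in the mapping file.
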