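# Methods

## The enrichment model

`ciscross` treats upstream-regulator prediction as a gene-level overlap
test. The unit of evidence is the *gene*, not the peak or the base pair:
for one peak set, a gene either has ≥ 1 binding peak in its promoter or
it does not, however many peaks actually fall there. This makes the test
robust to peak fragmentation and peak length, at the cost of ignoring
binding multiplicity.

Given a promoter length *L*, the promoter of a gene is the half-open
interval of up to *L* bases strictly upstream of its 5′ gene boundary on
its strand — `[max(0, start−L), start)` for a `+` gene,
`[end, min(chrom_len, end+L))` for a `−` gene. The TSS base itself is
excluded. Working at gene-feature level (one promoter per gene, TSS =
gene-body 5′ boundary) avoids transcript-model ambiguity; no masking of
overlapping genes or promoters is applied. Genes whose promoter clips to
zero width (a gene starting at base 0 on `+`) leave the analysis
universe with a warning.

The universe is every annotated gene with a non-empty promoter. The
foreground is the input list ∩ universe (ids matched case-insensitively
after trimming; duplicates collapse; unmatched ids are dropped, warned
and counted); the background is the rest of the universe. For each peak
set the 2×2 table (a, b, c, d) of foreground/background ×
overlap/no-overlap is scored with the one-sided ("greater") Fisher's
exact test — the question is enrichment, so the lower tail carries no
evidence; a two-sided variant is available as an option. Overlap means
≥ 1 shared base under half-open semantics: a peak starting exactly at
the promoter's end base does not count.

Correction for multiple testing is applied across exactly the peak sets
present in the supplied (QC-filtered) collection — the size of the
collection therefore changes adjusted values, which is intended: a
larger collection is genuinely more tests. Benjamini–Hochberg (step-up
with monotonicity enforcement, clipped at 1) is the default; Bonferroni
is the alternative. Output rows are sorted by adjusted p, ties broken by
raw p and then peak-set name, so runs are bit-reproducible.

Degenerate inputs are hard errors rather than silent answers: an empty
foreground after id matching, a foreground equal to the universe, an
empty collection, and (in light mode) a gene id outside the universe.

## QC rules

FRIP is the fraction of aligned reads (any interval representation; a
≥ 1 bp overlap counts) falling in peaks. Collection QC removes peak sets
with FRIP < 0.01 — a near-total failure of target capture — and sets
with fewer than 200 peaks, too sparse to support an overlap test. Both
bounds are keep-side-inclusive: FRIP = 0.01 and 200 peaks survive. Sets
without a FRIP value skip that criterion with a warning. The filter is
idempotent and is applied before any replica merging by default (both
orders are possible by composing the functions directly).

For replicated experiments processed through an external IDR pipeline,
the final track is the IDR-merged set iff it contains **more than** 2000
peaks or its size is **at least** twice the largest individual replica;
otherwise the replica with maximal FRIP is chosen. The inequalities are
deliberately asymmetric (strict vs inclusive), mirroring the rule's
wording. FRIP ties break by larger peak count, then name, so selection
is deterministic. A lone replica with an empty IDR set short-circuits to
that replica ("single-replica").

## Track statistics

The Jaccard statistic of two tracks is shared covered bases divided by
bases covered by either, computed on merged intervals; an empty union is
reported as 0 with a flag rather than NaN. The co-localization test
builds an interval-count 2×2 table: n11 = merged-A intervals overlapping
B, n12 = |A| − n11, n21 = merged-B intervals overlapping A minus the n11
shared pairings (floored at 0), and n22 = max(0, ⌊G/μ⌋ − n11 − n12 −
n21), where G is the genome length and μ the mean length of the pooled
merged intervals — i.e. the genome is treated as ⌊G/μ⌋ interval-sized
slots. The construction is returned with the p-value so it can be
audited; it is one reasonable interval-Fisher construction among
several, and agreement with any particular external toolkit's version is
not claimed. The classification of peak-count changes between collection
versions uses inclusive twofold boundaries (exactly 2× counts as
Increase/Decrease); in the vacuous case old = new = 0 both twofold
conditions hold and the Increase branch, tested first, wins.

## Synthetic data

The generator emulates a desk-scale Arabidopsis-like study: 5
chromosomes × 2 Mb, 2,000 non-overlapping genes of 500–2500 bp (one gene
per ~5 kb, near real gene density), promoters of L = 1000 bp, 100 peak
sets of 300 peaks with lengths 100–400 bp (bracketing the ~250 bp
typical of variable-width peak calling), a 100-gene foreground, and
planted regulators at p_fg = 0.5 / p_bg = 0.05 — the conditions under
which recovery and null calibration are measured. Genes are placed one
per equal-width slot with a promoter-length margin on both sides, so
genes never overlap and every promoter has full width; placement that
cannot satisfy this is an error, not a retry loop. Planted peaks are
drawn per gene (Bernoulli) and placed fully inside the promoter, so a
planted hit is guaranteed regardless of interval arithmetic; planted
sets contain only their planted peaks. Each artifact (gene layout,
foreground choice, each peak set, FRIPs, reads) draws from its own RNG
stream keyed off (seed, artifact name), so outputs are byte-stable and
adding an artifact never perturbs the others.

What the generator does **not** emulate: sequence content (no motifs, no
FASTA), read-mapping noise, chromatin or methylation structure,
correlated binding between TFs of one family, and the long-tailed
peak-count distributions of real collections. Passing recovery and null
tests therefore demonstrates the statistical machinery is correct and
calibrated under independence — not that real DAP-seq collections meet
those assumptions.

Simulated reads place ⌈f·n⌉ reads overlapping randomly chosen peaks and
the rest uniformly, so the realized FRIP is bounded below by the
requested fraction f and exceeds it only by the uniform reads that land
in peaks by chance.

## Numerical and design choices

- All internal coordinates are 0-based half-open (BED); GFF3 is
  converted on read (1-based inclusive → half-open) and on write.
- The one-sided Fisher p is evaluated as the hypergeometric survival
  function; the suite verifies it against exact-integer tail enumeration
  (every table with N ≤ 40, tolerance 1e-12) and a log-gamma summation
  (random tables with margins to 10⁴, tolerance 1e-9).
- The overlap engine merges each peak track and answers promoter queries
  with one binary search per query; it is verified against naive
  all-pairs scans and per-base masks.
- Duplicate gene ids in a GFF3 keep the first record (warned, counted);
  a strict mode errors instead.
- p-values are printed with '.' decimals, scientific notation below
  1e-4, so output files are byte-stable across runs and platforms.
- Problem sizes in the test suite (100 recovery seeds, 200 null seeds,
  desk-scale fixtures elsewhere) keep the full suite under a minute of
  compute while leaving the binomial bounds on planted counts sharp.

## Known limitations

- One promoter per gene: no transcript-isoform TSSs, no
  annotation-supplied 5′ UTR logic.
- The co-localization table construction is a documented convention, not
  a canonical statistic; treat its p-values as comparative, not
  calibrated.
- No peak calling, read mapping, IDR model fitting, motif analysis or
  GO-style annotation enrichment — the package starts from called peak
  tracks and an annotation.
- BH calibration of the null is guaranteed only under independence of
  peak sets; real collections contain closely related TFs with highly
  correlated tracks.
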