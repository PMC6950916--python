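# Methods

This note records the model behind `cncc`, the conventions the code commits
to, and the reasoning behind the less obvious implementation choices.

## Input model

The unit of data is a **strand profile**: per-base counts of read-1 5′-end
positions on one strand, 0-based coordinates, stored sparsely as
`{chrom: {position: count}}`. A break-mapping experiment yields one positive-
and one negative-strand profile. A cut at position `p` (the last base of the
upstream fragment's negative-strand end) produces:

- a negative-strand end at `p`, and
- a positive-strand end at `p + 1` (blunt), `p + 1 + L` (3′ overhang of
  L nt, trimmed during blunting), or `p + 1 − L` (5′ overhang, filled in).

Profiles are built by `cncc coverage` from single-nucleotide BED6 records or
from a BAM (read 1 of proper pairs; unmapped, secondary, supplementary,
QC-fail and duplicate records excluded; optional MAPQ floor), optionally
minus masked intervals (e.g. centromeres).

## CNCC

With positive-strand coverage `x` and negative-strand coverage `y`,

    CNCC(t) = Σ_i y(i) x(i − t) / sqrt(Σ x² · Σ y²)

The numerator is accumulated per chromosome (no cross-chromosome products);
the denominator uses genome-wide sums of squares. Properties relied on by the
test suite:

- |CNCC(t)| ≤ 1 (Cauchy–Schwarz), with equality iff `y` is a translated
  multiple of `x`;
- invariance under `x, y → c·x, c·y` (depth independence);
- covariance under joint translation.

Implementation: for each shift, positions of one strand are looked up in the
other strand's sorted position array with `numpy.searchsorted`, so cost is
O(shifts × nonzero positions) and independent of genome length.

The argmax shift ties break toward the smallest |t| (then the more negative
t), so degenerate flat maxima decode to the most conservative structure.

**Shift decoding** inverts the geometry table: t = −1 → blunt; t < −1 →
3′ overhang of −1 − t nt; t > −1 → 5′ overhang of t + 1 nt.

**Resection signature.** Resection produces a mixture of 3′ overhang lengths,
i.e. CNCC mass spread over shifts < −1. `resection_range` takes the maximal
contiguous run of shifts, containing the window argmax, whose values are
≥ 90% of the window maximum (window default [−201, −2]), and decodes the run
ends to a min/max overhang length. The 90% band, rather than a fixed
threshold, keeps the operation scale-free.

**Peak calling** (`dominant_shifts`) uses `scipy.signal.find_peaks` with a
prominence floor; a flat curve has no peaks by construction.

## Stringent shuffled control

A null must answer: "would this spike survive if the pairing between
negative- and positive-strand counts were broken, while everything else about
the coverage were kept?" A free genome-wide shuffle is far too permissive —
it also destroys the local coverage texture and flattens everything. The
control here is deliberately stringent; each strand is shuffled
independently in two steps, per chromosome:

1. **Count permutation** among the originally non-zero positions. This keeps
   the exact multiset of counts and the exact set of occupied positions, but
   destroys the count *correlation* between the two ends of one break —
   strong sites no longer face strong sites.
2. **Non-zero wiggle**: every position then moves by a uniform draw from
   {−W, …, −1, +1, …, +W} (zero excluded, so nothing stays put), reflected
   at chromosome edges; collided positions have their counts summed.

Totals are conserved exactly. For enzyme-scale spikes W = 2 suffices; for
signals paired over kilobases (e.g. topoisomerase-II cleavage distributed
across wide regions) W of ~2000 is appropriate. On simulated digests the
spike suppression is monotone in W.

Step 1 does most of the work only when site strengths are heterogeneous,
which is why the simulator's default site-strength model is lognormal
(σ = 1.25, mean-corrected): with equal per-site counts a permutation changes
nothing and only the wiggle suppresses (~4×); with realistic heterogeneity
the combined suppression is >10× at W = 2, matching what the control is
designed to test.

**Relative CNCC** subtracts a scalar — the median over all control values
(all shifts, all replicates) — from the raw curve. A scalar, not a per-shift
median, is the default because per-shift medians from few replicates are
noisy and would imprint control noise onto the curve shape; a `per_shift`
flag exists for users with many replicates. The baseline used is recorded in
the curve's metadata.

## Sensitivity scan

To attribute a spike to a candidate site set, the scan masks random site
subsets at fractions 0, 0.1, …, 1.0 (⌊fraction × n⌋ sites, drawn without
replacement, 100 iterations per fraction by default; sites first filtered to
those with strictly more than 5 supporting reads) and records CNCC at the
target shift. For a species contributing a fraction of reads at one shift,
the median at that shift decreases linearly in the masking fraction; the
off-target curve barely moves; a shuffled companion stays flat.

Masking removes the full count at each site's two end positions. The scan
does not recompute the whole curve per iteration: from the unmasked
numerator `N` it subtracts the removed-negative and removed-positive
contributions and adds back the doubly removed overlap
(`N − A − B + C`), and adjusts the two sums of squares by the removed
squares — O(sites) per iteration, exact to the full recomputation (asserted
to 1e−12 in the tests). Per-iteration RNG streams are derived as
`default_rng([seed, fraction_index, iteration])`, so any iteration is
reproducible in isolation.

## Region partition and break density

Gene-anchored classes, all half-open `[start, end)` in 0-based coordinates,
for a gene with transcription start `TSS` and end `TTS` (strand-aware,
mirrored for − genes):

- promoter: `[TSS − 1000, TSS − 250)` (upstream of the TSS window)
- TSS: `[TSS − 250, TSS + 250)`
- TTS: `[TTS − 250, TTS + 250)`
- gene body: `[TSS + 250, TTS − 250)`
- intergenic: the complement

Overlaps are resolved by precedence TSS > promoter > TTS > gene body, then
intergenic takes the rest, so the five labels **partition** the genome
exactly (property-tested against a per-base sweep oracle).

Density is reported as BPMM — breaks per megabase per million mapped
breaks: `(breaks_in_class / (class_bp / 10⁶)) / (total_breaks / 10⁶)` — so
100 breaks in a 1-Mb class out of 10⁶ mapped breaks give BPMM = 100, and a
uniform dataset gives every class the same value. Group comparison uses
Kruskal–Wallis followed by Dunn's test (tie-corrected; implemented in-package
since SciPy has no Dunn post hoc) with Benjamini–Hochberg adjustment via
`scipy.stats.false_discovery_control`.

## Spike pairs

A single cut with a 3′ overhang of L nt leaves a negative-strand spike and a
positive-strand spike separated by a **gap** of L reference bases
(`pos = neg + L + 1`), the per-locus counterpart of the CNCC spike at
−1 − L. `find_pairs` reports all such pairs with both counts ≥ 2 (default),
and `export_pair_fasta` writes `[neg − flank, pos + 1 + flank)` sequences for
external motif discovery.

## Simulator

`cncc.simulate` generates post-alignment 5′-end positions directly — the
method's actual input domain — not reads or alignments. A digest draws site
positions uniformly (length-weighted across chromosomes, deduplicated, away
from edges; out-of-bounds explicit sites are skipped with a warning),
assigns each site a lognormal strength (σ = 1.25 default; σ = 0 means
exactly `reads_per_end` reads per end), emits Poisson reads per end with the
strength *shared* by the two ends of a site (the correlation the shuffled
control exists to break), applies a per-site capture probability, and adds
uniform single-read background of random strand. Resection mode draws each
site's overhang length from a supplied set; mixtures combine a major and a
minor species with the minor's depth rescaled to a target read fraction.
Every run returns a ground-truth table (site, geometry, per-end reads,
captured/skipped flags, species).

Scales used in the validation suite are package choices sized for a laptop
CPU: 10-Mb genome / 1000 sites for shift recovery (seconds), 20-Mb for the
sensitivity scan (~20 s for 11 fractions × 100 iterations), and 500 Mb /
150,000 sites for resection-range recovery — the multinomial noise on 41
overhang-length bins must be well under the 10% band threshold for the
90%-of-max run to be stable, which ~3,600 sites per bin provides.

## Numerical conventions

- Coordinates 0-based, intervals half-open, BED conventions on disk.
- Counts are integers; CNCC in float64. Comparisons against the brute-force
  oracle hold to 1e−12 absolute.
- All stochastic code takes explicit seeds and uses
  `numpy.random.default_rng` with spawn-style list seeding
  (`[seed, index, …]`) so parallel streams are independent and individually
  reproducible.

## Limitations

- Background is uniform; chromatin-biased break density is not modeled.
- The simulator does not model sequencing error, mappability or aligner
  artifacts; profiles are taken as correctly mapped.
- Characteristic shifts assume clean blunting chemistry (complete trimming /
  fill-in). Partial processing would smear spikes between t and −1.
- The shuffled control conserves counts per chromosome; chromosomes with
  very few occupied positions shuffle poorly and contribute unstable nulls.
- Dunn's test assumes independent observations; window densities from
  adjacent windows are weakly dependent, so its p-values are approximate.
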