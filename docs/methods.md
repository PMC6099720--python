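# Methods

## Model and procedure

`atacmd` infers differential transcription-factor activity from chromatin
accessibility alone. The underlying assumption is that a TF's activity is
reflected in how tightly its recognition motif co-localizes with the centers
of accessible regions: active TFs hold open (or occupy the center of)
accessibility peaks at their binding sites, so the distribution of
motif-center-to-peak-midpoint distances sharpens; losing activity flattens
it. The statistic deliberately aggregates over the whole genome — it ranks
motif *models*, not loci — which makes it robust at shallow sequencing depth
but blind to locus-level changes.

The pipeline is: (1) reduce each called peak to its integer midpoint
(`floor((start+end)/2)`; peaks are unstranded, so strand is ignored);
(2) for each motif instance, find the unsigned distance to the nearest peak
midpoint on the same chromosome (binary search over per-chromosome sorted
midpoint arrays; distances never cross chromosomes, since a motif on one
chromosome cannot interact with a peak on another); (3) count instances
within the small radius (`n_small`, d ≤ 150 bp) and within the large local
window (`n_large`, d ≤ 1500 bp) and form the MD-score `n_small/n_large`;
(4) compare two conditions per motif with a pooled two-proportion Z-test and
classify by two significance tiers.

The counted unit is the **motif instance**, assigned once to its nearest
midpoint. This makes the MD-score a true binomial proportion over
independent-ish trials, which is what the two-proportion Z-test assumes. A
peak-centric variant (count peaks by distance to the nearest motif center)
is available via `counting_mode=peak_centric` for sensitivity analysis; it
answers a subtly different question and is not the default.

Boundary handling is inclusive (`d ≤ r`): "within a radius" is read
inclusively, and inclusivity is deterministic under integer coordinates.
A motif center exactly equidistant between two midpoints is assigned to the
upstream (smaller-coordinate) midpoint; this only affects the signed-offset
histogram, never the unsigned counts.

## Statistical test

The pooled two-proportion Z-test uses

    p̂ = (x₁+x₂)/(n₁+n₂),  z = (x₂/n₂ − x₁/n₁) / sqrt(p̂(1−p̂)(1/n₁+1/n₂))

with a two-sided standard-normal p-value and no continuity correction. When
the pooled proportion is degenerate (0 or 1) both proportions are equal and
the test reports z = 0, p = 1. Motifs with an undefined MD-score
(`n_large = 0`) in either condition are excluded from testing and logged;
no smoothing is added to the counts, keeping the proportion exact.

P-values are reported raw and classified against two tiers, strong
(p < 10⁻⁵) and weak (p < 10⁻⁴), in each direction of change. Raw
thresholds — not multiplicity-adjusted ones — are the convention this
statistic is used with; given ~10²–10³ motif models per run, users wanting
family-wise control can enable the Bonferroni switch (`--bonferroni`),
which is off by default. Two-sidedness is required because both gains and
losses of activity are biologically meaningful.

## PWM scanner

Motif site sets may be supplied as BED files (e.g. precomputed genome-wide
maps) or generated by the built-in scanner.

* **Models.** Per-position base probabilities over {A,C,G,T}. Count
  matrices (HOCOMOCO-style PCM, 4 columns, one row per position) are
  converted with an additive pseudocount (default 1.0) per cell.
  Probability matrices (MEME text format) pass through unchanged unless a
  row contains an exact zero, in which case a small fixed mass (10⁻⁴ per
  base) is mixed in so log-odds stay finite; rows without zeros are not
  perturbed.
* **Scoring.** log₂(p/background) per position (bits). The background
  defaults to uniform (0.25 each) and is configurable; no higher-order
  background model is offered.
* **Exact p-value thresholds.** The match threshold for a requested
  p-value is the smallest attainable score t with background
  P(score ≥ t) ≤ p. The score axis is discretized to integer units of
  1/1000 bit, and the exact distribution of W-mer scores under the
  background is built by convolving the four-point per-position
  distributions (the same construction FIMO uses). Scanning sums the same
  integer-discretized matrix, so `score ≥ threshold` is exact by
  construction; the only approximation is the discretization itself,
  bounded by W/1000 bits. At granularity 1000 that bound is far below any
  per-position log-odds gap that occurs in practice.
* **Conventions.** Both strands are scanned by default (reverse-complement
  matches are reported with forward-strand coordinates, so a palindromic
  site yields one hit per strand); windows containing N are skipped rather
  than scored against the background, to avoid fabricating matches in
  assembly gaps; overlapping matches of the same motif are all retained —
  the MD-score counts motif instances and imposing a merging rule would
  change the statistic.

Note an intrinsic floor: the single best W-mer has background probability
≥ 4⁻ᵂ, so a width-8 motif cannot satisfy a 10⁻⁶ per-window p-value and
yields an empty site set at that stringency. This is a property of exact
thresholds, not an implementation limit; the scanner reports such motifs
with zero sites.

## Synthetic data generator

The generator emulates the post-peak-calling data regime the statistic
consumes; it starts from *called peaks*, not reads (read simulation and
peak calling are upstream concerns, out of scope).

* A toy genome of `n_chroms` chromosomes (default 2) of `genome_length` bp
  (default 1 Mb each), optionally with random uniform sequence when the
  FASTA is needed.
* Per condition, `n_peaks` peaks (default 1000) with widths uniform in
  `peak_width_range` (default 200–600 bp, typical of ATAC-seq broad-peak
  widths), placed uniformly; an optional no-overlap mode places them by gap
  sampling and rejects configurations that cannot fit.
* Per motif and condition, `n_sites` site centers: a fraction `pi` is
  planted uniformly within ±150 bp of a randomly chosen peak midpoint of
  that condition, the rest uniform over the genome. `pi_b − pi_a` is the
  planted differential signal. The truth table records, per motif, the
  planting fractions and the expected MD-scores
  `(pi + (1−pi)·f_h) / (pi + (1−pi)·f_H)`, where `f_r` is the realized
  fraction of the genome within r of a peak midpoint.
* One seeded NumPy generator drives everything; identical configs write
  byte-identical files.

What the simulation does *not* emulate: sequence composition biases around
real regulatory regions, clustered/correlated motif occurrences (CpG
islands, repeats), replicate-level peak-calling noise, and chromosome-scale
heterogeneity. Passing the simulation-based tests therefore demonstrates
the statistic and test are implemented correctly and calibrated under the
stated sampling model — not that the biological signal in any particular
real dataset will be as clean.

## Numerical and interface choices

* Coordinates are BED-convention 0-based half-open everywhere; floor
  midpoints for even-width intervals.
* MD-score tables carry a comment header recording radii, counting mode and
  version; the differential command refuses pairs whose headers disagree,
  since a silent radius mismatch would corrupt the Z-test.
* The MA-plot x-axis is `log10(mean n_large + 1)`; the +1 guards zero
  abundance and log₁₀ is the MA-plot convention.
* Per-motif work is independent; the `md` command's thread pool never
  changes output because rows are sorted by motif id before writing.
* Tie-breaks: equidistant midpoints resolve upstream; equal p-values sort
  by |ΔMD| descending, then motif id.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 500 random instances
(≤ 100 sites, ≤ 50 peaks per chromosome) for the all-pairs MD-score oracle;
a 1000-point random grid for the Z-test closed form (agreement within
10⁻¹⁰); 2000 null replicates at `n_large ≈ 1000` for type-I error at
α = 0.05 (checked against the 99% binomial interval); 20 seeds of a planted
`pi 0.1 → 0.6` motif among 20 nulls (2000 sites, 1000 peaks) for recovery;
exhaustive 4ᵂ enumeration for scanner thresholds at widths ≤ 8; and 20 000
uniform sites over evenly spaced midpoints for the neutral `md → 0.1`
geometry check. These sizes give each check comfortable statistical margin
while keeping the whole validation run in well under a minute.

## Known limitations

* Genome-aggregate only: no locus-level differential accessibility calls.
* Motifs with near-identical recognition sequences (e.g. members of one TF
  family) move together; the method cannot distinguish which family member
  acts, as the worked analyses of such families show.
* No footprint/cleavage-bias correction; the local-window normalization
  addresses composition bias but not enzyme sequence preference.
* The Z-test treats motif instances as independent trials; clustered sites
  (tandem repeats of a motif) mildly violate this and inflate confidence
  for repetitive motifs.
* Undefined MD-scores (no sites within 1500 bp of any peak) are excluded,
  which silently drops motifs in tiny or sparse peak sets — the exclusion
  log names them.
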