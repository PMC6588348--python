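# Methods

## The quantification problem

Conventional ChIP-seq tracks are internally normalised (e.g. reads per
million), so they cannot say whether a perturbation removed protein from
chromatin genome-wide: a uniform two-fold loss disappears entirely after
per-sample normalisation. Spike-in calibration fixes this by mixing the
experimental cells (*S. cerevisiae*-like, 16 chromosomes) with a fixed
quantity of calibration cells from a diverged species (*C. glabrata*-like)
*before* chromatin preparation, at a 3:1 ratio of culture units. Both
species' chromatin travels through shearing, immunoprecipitation and
sequencing together, so the calibration genome's signal acts as an internal
ruler shared by all samples.

`calchip` implements the downstream quantification: sequential two-genome
read assignment, occupancy-ratio calibration, dense gap-filled coverage
tracks, CDEIII-anchored meta-profiles, and before/after retention
statistics — together with a generative model of the whole experiment so
every stage can be validated against known ground truth.

## Occupancy-ratio calibration

Let Wx, Wc be the unique read counts on the experimental and calibration
genomes in the whole-cell-extract (WCE) library, and IPx, IPc the same in
the immunoprecipitated (IP) library. The occupancy ratio is

    OR = (Wc · IPx) / (Wx · IPc)

and the calibrated track is the raw unique-read depth multiplied by
`OR · 1e6 / IPx`. Three algebraic/statistical contracts pin this choice
down, and all are tested:

* **Depth invariance.** Rescaling either library's counts uniformly leaves
  every calibrated value unchanged (exactly, as rational arithmetic; to
  float round-off in the implementation).
* **Spike-in invariance.** Changing the cell mixture (3:1 → 3:2) leaves the
  expected calibrated experimental signal unchanged (< 3% observed shift in
  simulation; < 0.3% typical).
* **Linearity.** Scaling the true occupancy by *c* scales the expected
  calibrated signal by *c*; this is what makes before/after ratios estimate
  the retained fraction.

The "normalised to 1 million reads" denominator is taken to be IPx — the
reads the track is actually built from; `denominator="ip_total"` switches
to IPx + IPc for sensitivity analysis.

## Read QC and sequential assignment

Reads are hard-clipped (first 10 bases) and truncated at original position
200 — a typical 220 bp single-end read becomes 190 bp — then reads shorter
than 50 bp are dropped. Assignment is calibration-first: a read with any
exact full-length occurrence (either strand) in the calibration genome is
consumed there and never tested against the experimental genome; leftovers
are tested against the experimental genome; the remainder are unassigned.
Reads with exactly one occurrence are "unique" and only they contribute to
the four OR counts and to coverage; multimappers are tallied but excluded.
The five-way partition (calib unique/multi, exp unique/multi, unassigned)
always sums exactly to the input count.

Matching is exact string matching accelerated by a sorted 31-mer index with
full verification of every candidate, so lookups return precisely the
occurrence set (a reverse-complement-palindromic query legitimately yields
two strand-tagged hits per position). Exactness is the right model here
because the synthetic genomes are *constructed* to make it the truth (next
section); real data is aligned upstream by a conventional aligner and
ingested as tab-separated alignment records.

## The generative model

The simulator draws, per sample of `reads_per_sample` reads:

* **WCE**: fragment start chromosomes/positions proportional to DNA mass
  (cells × length), uniform within the chromosome.
* **IP**: fragment midpoints proportional to cells × per-bp occupancy,
  except a fraction `ip_background` drawn WCE-style (occupancy-blind
  capture).
* Fragment length uniform on [200, 1000] bp (the stated shearing range,
  with the uniform law as the simplest consistent choice), truncated at
  chromosome ends; one read of 190 bp from the fragment 5′ end on a
  uniformly chosen strand.

True occupancy is `baseline + amplitude · max(0, 1 − |p − anchor|/halfWidth)`
— a flat chromosome-arm level with a triangular pericentric peak at each
CDEIII anchor; the calibration genome's occupancy is flat. A release
perturbation multiplies the landscape (optionally under a mask) by a known
`retained_fraction` in [0, 1].

Genomes are i.i.d. uniform nucleotides; the calibration genome is
regenerated until the pair shares no k-mer, forward or reverse complement,
at k = min(31, read length). Since any shared substring of length ≥ k
contains a shared k-mer, full-length (and default-trimmed, 180 bp) reads
then match at most one genome, making exact matching a faithful oracle.
Ambiguity can be injected deliberately (`shared_segment_length`) to
exercise the calibration-first precedence rule. For read lengths below
about 31 bp the guarantee applies at the full read length only, so heavily
trimmed ultra-short reads could in principle become ambiguous; the default
configuration never enters that regime.

All randomness flows from one root seed through `numpy` `SeedSequence`
children spawned in a fixed order (genomes first, then WCE/IP per
condition), so identical configurations produce byte-identical FASTA/FASTQ
and reports.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| chromosomes × length | 16 × 150 kb | enough chromosomes for 16-fold averaging at desk scale |
| calibration genome | 2.4 Mb (4 chromosomes) | equal to the experimental total, so the 3:1 cell mix gives a ¼ calibration DNA-mass share |
| mix_ratio | 3.0 | the protocol's 15:5 culture-unit mixture |
| fragment_min/max | 200 / 1000 bp | the stated shearing size range |
| read_length | 190 bp | the platform's average read length |
| arm_baseline / amplitude / half-width | 1 / 4 / 10 kb | a strong but localised pericentric enrichment over a uniform arm level, the qualitative shape of budding-yeast cohesin profiles |
| ip_background | 0.02 | an efficient IP with ~2% occupancy-blind capture |
| reads_per_sample | 200,000 | resolves a 2% retention difference at the default genome size |

`ip_background` deserves a note: occupancy-blind IP reads add a
mass-proportional floor to both genomes' IP signal, which biases the
retention estimator slightly upward (the floor does not shrink with the
release). The bias has a closed form under this model; at the defaults it
is at most ≈ +0.007 absolute over retained fractions in [0.14, 1], well
inside the ±0.02 recovery tolerance the tests assert. Larger backgrounds
inflate it roughly linearly — a real limitation of OR calibration, not of
the simulator.

## Coverage, retention, meta-profiles

* **Pileup**: depth(p) = number of unique alignments with start ≤ p < end,
  materialised densely (explicit zeros everywhere, the gap-filled
  representation). Verified exactly against a per-position brute-force
  counter on randomized instances.
* **Retention**: both calibrated tracks are mean-binned (default 1 kb —
  per-bp ratios are hopelessly zero-inflated at realistic depth; the bin
  size is a declared choice, configurable), then percent remaining =
  100 · after/before per bin, masked where before = 0 (masked fraction
  reported); the median is over defined bins. The reciprocal
  (fold reduction) is reported alongside, since "ratio before/after" is
  ambiguous in prose.
* **Meta-profile**: for each offset in −window..+window (default 60 kb),
  the mean of the calibrated track at anchor+offset over the chromosomes
  that cover that coordinate. Truncation (with per-offset contributing
  counts) rather than zero-padding at chromosome ends: zero-padding would
  drag edge offsets toward zero and bias retention ratios. Asymmetric
  windows (e.g. −100 kb..+60 kb) are supported.
* **Genome fold change**: retention = mean(after)/mean(before) over offsets
  defined in both profiles, fold reduction its reciprocal.
* **Pericentric fraction**: signal in [anchor−w, anchor+w] over the
  chromosome (or genome) total. On a uniform track spanning 1.5 Mb with
  w = 60 kb this is 120 001/1 500 000 ≈ 8.0% (tested analytically). Note
  that on the default *synthetic* genome (150 kb chromosomes) the ±60 kb
  window covers most of each chromosome, so the synthetic pericentric
  fraction (~84%) is a property of the scaled-down genome, not a biological
  statement.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally and in BED/bedGraph output.
Zero denominators never produce infinities: retention bins, ratio-profile
offsets and fold-change means are masked or raise with the offending
quantity named. Empty queries to the index raise; empty post-trim reads are
counted as unassigned. `fill_gaps` rejects duplicate or out-of-range
positions. Partial trailing retention bins average over their actual width.

## What the synthetic tests do and do not show

Passing recovery tests show the pipeline's statistics are unbiased and
precise *under the generative model*: uniform base composition, perfectly
mappable genomes, exact matching, uniform fragment lengths, no PCR
duplicates, no GC or mappability bias, and a background that is a simple
mass-proportional mixture. Real libraries violate all of these to some
degree; in particular mappability holes and copy-number differences between
the two genomes move the OR, and none of that is modelled here. The
synthetic results validate the arithmetic and the estimator, not the
biology of any particular dataset.

## Problem sizes used in the shipped checks

The recovery experiments run at the defaults above (2 × 10⁵ reads per
sample, three seeds per retained fraction in {0.14, 0.5, 1.0}); the
spike-in comparison uses five seed-paired runs per mixing ratio. These
sizes make the Monte-Carlo error comfortably smaller than the asserted
tolerances (±0.02 retention, ±3 percentage points on medians, 3% on
spike-in shift) while keeping a full validation run in minutes on one core.
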