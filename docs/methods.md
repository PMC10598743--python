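# Methods

This note records the models, conventions and numerical choices behind
`utrpause`, in the order data flow through the package.

## Coordinates

All genomic coordinates are 0-based half-open (BED convention).
Transcript-relative positions are 0-based with 0 = the first nucleotide
downstream of the stop codon, increasing in the direction of
transcription; "upstream"/"downstream" always follow transcription, so
on the minus strand downstream means decreasing genomic coordinate.
Plots that label the window "1 to 400 nt downstream" correspond to
relative positions 0..399 with a +1 display offset.

A transcription unit's 3′UTR window is exactly `utr3_len` nt
(default 400).  Units whose window would run past a chromosome end are
**excluded, not truncated**: uniform window lengths keep metagene
profiles and densities comparable across genes.  The cost is the loss of
telomere-proximal genes, which on a realistic genome is a handful of
units.

## Pause calling

The caller treats the background read count at each nucleotide as
negative binomial and asks whether the focal count is extreme relative
to its own neighborhood.

* **Window.**  Up to 100 nt on each side of the focal position ("the
  surrounding 200 nucleotides"), clipped to the unit span; positions
  whose clipped window holds fewer than 50 nt are not callable.  The
  focal nucleotide is excluded from its own window so a tall spike
  cannot inflate the threshold that judges it.
* **Fit.**  Method of moments: the window mean m and sample variance v
  (ddof = 1), with v floored at m before taking σ = √v.  The floor is
  required because an NB has variance ≥ mean; without it, a locally
  constant window (v = 0) would make every fluctuation a pause.  Moments
  rather than maximum likelihood because only (μ, σ) are consumed and
  the moment fit is exact, fast and has no convergence failures on
  degenerate windows.
* **Rule.**  Called iff count ≥ `min_pause_reads` (default 2) **and**
  count > μ + 3σ, strictly.  Strictness makes perfectly uniform
  coverage non-pausing even where σ = 0.
* **Unit filter.**  Mean coverage over the unit plus its window must be
  ≥ 2 reads/nt (inclusive).  Replicate tracks are summed before
  filtering and calling.  The same filter backs the nucleotide-level
  replicate correlation; gene-level correlations use per-unit RPKM with
  the unit-plus-window length as the denominator.

A note on the false-positive floor: for right-skewed count
distributions the "mean + 3σ" rule does not enjoy the Gaussian
one-sided 3-SD tail (0.00135).  Even an ideal Poisson(4) background with
known parameters has P(X ≥ 11) ≈ 0.0028, and local estimation plus
overdispersion push the realized per-nucleotide call rate on pure
background to roughly 0.005–0.01 under the generator defaults.  Users
comparing conditions should therefore always normalize against shuffled
sets rather than treating raw pause counts as purified signal.

* **Shuffles.**  Per unit (optionally per region, body vs 3′UTR), the
  same number of positions is redrawn uniformly without replacement;
  read counts are carried over from the source records so read-weighted
  statistics stay comparable.  If a region holds fewer positions than
  pauses the draw falls back to replacement with a warning.  Seeds are
  mandatory and per-unit substreams are derived via CRC32 so results do
  not depend on Python's hash randomization.
* **Overlap.**  The overlap of two pause sets is reported against its
  maximum possible value: 100·|A∩B|/min(|A|,|B|).

## Trinucleotide preferences

The context at a pause is read on the transcribed strand at a contiguous
offset triple, default (−1, 0, +1); minus-strand pauses are complemented
and read in transcription direction.  Pauses whose context leaves the
chromosome or contains N are counted as skipped, so the 64 counts always
sum to (pauses − skipped).  The preference for a trinucleotide is
(real + pc)/(shuffled + pc) with pseudocount pc = 1 by default; pc = 0
gives raw ratios for exact-count work, with undefined entries flagged
rather than dropped.  Because the shuffled set is size-matched per unit,
raw counts stand in for frequencies.  Body-vs-UTR contrasts subtract raw
ratios (not logs); cross-condition comparisons are Pearson correlations
over the 64 ratios.

## Poly(A) sites (3′READS logic)

Reads must begin with T; the maximal leading T-run of length t is
trimmed and recorded in the read id.  The next 17 nt are
reverse-complemented and matched exactly against the genome; 0 or ≥ 2
genome-wide hits (both strands counted) discard the read.  Exact unique
17-mer matching replaces a short-read aligner run with zero mismatches
and unique-hit filtering — equivalent on the synthetic genomes this
package targets, and pre-mapped positions can be supplied for real
genomes.  A mapped read survives iff t strictly exceeds the maximal
sense-strand A-run starting immediately downstream of its last templated
base; the site is recorded at that base, not shifted past the run (the
strictest reading of "more Ts than the genome can template").  Retained
reads accumulate into single-nucleotide site counts and project onto
unit windows as per-unit profiles.

## Spatial statistics

Upstream distance from a pause to a site is d = pause − site ≥ 0;
co-located events (d = 0) fall in the first bin and bins are half-open
([0,10), …, [40,50)), so d = 50 is excluded.  Per-pause bin counts use a
site indicator by default (any retained read), with a read-weighted
variant behind a flag.  The KS test compares per-pause count
distributions, real vs shuffled, one bin at a time — the finest sample
unit consistent with a per-pause statistic; per-gene aggregation is
available by summing beforehand.  Because these counts are small
integers, ties defeat the exact two-sample computation and the
asymptotic p-value is used; the test is then conservative (its realized
null rejection rate sits well below the nominal α — 0/1000 bin-tests at
α = 0.05 in the package's own 200-seed calibration), which costs power
at small n but never manufactures significance.  The distance ratio
divides mean nearest-upstream-site distances (real/shuffled), excluding
pauses with no upstream site symmetrically, with a delta-method SE:
SE(r) = r·√(SE_r²/m_r² + SE_s²/m_s²).

## Random-forest classification

Feature categories: `distance_to_polya` (nearest upstream site distance,
with sentinel `utr3_len` when a pause has no upstream site — rows are
kept, not dropped; plus the five 10-nt bin counts), `sequence_context`
(one-hot sense-strand bases at offsets −4..+4; out-of-range or N offsets
one-hot to all-zero), and per-position tracks (`dna_shape`,
`chromatin`, `ctd`) read at the exact candidate position.  The forest
uses mtry = 5 features per split and 2000 trees, trained on a stratified
75% split and scored by ROC AUC on the held-out 25%.  Class imbalance
(shuffled counts per unit are similar but not equal to real after
region restriction) is handled by stratification alone; AUC is
imbalance-robust.  Cross-condition matrices train on all rows of one
condition and score all rows of another; diagonal cells use the
within-condition split.  Note that scoring a model on its own training
rows only measures memorization (a fully grown forest reaches AUC 1.0
there by construction), so "same-condition generalization" must be read
off the diagonal, not off a duplicated condition.

Fully grown forests also carry an intrinsic excess risk on
low-dimensional problems: on a one-feature task with two unit-variance
Gaussian classes 2σ apart, the held-out AUC plateaus near 0.88 —
measurably below the Bayes AUC Φ(√2) ≈ 0.921 — and does not close with
more data, in either scikit-learn or R's randomForest.  AUCs from this
package should be compared between categories or conditions, not read
as Bayes-optimal separability.

Strain-level PCA encodes each condition as a presence/absence vector
over the union of (unit, position) pause sites, centers, and projects
onto the first two components; identical inputs are returned as all-zero
coordinates with a degeneracy flag instead of NaNs.

## The synthetic generator

The generator emulates the *structure* the analyses assume, not yeast
biology:

* **Coverage** — i.i.d. NB(mean, size) per nucleotide of each unit span
  on the unit's strand.  Defaults: mean 4 reads/nt (a realistic
  high-coverage gene after summing replicates) and size 10, i.e.
  variance/mean = 1.4, moderate overdispersion.  Positional
  independence matches the marginal-NB model the caller fits;
  autocorrelated backgrounds are intentionally out of scope.
* **Pauses** — planted uniformly at 5/kb (mid-range of per-strain 3′
  pause densities), count = round(20 × mean), overwriting background.
* **Poly(A)** — `coupled`: each 3′UTR pause spawns one site U(5, 45) nt
  upstream (sites pushed below the window are dropped); `uniform`:
  fixed sites per unit, uniform over the window.  Placement direction
  (sites upstream of pauses) matches the measurement direction of the
  coupling statistics.  When the genome is supplied, a site landing on
  a sense-strand A is nudged upstream to the nearest non-A base: a
  cleaved transcript's last templated base is only identifiable at a
  non-A position because templated As are absorbed into the tail.
  Without the nudge, reads gain extra leading Ts, truncating the mapped
  17-mer and shifting recovered sites — the generator therefore plants
  only recoverable sites, and exact-recovery tests mean exactly that.
* **Reads** — R1 = T^k + revcomp(last 17 templated nt).  Genuine reads
  draw k = downstream A-run + U(4, 15), guaranteeing survival of the
  internal-priming filter; with probability `internal_priming_frac` the
  read is instead anchored immediately upstream of a genomic A-run with
  k ≤ run length, guaranteeing rejection.  Qualities are constant 'I'
  and unused.
* **Feature tracks** — standard normal noise plus snr × a
  peak-normalized Gaussian-smoothed pause indicator (kernel sd 0.5 nt).
  The association is essentially nucleotide-resolution because
  downstream consumers read the value at the exact candidate position;
  snr is therefore the at-pause signal amplitude in noise-SD units, and
  snr 0 yields pure noise.

Every simulator is a pure function of (config, seed); each draws from an
independent stream derived from the seed, so changing one stage's
settings never perturbs another's draws.  Truth tables (planted pauses
and sites) are emitted alongside the data for recovery tests.

What passing tests on this generator do **not** show: robustness to
autocorrelated or position-dependent backgrounds, realistic base
composition (A-rich 3′ ends make internal priming far more frequent than
a uniform genome suggests), mappability structure of a real genome, or
biological coupling mechanisms beyond a fixed upstream offset.

## Problem sizes

Tests and the acceptance script run at deliberately small scales chosen
to make each statistical claim decisive while staying desk-sized:
50-unit strains for caller checks, ~1000 units (≈2000 3′UTR pauses) for
per-bin coupling significance, 200 seeds at 40 units for null
calibration, and 10 seeded repetitions of the 2000-row classifier
baseline.

## Known limitations

* The caller is designed for the 3′-window question; gene-body calling
  ignores introns and multi-sample joint calling is out of scope.
* Exact-match mapping cannot place reads on repetitive real genomes;
  supply pre-mapped positions there.
* KS on small discrete counts is conservative (see above); for small
  pause sets prefer the distance ratio.
* The 3-SD rule's false-positive floor (≈0.3–1 calls per kb of pure
  background) makes shuffled-normalized statistics mandatory for
  cross-condition claims.
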