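# Methods

## Signal model

Translation elongation advances one codon (3 nt) per step, so the
density of ribosome P-sites along a translated region is enriched at
every third nucleotide relative to the reading frame. `ribospec` treats
the P-site-adjusted coverage of a region as a discrete signal over its
transcript-space coordinate set and asks how much power it shares with
an idealized unit comb (1,0,0,1,0,0,…) at exactly 1/3 cycles per
nucleotide. Shared power is measured by magnitude-squared spectral
coherence, which is scale-free and phase-invariant: a region translated
in *any* frame scores high, and multiplying coverage by a constant
changes nothing (the explicit max-normalization additionally pins values
to [0,1] for visualization).

### Windowed estimation

Coherence of two fully deterministic sequences estimated from a single
unsegmented stretch is identically 1, so estimation must average over
sub-estimates. Two nested levels are used:

* **Sliding windows** of N = 30 nt stepped by L = 3 nt across the
  region. M = ⌊(|C| − N)/L⌋ + 1 windows fit; the per-window coherences
  are averaged into the region score and are also exported as a genomic
  track (split across splice junctions) for inspection.
* **Welch segments** inside each window: overlapping 12 nt segments
  (overlap 6 nt ⇒ 4 segments per window), each mean-subtracted, no
  taper (rectangular). Cross- and auto-spectra are averaged across
  segments before forming |P̄ₓᵧ|²/(P̄ₓₓ·P̄ᵧᵧ). Window and segment lengths
  are constrained divisible by 3 so the tri-nucleotide frequency falls
  exactly on segment DFT bin seg/3 (= 4 by default); no interpolation is
  ever needed. The estimator is numerically identical to
  `scipy.signal.coherence(..., window="boxcar", nperseg=12, noverlap=6,
  detrend="constant")` evaluated at that bin (cross-checked in tests),
  but is computed with a vectorized single-bin DFT so thousands of
  regions and resampling trials stay fast.

The ideal signal's local phase in the window starting at m is
(frame_offset − m) mod 3, so every window probes the same absolute
frame; with the default step of 3 this phase is constant. Because
coherence magnitude is invariant to a pure phase shift of one input,
this choice affects only the exposed ideal-signal construction, not the
score.

### Degenerate inputs and tie-breaks

* A region with no coverage at all is *unscorable* ("no coverage"), as
  is a region shorter than one window ("too short"); both appear in the
  output with a reason instead of a score.
* A window whose auto-power at the target bin is numerically zero
  (empty or constant coverage) contributes coherence 0. "Numerically
  zero" is relative — below 1e−20 of the window's mean square — so the
  float residue left by demeaning a constant window does not
  masquerade as signal.
* Coherence values are clamped to [0,1] against round-off; scores are
  written with 6 decimals.
* A score exactly at the calibrated threshold is called translated
  (inclusive boundary, a documented convention).

Mean windowed coherence has a substantial noise floor: for white-noise
coverage the expected per-window coherence with 4 half-overlapping
segments is ≈ 0.35–0.4, which is why untranslated regions score around
0.4 rather than 0. Classification works on the contrast, not the
absolute value.

## P-site assignment and coverage

Reads are reduced to a single inferred P-site: 5′ end + offset, with the
community-standard +12 nt offset for fragment lengths 26–32 by default
(configurable per length; a global default offset can catch other
lengths, otherwise such reads are skipped and tallied). Only primary,
strand-matched alignments above a MAPQ floor count, and a read
contributes only if its P-site coordinate is a member of the scored
region's coordinate set. The same reads define the region's FPKM
(count × 10⁹ / (length × library size)) so abundance and score describe
identical evidence. When the alignment file is a subset of a larger
library (every simulated fixture is), the library size can be supplied
explicitly (`--library-size`); otherwise the BAM's own mapped-read total
is used.

Transcripts whose genomic span overlaps (on either strand, optionally
within a flank) a transcript of the opposite coding/non-coding class can
be removed before analysis; both members of a conflicting pair are
dropped, same-class overlaps (isoforms) are kept.

## Calibration and posterior

Scores from protein-coding regions with FPKM ≥ cutoff (default 5) form
the active sample; scores from regions below the cutoff form the
empirical null (an alternative mode takes annotated non-coding biotypes
as the null). The translation threshold is the empirical (1 − FDR)
quantile of the null — per-comparison false-positive control on the
empirical null — so it depends on the null sample alone. The posterior
is f_a(s)·π / (f_a(s)·π + f_n(s)·(1 − π)) with π the active sample
fraction and f_a, f_n Gaussian KDEs fit on the logit of the (bounded)
scores, Jacobian-corrected back to score space and floored at 1e−10.
KDE (rather than histogram) densities are a deliberate smoothness
choice; the bandwidth is scipy's Scott rule unless overridden.

Both partitions must hold at least 50 scores (configurable) or
calibration aborts with advice to change the cutoff.

Note a structural property of FPKM-stratified calibration: the null
partition contains *translated but weakly covered* regions, so the
threshold lands well above the scores reachable at low coverage.
Sensitivity at the FDR threshold is therefore a statement about
adequately covered regions — in the fixtures, essentially all translated
regions above the calibration cutoff are recovered (~0.99), while
recovery over *all* translated regions including near-empty ones is
bounded by coverage, not by the classifier.

## Comparator metrics

* **FLOSS**: a region's fragment-length distribution (default range
  20–40 nt, out-of-range reads tallied and ignored) is compared with the
  pooled distribution of annotated coding CDS regions by total-variation
  distance (half the L1 difference; 0 identical, 1 disjoint). Outlier
  calling bins coding regions by log₁₀ read count (bin width 0.5 dex,
  sparse bins merged), takes each bin's Tukey upper fence Q3 + 3·IQR,
  enforces a monotone non-increasing fence in abundance, and
  interpolates between bin centres.
* **ORFscore**: P-site counts folded into the three codon frames of the
  annotated CDS (first and last codon excluded by default — initiation
  and termination pile-ups), X = Σ(Fᵢ − F̄)²/F̄, score = log₂(X + 1),
  negated when an out-of-frame count exceeds the in-frame count.

## Benchmarking

ROC/AUC uses the midrank Mann–Whitney statistic with a full threshold
sweep, over the abundance cutoff grid {0.5, 1, 3, 5, 10} FPKM. Two
labelling modes exist because two ground truths exist. On real
libraries translation status is unobserved, so the label is the
abundance proxy fpkm ≥ cutoff over all regions. On simulated data the
simulator's truth is the label and the cutoff instead acts as the
evaluation's inclusion floor, since benchmarks in this field are always
restricted to minimally covered regions; FLOSS is negated before
ranking. Under the abundance-proxy protocol the coherence score
dominates both comparators at every cutoff (e.g. ≈0.98 vs ≈0.66 for
ORFscore at the 1.0 FPKM cutoff on default fixtures). Under truth
labels at the lowest floors, ORFscore ranks (near-)perfectly on this
simulator — unsurprisingly, since the generator plants its signal
directly in frame occupancy and every simulated read's frame is exactly
recoverable, making whole-region frame enrichment the sufficient
statistic of the generative model; real libraries, with heterogeneous
digestion offsets and non-canonical ORF usage, are far less kind to it.

Pipeline work is chunked by chromosome and merged in fixed
(chrom, start, transcript_id) order, so serial and multi-worker runs
produce byte-identical output.

## Synthetic data: what it emulates, what it does not

The simulator writes a GENCODE-style GTF (two chromosomes, ~half
multi-exon transcripts, coding ones with 5′UTR/CDS/3′UTR and CDS length
a multiple of 3), a coordinate-sorted SAM, and a truth table, all
deterministic under one seed. Translated regions draw each P-site by
choosing a codon uniformly and a frame with probabilities
(p, (1−p)/2, (1−p)/2) — p = 1/3 is no periodicity, p = 1 a perfect
comb; untranslated regions place P-sites uniformly. Read lengths follow
a 28–30 nt-peaked mix over 26–32 for coding-style reads and a flatter
mix for non-coding transcripts. Reads are emitted as single-block
alignments anchored so the +12 P-site recovers the drawn position
exactly; read bodies may overhang an exon end but P-sites never do, so
extraction reproduces the truth count vectors exactly.

Default study conditions, chosen once for realism: frame fidelity
p = 0.85 (a good cycloheximide library), abundance
FPKM ~ LogNormal(ln 8, 1.5) shared by both classes (so classification
cannot lean on abundance), notional library size 5×10⁷ mapped reads,
expected region read count = FPKM × length × library/10⁹ (Poisson).

Not emulated: realistic sequence content (reads are poly-A
placeholders), base qualities, UMI/duplication structure, multimapping,
offset heterogeneity across read lengths, splice-spanning read bodies,
and UTR background coverage on coding transcripts. Passing tests
therefore demonstrate correct recovery of the modelled signal, not
performance on the full messiness of real libraries.

## Length-bias resampling robustness

To mimic libraries whose fragment-length distribution drifts away from
the 28–30 nt peak (e.g. cycloheximide-free protocols), reads from one
high-coverage synthetic gene (100,000 reads, 1,200 nt CDS) are
resampled — 1,000 trials of 10,000 reads — with weight
exp(b·|length − 28.5|), and each trial's coverage is re-scored. b = 0
reproduces the population mix; increasing b flattens the length
distribution toward uniform. This exponential weight is an invented
stand-in with the right qualitative behaviour, not a published scheme,
and it overshoots for b ≳ 1 (extreme lengths start to dominate), so the
monotone-flattening property holds on b ∈ [0, 1] and b = 2 serves as
the "strongest bias" condition. Because the score depends only on
P-site positions, and positions are resampled almost uniformly within
the gene, the median score at the strongest bias stays within the Tukey
fence of the unbiased trials — coherence scoring is insensitive to
fragment-length composition per se. Sampling is without replacement via
the Gumbel top-k device, deterministic under the seed.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: libraries
of 100 coding + 100 non-coding transcripts (5 seeds averaged for AUCs),
score mixtures of 2,000 nulls + 600 actives (10 seeds) for FDR
calibration, 50 regions per periodicity level for the p-sweep, and the
1,000 × 10,000-read resampling analysis above. These sizes give stable
estimates (AUC standard error ≈ 0.01) while a full suite run stays
around a minute.

## Known limitations

* The windowed-coherence noise floor (~0.4) compresses the usable score
  range; scores are comparable within a library but not across
  estimator geometries.
* FPKM-stratified calibration inherits the biases of FPKM itself on
  short regions and shallow libraries.
* The per-window track reports window-start-anchored values; sub-window
  (per-codon) resolution is out of scope, as is de novo ORF enumeration
  across frames — candidate uORFs are scored as user-specified
  sub-regions.
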