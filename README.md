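# ribospec

Classification of actively translated transcripts and sub-regions from
ribosome profiling (ribo-seq) alignments, by spectral coherence with the
tri-nucleotide periodicity of translation.

## The problem

Ribosome profiling sequences ~28–30 nt mRNA fragments protected by
translating ribosomes. Because ribosomes advance codon by codon, the
P-site-adjusted coverage of a *translated* region carries a strong
period-3 component, while untranslated regions (most non-coding RNA,
untranslated ORFs) do not. `ribospec` quantifies that component and
turns it into an FDR-calibrated translation call — using the ribo-seq
library alone, with no matched mRNA-seq requirement. It is aimed at
anyone asking "which annotated transcripts (or which candidate uORFs)
are being translated in my sample?"

## The score

For a region with coordinate set *C* (in transcript orientation), P-site
counts are normalized to the position of highest coverage, giving
*R* ∈ [0,1]. The score is the mean magnitude-squared coherence, at the
tri-nucleotide frequency *j* = 1/3 cycles·nt⁻¹, between *R* and an
idealized periodic reference *S* = (1,0,0,1,0,0,…) over sliding windows:

    Spec(R,S;j) = (1/M) · Σₘ Coh(R[m, m+N), S_N ; j)

with window length *N* = 30 nt, step *L* = 3 nt, and *M* the number of
windows fitting the region. Within each window, `Coh = |P̄ₓᵧ|²/(P̄ₓₓ·P̄ᵧᵧ)`
is estimated by Welch's method from overlapping mean-subtracted 12 nt
segments (overlap 6 nt, rectangular taper), so the target frequency sits
exactly on DFT bin 12/3 = 4.

Scores from protein-coding regions above a user-set FPKM cutoff form the
"active" distribution, scores below it the empirical null; the call
threshold is the (1 − FDR) quantile of the null, and a posterior
probability of translation comes from kernel-density estimates of both
distributions. The two standard comparator metrics are included: FLOSS
(total-variation distance between a region's fragment-length
distribution and a pooled coding reference, with Tukey-fence outlier
calling) and ORFscore (signed log₂ chi-square statistic of P-site counts
across the three codon frames).

## Worked example

Everything below runs on synthetic data with known ground truth — no
downloads needed.

```bash
ribospec make-fixtures --out-dir demo/fx --n-coding 100 --n-noncoding 100 --seed 7
ribospec score --bam demo/fx/fixture.bam --gtf demo/fx/fixture.gtf \
    --out-dir demo/out --no-filter --library-size 50000000
# scored 200 regions -> demo/out/results.tsv
```

`results.tsv` (columns abridged):

```
transcript_id  region  read_count  fpkm       spectre_score  posterior  translated  floss     orfscore
SIMC00000      CDS     736         12.777778  0.887708       0.995736   True        0.026814  9.742972
SIMC00002      CDS     94          3.181049   0.608065       0.068847   False       0.083436  6.433283
SIMC00004      CDS     907         22.904040  0.942911       1.000000   True        0.022582  10.095903
```

SIMC00000 is a simulated translated CDS: coherence score 0.89, above the
calibrated threshold, posterior ≈ 1. SIMC00002 is translated but weakly
covered (FPKM 3.2): its score 0.61 falls below the threshold derived
from the null distribution, so it is not called at FDR 0.05 — abundance
limits power exactly as in real libraries. `calibration.json` records
the machinery:

```json
{"fpkm_cutoff": 5.0, "fdr": 0.05, "threshold": 0.705951519845587,
 "prior_active": 0.4189189189189189, "n_active": 62, "n_null": 86}
```

Benchmarking against the simulator's ground truth over abundance floors:

```bash
ribospec benchmark --results demo/out/results.tsv --truth demo/fx/truth.tsv --out demo/bench.tsv
#        metric  fpkm_cutoff      auc  n_pos  n_neg
# spectre_score          0.5 0.958333     95     96
#      orfscore          0.5 1.000000     95     96
# spectre_score          3.0 1.000000     71     69
# ...
```

At minimally covered regions (floor 0.5 FPKM) the coherence score
separates translated from untranslated regions with AUC 0.96; from
3 FPKM upward separation is perfect. Without `--truth`, labels follow
the FPKM-cutoff proxy used for benchmarking real libraries. A
`resample` subcommand runs the fragment-length-bias robustness analysis
(see `docs/methods.md`).

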