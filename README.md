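# inoseq

Tools for detecting and quantifying **stochastic inosine misincorporation
into RNA** — the transcription error that arises when inosine triphosphate
(ITP) accumulates in the nucleotide pool, e.g. upon loss of the
house-cleaning enzyme ITPase. The package is aimed at researchers analysing
ITPase-deficiency models (or any system with non-canonical NTP
incorporation) who need to turn standard upstream outputs — pileup
statistics from aligned reads, variant calls, LC-MS/MS nucleoside levels,
polysome absorbance traces — into per-base misincorporation rates and
translation metrics.

## What it computes

**Substitution statistics (direct-RNA and short-read).** At each reference
position the base substitution frequency is

    freq(i) = 100 · mismatches_i / (matches_i + mismatches_i)

with N calls and deletions excluded. Per-base accuracy is
`100 − mean(freq over positions with that reference base)`; its ranking
across A/C/G/U is the accuracy hierarchy, whose degradation pattern reveals
which template bases inosine replaces. Two-condition comparisons subtract
positionwise frequencies (treated − control) and tally enriched positions
on each side. Class-specific frequencies (e.g. `C>G`, the reverse
transcription signature of inosine) restrict the numerator to one
alternative base.

**Candidate-gene windows.** For short-read data the per-gene readout is the
pooled class frequency inside the first contiguous 1 kb window from the
5′ end where every position has ≥ 50× coverage; Q ≥ 20 variant filtering,
two-group *t*-tests and Dunnett-adjusted panel comparisons are included.

**Mass-spec conversions.** LC-MS/MS reports inosine as IMP per 10⁶ AMP.
Since A is a fraction *f*₍A₎ of all bases, the per-base frequency is
`level/10⁶ · f_A` and the familiar "1 in N bases" denominator is the
nearest integer to 1/freq. *f*₍A₎ comes from a reference sequence or is
calibrated from one paired (level, denominator) measurement. Calibration
curves use 1/x-weighted least squares.

**Polysome profiles.** A254 traces are baseline-subtracted at the lowest
point between the 40S and 60S apexes, peak boundaries are the lowest
abutting points, the polysome window spans 1.42× the 60S→80S&disome apex
distance, and translation is summarised as the polysome:(80S&disome)
trapezoid-AUC ratio, compared between genotypes by Student's *t*-test.

**Synthetic data.** `inoseq.simulate` generates all of the above —
transcripts, inosine-bearing molecule populations with a G>C>A>U template
preference, direct-RNA or short-read pileups, MS levels, polysome traces —
deterministically from one seed, so every stage is testable offline.

## Worked example

```python
from inoseq.msquant import MsLevel, calibrate_f_A, rate_from_level

f_a = calibrate_f_A(427, 9379)          # 0.2497, from the 0.1 mM ITP pair
rate = rate_from_level(MsLevel(21649), f_a)
print(rate.denominator)                  # 185  -> 1 inosine in 185 bases
```

Running `python examples/two_condition_profiles.py` (a 1650-nt transcript,
depth 300, misincorporation rates 0 vs 1/185 under a 3%-background
direct-RNA readout) prints:

```
positions enriched in treated: 943/1650
positions enriched in control: 577/1650
ties: 130
control: accuracy hierarchy U>A>C>G (A=96.98%, C=96.95%, G=96.91%, U=97.03%)
treated: accuracy hierarchy A>U>C>G (A=96.77%, C=96.50%, G=96.25%, U=96.76%)
```

The treated library shows a clear majority of positions with elevated
miscalls (stochastic, transcript-wide misincorporation) and its accuracy
hierarchy bottoms out at G — inosine most often replaces guanosine. The
other scripts in `examples/` cover MS conversions, candidate windows,
polysome ratios and calibration fits, each printing the numbers it
computes and what they mean.

A thin CLI mirrors the stages:
`inoseq simulate|stats|delta|window|msconvert|polysome|e2e` (see
`inoseq --help`).

## Layout

- `src/inoseq/io.py` — FASTA / pileup-TSV / minimal-VCF / trace-CSV readers
  and writers with strict validation (1-based coordinates, RNA alphabet)
- `src/inoseq/simulate.py` — the synthetic-data generator
- `src/inoseq/pileup.py` — substitution frequencies, accuracies, deltas
- `src/inoseq/windows.py` — depth-gated windows, variant filters, panel tests
- `src/inoseq/msquant.py` — level↔rate conversions, weighted calibration
- `src/inoseq/polysome.py` — trace quantification and group comparison
- `docs/methods.md` — models, assumptions, parameter choices, limitations
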