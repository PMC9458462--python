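# Methods

## The measurement problem

RNA polymerases incorporate inosine triphosphate opposite template bases
when ITP escapes pool sanitation, leaving inosine scattered through
transcripts at rates from roughly 1 in 10,000 to 1 in 100 bases. No
sequencing chemistry calls inosine directly, so the package quantifies it
through three indirect readouts: (i) elevated basecall errors in nanopore
direct-RNA reads, (ii) apparent X>G substitutions in short-read cDNA data
(inosine pairs with cytosine during reverse transcription and is read as
guanosine), and (iii) IMP nucleoside abundance by LC-MS/MS after digestion.
A fourth arm quantifies the downstream phenotype — reduced translation —
from polysome profiles.

## Substitution statistics

For a pileup row with per-base call counts, matches are calls of the
reference base and mismatches are calls of the three other canonical
bases; N calls and deletions never enter either term. The positional
statistic is `100·mismatches/(matches+mismatches)`, undefined (NaN) when
the denominator is zero; undefined positions are excluded from every mean
and tally and surfaced in a QC summary rather than silently counted as 0.

Per-base accuracy averages the positional frequencies of one reference
base **unweighted by depth** — each position counts once. Whether the
positional average should be read-weighted is genuinely open; both are
implemented (`depth_weighted=True`) and unweighted is the default because
the accuracy figures it is compared against are transcript-position
averages. Class frequencies (`ref>alt`) use the same denominator with the
numerator restricted to one alternative base, so the three classes of a
position partition its total frequency exactly — a tested identity.

Condition deltas are positionwise (treated − control); the sign tally uses
`tie_epsilon` (default 0, i.e. exact ties only — float frequencies at
realistic depths essentially never tie, but the knob exists because a
coarse depth quantises frequencies). Tally conservation
(enriched-a + enriched-b + ties = evaluated positions) is a tested law.

## Candidate-gene windows

"First continuous 1 kb stretch at ≥50× from the 5′ end" is interpreted
**pointwise**: every position in the window must clear the threshold, and
the 5′-most qualifying window wins (multiple qualifying windows and
overlapping genes have no stated rule; first-window is the deterministic
choice). A mean-depth reading of the threshold is available via
`criterion="mean"`. Window class frequencies pool
raw counts across the window (`100·Σcount_alt/Σ(matches+mismatches)`)
rather than averaging positional percentages; pooling is robust at modest
depth and equals the evaluated-call-weighted mean of positional values, an
identity the tests assert. Variant records are filtered at Q ≥ 20
(boundary inclusive); a missing QUAL is conservatively treated as 0 so the
filter excludes it. Two-group comparisons use the equal-variance *t*-test;
multi-gene panels against a shared control use one-way ANOVA plus
Dunnett's multiple-comparison adjustment (multivariate-*t* based, via
scipy).

## Mass-spec conversions

IMP is reported per 10⁶ AMP. With *f*₍A₎ the fraction of A among all
bases, per-base inosine frequency is `level·10⁻⁶·f_A` — the only
conversion consistent with all published (level, "1 in N") pairs we use as
a fixture, each of which implies *f*₍A₎ ≈ 0.25 for these transcripts. The
"1 in N" denominator is the **nearest integer** to 1/freq (floor or
ceiling fail to reproduce the anchored pairs). For total-RNA samples where
no reference composition exists, *f*₍A₎ is calibrated from one paired
measurement via `f_A = 10⁶/(level·denominator)` rather than assumed to be
0.25. Because published levels and denominators are rounded means,
cross-pair reconstructions can land ±1–2 off the published integer; the
fixture test tolerates ±2 while the anchored conversions reproduce
exactly. Calibration curves minimise `Σ(1/xᵢ)(yᵢ−a−bxᵢ)²` (weighted least
squares, statsmodels), the standard response-proportional-noise weighting;
unknowns are inverse-predicted from the fitted line.

## Polysome quantification

Traces are normalised by **subtracting** the minimum absorbance between
the 40S and 60S apexes (subtraction, not division: it zeroes empty-region
areas and makes the AUC ratio invariant to detector scaling). Users supply
approximate apex landmarks for 40S, 60S and 80S&disome (the latter treated
as one peak, since monosome and disome are often unresolved); boundaries
between labelled peaks are the lowest abutting points — exact argmins over
the sampled trace, leftmost on ties. The 80S&disome trailing edge has no
stated rule; we search for the minimum within a span mirroring the
60S→apex distance, a configurable choice. The polysome window starts at
that trailing boundary and spans `factor × (80S&disome apex − 60S apex)`
with `factor = 1.42` by default; the geometric anchoring of that factor is
our interpretation and both the factor and anchoring are exposed. Areas
use the composite trapezoid rule with linear interpolation at interval
endpoints; AUC additivity over abutting intervals holds to 1e-9. Group
comparison is an unpaired two-tailed Student's *t*-test (equal variance;
Welch behind a flag, since the original choice is unstated), with an
explicit exact-separation flag when within-group variance vanishes.

## Synthetic-data generator

The generator emulates the study conditions, not nanopore physics:

- **Transcript**: 1650 nt, uniform composition by default (the scale of a
  firefly-luciferase coding sequence).
- **Misincorporation**: per-molecule independent Bernoulli substitutions.
  Template weights default to `G:1.0, C:0.6, A:0.35, U:0.25` — any
  strictly ordered positive vector realises the observed G>C>A>U
  preference; the values are invented and config-exposed. Per-base
  probabilities are normalised so the composition-weighted mean equals
  `overall_rate` exactly, making rates directly comparable with "1 in N"
  figures. Default condition rates: 0 (control) and 1/185 (high-ITP-like).
- **Direct-RNA readout**: background miscall 0.03 (per-base accuracies
  ~97%, matching the 96–98% control range), uniform across wrong bases;
  at inosine positions reads miscall with probability 0.8, the called base
  drawn from `G:0.5, C:0.25, A:0.15, U:0.10` renormalised to exclude the
  template base. These inosine parameters are placeholders for testing —
  no published data constrains the true pore emission distribution.
- **Short-read readout**: inosine is read as G with probability 1 (the
  reverse-transcription rule); at G template positions it is therefore
  invisible, as in real cDNA data.
- **Pileup collapse**: incidence is carried per position as a fraction of
  molecules and read calls are i.i.d. draws from the marginal call
  distribution. Read-level correlation along molecules, read-length
  distributions, alignment artifacts and signal-level effects are *not*
  modelled; every downstream statistic is positionwise, so tests passing
  on this generator say nothing about, e.g., alignment-induced error
  clustering in real libraries.
- **MS / polysome**: Gaussian replicate noise around the analytic level
  (truncated at zero); traces are Gaussian mixtures on a flat baseline
  (defaults: 40S/60S/80S&disome/polysome peaks at 8/12/17/24 gradient
  units). Real traces have sloping baselines and asymmetric peaks; the
  landmark-guided boundary logic is exercised, not proven, on them.

Determinism: one master seed; per-component generators derive from
`numpy.random.SeedSequence(seed, spawn_key=(k,))` with fixed component
keys, so identical configs give byte-identical outputs and the control and
treated libraries use independent streams.

## Numerical and interface choices

- Coordinates are 1-based inclusive everywhere; 0-based inputs must be
  converted at the reader boundary. DNA input (T) is silently normalised
  to U; ambiguity codes are rejected.
- Pileup rows whose matches/mismatches columns disagree with per-base
  counts are an error in strict mode (default); lenient mode recomputes
  from per-base counts with a warning.
- Argmin ties in boundary detection resolve leftmost, deterministically.
- Division-by-zero in batch statistics (fold changes, ratios, empty
  windows) yields NaN markers, never exceptions.
- Problem sizes in the test suite (transcripts of 300–1650 nt, depths
  30–10,000, 1000-case fuzzing for window/boundary oracles) were chosen so
  the full suite completes in a few seconds while keeping binomial
  standard errors small enough for 3-SE recovery assertions to be
  meaningful.

## Known limitations

- The direct-RNA inosine miscall model is qualitative; absolute treated
  accuracies track the configured parameters, not biology.
- Window analysis assumes one supplied transcript reference per gene;
  genome-coordinate and strand resolution belong upstream.
- The MS arm starts from reported nucleoside levels; chromatogram peak
  integration and instrument formats are out of scope.
- Landmark positions for polysome peaks are user input; there is no
  landmark-free peak caller.
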