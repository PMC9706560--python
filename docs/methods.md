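# Methods

## Sequence model and stack combinatorics

Sequences are single PNA strands over {A, C, G, T}, stored N→C; the duplex
partner is implied by antiparallel Watson–Crick complementarity and never
stored. A homoduplex of length `L` is a chain of `L − 1` overlapping
dinucleotide stacks. Because the duplex can be read from either strand, the
dinucleotide `X₁X₂` and its reversal-complement `comp(X₂)comp(X₁)` name the
same physical stack; this equivalence partitions the 16 dinucleotides into
10 classes (four self-equivalent: AT, TA, GC, CG; six paired: AA/TT, AG/CT,
GA/TC, AC/GT, CA/TG, GG/CC). Stack counts and the terminal-GC count are
therefore strand-symmetric, which the property suite checks exhaustively.
Odd-length strands are never self-complementary (the central base would
pair with itself) and need no special-casing.

## Nearest-neighbor model

The binding quantity of a duplex is

    Δχ = Σᵢ jᵢ·ΔΔχᵢ + Δχ_init + B·Δχ_T.GC

with the 0/1 indicator `B = 1` only when *both* terminal base pairs are
G·C. Rows of per-duplex counts form the `N × 12` design matrix (10 stack
columns, an all-ones initiation column, the B column). Fitting minimizes
`‖σ⁻¹(χ − Sε)‖²`; the reciprocal-SE weighting uses `wᵢ = 1/σᵢ²` in a
standard weighted least-squares solve (statsmodels WLS). Parameter standard
errors come from the scaled weighted normal-equations covariance and
p-values from two-sided t-tests on `N − 12` degrees of freedom.

Conventions and numerical choices:

- **Sign convention.** All quantities are stored signed (binding
  enthalpies negative). Published-style tables print magnitudes (−ΔH);
  conversion happens only at file boundaries (`neg_dH_kcal` columns,
  parameter CSVs). This prevents double-negation bugs.
- **Zero standard errors.** Literature-derived observations sometimes
  carry SE = 0, which reciprocal-SE weighting cannot invert. SEs below a
  floor (default: the smallest strictly positive SE in the set;
  configurable) are clamped to the floor with a logged warning. If every
  SE is zero the fit falls back to unweighted, again with a warning.
- **Rank checking.** The weighted design is screened by SVD; singular
  values below `1e-10 ×` the largest indicate unidentifiable columns,
  which are named in the error.
- **Prediction SE.** By default term errors are treated as independent
  (`SE² = Σ (jᵢ σᵢ)²`); fitted parameter sets retain the full covariance
  and `predict(..., use_covariance=True)` gives exact propagation.
- **Symmetry correction.** The 1.4 cal K⁻¹ mol⁻¹ C2-symmetry decrement
  applies to *entropy* predictions of self-complementary duplexes only,
  never to the enthalpy fit, and at most once per prediction.

The packaged reference parameter set (`data/nn_enthalpy_pna.csv`) holds
fitted stack/initiation/terminal-GC binding-enthalpy magnitudes for PNA
homoduplexes at 2-decimal precision. Eight of the ten benchmark-set
predictions recompute from it to within 0.05 kcal/mol of their published
values (residuals ≤ 0.02, attributable to table rounding); two sequences
(TGTTACGACT, AGGTAACCAG) deviate by > 2 kcal/mol under every defensible
stack convention and are flagged as anomalous rather than "fixed" — the
acceptance tests assert that they deviate. Recomputing the benchmark mean
relative error with these recomputed predictions gives 8.63% instead of
the published 8.74%, entirely from those two rows.

The grouped stack summary (mean magnitude per Watson–Crick bond-count
class) is the plain unweighted mean of class members; the 4- and 6-bond
class means reproduce their published values exactly, while the published
5-bond value (9.72) differs from the unweighted member mean (9.69) by an
unstated averaging choice we do not attempt to reverse-engineer.

## Two-state melting analysis

Absorbance curves are normalized by plain min-max,
`α = (A_max − A)/(A_max − A_min)`, without baseline fitting (a linear
sloping-baseline option exists in the generator only). Tm is the first
downward crossing of α = 0.5, linearly interpolated between bracketing
grid points. Equilibrium constants use the two-state concentration
relations (self-complementary `K = α/(2(1−α)²C_T)`, which gives exactly
`K = 1/C_T` at α = 0.5; otherwise `K = 2α/((1−α)²C_T)` for equal strand
concentrations). The van't Hoff regression is OLS of ln K on 1/T over
points with α in a configurable window, default (0.15, 0.85), to avoid
the divergent tails; `R = 1.987204 cal K⁻¹ mol⁻¹`, enthalpies in kcal and
entropies in cal K⁻¹ to match the field's tables; ΔG = ΔH − TΔS/1000 at a
298 K reference.

**Known limitation — min-max bias under noise.** With Gaussian absorbance
noise, the observed extremes overshoot the true baselines (the expected
maximum of the tail noise is positive), compressing α and biasing the
recovered ΔH toward less negative values — about +4.5% at noise
sd 0.005 on the default synthetic curve, several times the regression SE.
The regression SE itself is calibrated to the run-to-run spread (≥ 95% of
runs within 3 SEs of the ensemble mean); the bias is a property of the
min-max procedure, stays well inside the ~10% typical experimental error
of such measurements, and vanishes for noise-free curves (round trip
exact to < 0.1%). Noise-free recovery over any interior α window is part
of the test suite.

## MM-GBSA post-processing

The package consumes MM-GBSA tables (sequence, replicate mean, SE); it
never computes generalized Born energies. The standard-state correction is
`ΔG_ss = −RT ln(V°/V_box)` with `V° = 1661 Å³`: the sign convention makes
binding in a box larger than the standard-state volume less favorable
(more positive ΔG), consistent with referencing to 1 M; the magnitude
`|RT ln(V_box/V°)|` is convention-independent and is what the tests
assert. Calibration against experiment is unweighted OLS
(`χ_exp = a·χ_com + b`). Because least squares is linear in the
observations, fitting on calibrated data equals scaling the stack and
terminal-GC terms by `a` and mapping the initiation term to
`a·Δχ_init + b` — the intercept rides entirely on the per-duplex constant
column. Propagated parameter sets are flagged `calibrated`: the intercept
can be dominated by systematic computational error rather than physics,
and ΔΔG = ΔΔH − TΔΔS consistency across separately calibrated observables
is not guaranteed. Benchmark metrics are the mean absolute difference,
the mean of per-entry relative errors (entries with zero reference are
excluded with a warning), and R² of predicted vs reference.

## Hydrogen-bond statistics

Bond detection uses strict inequalities at both cutoffs (donor–acceptor
distance < 0.325 nm, angle < 30°), with the angle measured at the donor
between donor→hydrogen and donor→acceptor; an angle-at-hydrogen
(deviation-from-linearity) alternative sits behind a flag because tooling
conventions differ. Events are frame-discrete: a bond broken for a single
frame is an event of duration `dt`. Events touching either series boundary
are counted but flagged censored; occurrence curves include them. Terminal
pairs are positions 1 and L, internal pairs default to 3rd-position pairs;
both selections are configurable. The partition identity (melted time +
fully bonded time = total time, per pair) holds exactly by construction
and is asserted.

## Synthetic data

Generators are fully deterministic under a seed (numpy `default_rng`) and
default to the study's scales: 49 sequences of lengths 6–18 at 50% GC,
triplicate observations with homoscedastic Gaussian replicate noise of
1 kcal/mol (a length-proportional option exists because longer duplexes
show larger spread in end-point simulation estimates), melting curves on a
274–372 K grid at 2 K steps with 0.005 absorbance noise, and per-bond
two-state Markov chains with per-step probabilities `1 − exp(−rate·dt)`,
terminal pairs opening faster than internal ones. The ground-truth
parameter set defaults to the packaged reference values, so synthetic
enthalpies span the realistic ~50–160 kcal/mol magnitude range.

What synthetic data does *not* emulate: sequence-correlated systematic
error in simulation enthalpies, instrument baseline drift beyond a linear
term, cooperative (non-independent) bond kinetics within a pair, and any
atomic-resolution trajectory detail. Passing tests therefore demonstrate
correctness of the estimators under the stated stochastic models, not the
accuracy of MM-GBSA or melting experiments themselves; quantities that
require the original trajectories or raw absorbance data (simulation
correlation coefficients, measured melting points, bonded-percentage
tables) are validated through these property suites instead.

## Monte-Carlo calibration checks and problem sizes

Statistical tests use seeded ensembles sized for tight, fast checks: 200
repetitions of the 49-sequence fit for parameter-recovery coverage
(asserted per-parameter at ≥ 95% within 3 reported SEs — the joint
"all 12 terms at once" event has a theoretical ceiling near 94% even for
perfectly calibrated errors), 200 noisy melting curves, and 30–40
hydrogen-bond runs of 40–50 ns at 10 ps frames against exact
discrete-chain oracles (stationary bonded fraction; mean melted-set dwell
time by linear solve over the broken-bond-count chain). The recovery
coverage check uses the unweighted fit, which is the correct estimator for
the homoscedastic generator; reciprocal-SE weighting with SEs estimated
from only three replicates correlates the weights with the errors and
makes the reported SEs anti-conservative (per-term coverage drops to
~89%) — a known hazard of weighting by small-sample variance estimates,
worth keeping in mind when applying it to real triplicate data.
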