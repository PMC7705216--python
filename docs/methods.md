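# Methods

## The model

A listener's categorical loudness perception is described by a
multi-category psychometric function (MCPF): at stimulus level *L* (dB SPL)
the response is one of 11 ordered categories coded in categorical units
CU ∈ {0, 5, …, 50}, from "Can't Hear" (0) to "Too Loud" (50).  The MCPF is
parameterized by 10 ordered boundary psychometric functions

Ψ_k(L) = 1 / (1 + exp(−(L − L_k) / w_k)),  k = 1…10,

where Ψ_k(L) is the probability that the response is at or above CU 5k,
L_k is the boundary's 50% point and w_k its width in dB.  Category
probabilities are differences of adjacent boundaries,
P(CU = 5j | L) = Ψ_j(L) − Ψ_{j+1}(L) with Ψ_0 ≡ 1 and Ψ_11 ≡ 0, which
telescope to an exactly normalized distribution.  The logistic kernel is the
conventional psychometric form; with it the "50% point of each boundary"
rule used to read a CLS function off a fitted MCPF returns `boundary_levels`
exactly.  Non-logistic kernels are deliberately out of scope.

Validity is enforced at construction: strictly increasing boundary levels,
positive widths, and non-negative category probabilities on a 1-dB grid over
the 0–110 dB SPL presentation domain.  Parameter sets violating
non-negativity (crossing boundaries from discordant widths) are rejected
rather than clipped, so normalization never needs repair.

## Bayesian tracking and MEI selection

The hypothesis space is a finite catalog of MCPFs.  The posterior over
entries starts uniform (entropy log₂ N bits) and after each trial (L, c) is
updated by p_i ∝ p_i · P_i(c | L), normalized.  Per-trial likelihoods are
floored at ε = 1e−6 and renormalized over the 11 categories before use.  The
floor prevents a single lapse from permanently zeroing an entry; the
renormalization makes the floored likelihood a proper conditional
distribution, so the expected posterior entropy obeys the "information never
hurts" inequality exactly rather than up to O(ε).  The same floored
likelihood is used by the posterior update, the expected-entropy evaluation
and the maximum-likelihood fit, keeping ML identical to the posterior mode
under a uniform prior.

The MEI rule evaluates, for every admissible candidate level, the
probability-weighted expected entropy over all 11 possible responses
(exact enumeration, not sampling) and presents the level with the lowest
value — i.e. the greatest expected entropy reduction.  Candidates are the
5-dB grid within the current run limits, excluding levels more than 45 dB
from the previous level and (by default) the previous level itself; both
follow the presentation constraints used for the randomized fixed-level
sequences, and whether the repeat rule binds the MEI tracker is exposed as a
flag since the original description states it only for the fixed-level
procedure.  Ties are broken toward the lowest level (comfort/safety; the
choice is otherwise arbitrary), with a 1e−12 tolerance so floating-point
noise cannot flip the argmin.  The candidate set is restricted to the
current dynamic-range limits rather than the full 0–110 grid, consistent
with never presenting into the "Too Loud" region deliberately.

## Procedures

Dynamic-range pre-phase: two interleaved sequences start at 60 dB SPL and
move in 10-dB steps (start level, step size and interleave order are
implementation choices; all configurable).  The ascending sequence stops at
the first "Too Loud" or at 110 dB SPL; the descending one at the first
"Can't Hear" or 0 dB SPL.  Upper end = last ascending level not judged "Too
Loud"; lower end = last audible descending level.  If the start level is
inaudible the first audible ascending level is used for the lower end; if
the start is "Too Loud" the start is stepped down first.  The measurement
stage starts at the midpoint of the range.

Fixed-level: every 5-dB level in the range, 10 repetitions each (≤22 levels,
≤220 trials), ordered by seeded sequential sampling with restarts so that no
level repeats immediately and consecutive levels never differ by more than
45 dB.

Slope-adaptive: 5 runs × 9 trials, the 9 levels evenly spanning the current
limits, presented in seeded random order within each run (order within a run
is not specified by the procedure description).

MEI-adaptive: 5 runs × 9 trials, first level at the range midpoint snapped
to the grid, all later levels from the MEI rule.  The posterior persists
across the 5 runs of a session ("per track" is read as per session).  Nine
*trials* per run are presented; distinct levels are not enforced.

URD: 45 trials drawn uniformly from the 5-dB grid within the current
limits; the uninformed comparison tracker.

All adaptive procedures share the safety rule: any "Too Loud" in a run
lowers the next run's upper limit by 5 dB, a run without one raises it by
5 dB, never beyond 110 dB SPL.  A guard keeps the upper limit at least one
grid step above the lower limit so a run always has a usable span.

## Synthetic catalog and simulated listeners

The original empirical catalog is not redistributable, so the package
generates one.  Each entry draws its CU-5 boundary (threshold-like) from
0–70 dB SPL and its CU-50 boundary from 85–110 dB SPL, rejecting pairs with
a span under 25 dB; interior boundaries are placed on a two-segment
bent line whose knee position (25–60% along the CU axis) and depth scale
with the drawn threshold, so higher-threshold entries show the compressed
dynamic range and rapid near-threshold loudness growth (recruitment) of
sensorineural loss.  Widths are drawn per boundary from 3–8 dB, retried (or
flattened to a common width, which can never cross) if a draw would produce
crossing boundaries.  The default size of 1460 entries matches the scale of
the catalog it stands in for.  All draws flow from a mandatory seed recorded
in the catalog's provenance block.

Simulated listeners hold a true MCPF and draw each response from its
category probabilities with a private seeded stream (`stochastic`), or
return the modal category (`modal`, for deterministic tests).  They are
memoryless: context effects of large level jumps (a known bias in human
CLS data) are not modeled, so simulations probe the tracking machinery, not
sequential response biases.  `perturbed` sampling jitters boundary levels
with Gaussian noise (default SD 3 dB, re-validated) to model listeners
outside the catalog.

## CLS-function estimation

`median_cls` takes the median presented level per used CU (midpoint
convention for even counts, no outlier removal, missing categories stay
missing).  `ml_cls` maximizes the summed floored log-likelihood over catalog
entries (ties to the lowest index) and reads the function off the winning
entry's boundary levels, giving a complete, category-smoothed function.
CU 0 and 50 are carried in the structures but excluded from analysis since
their level sets are unbounded.

CU→phon conversion is a pluggable strictly-monotone anchor table with
linear interpolation; the bundled default (`linear-2phon-per-cu`) is a
generic placeholder scaling, not an empirically fitted loudness-level
function, and every phon-space output is labeled with the map identifier so
a fitted table can be substituted without ambiguity.

Threshold is the level at 2.5 CU from an ordinary least-squares regression
of CU on level over the CU ≤ 20 points (2.5 CU is halfway between "Can't
Hear" and "Very Soft", a 50%-audibility criterion).  With a single such
point its level is returned; with none, the lowest level in the function.

## Statistics and the simulation study

Bland-Altman: bias = mean difference, 95% limits of agreement =
bias ± 1.96 SD, bias CI = bias ± 1.96 SD/√n; normality of the differences is
screened by a Kolmogorov–Smirnov test with estimated mean/SD (a
Lilliefors-style usage — the p-value is a screen deciding whether the
1.96-SD or 2-SD convention is the appropriate annotation, not an exact
test).  Cronbach's α uses the variance decomposition
α = k/(k−1)·(1 − Σvarᵢ/var_total) with sample variances, banded as ≥0.9
excellent, ≥0.8 good, ≥0.7 acceptable, ≥0.6 questionable, ≥0.5 poor, else
unacceptable.  Both are cross-checked in the test suite against independent
textbook recomputation (and α against pingouin).

The Monte-Carlo study draws listeners from the catalog, runs full MEI and
URD sessions per listener (pre-phase included; a repeatedly degenerate
stochastic pre-phase falls back to the full 0–110 dB range), and replays
each session through the Bayes update to record per-trial posterior entropy
and the rmse between the running ML estimate's per-CU levels and the true
listener's over CU 5–45 (the estimator always yields a complete function;
the error domain is recorded in the output metadata).  Curves are averaged
across listeners.  The validated directional claim is entropy only: MEI's
final mean entropy is below URD's.  No direction is asserted for rmse, which
matches the finding that entropy reduction does not automatically translate
into more accurate CLS functions when the catalog's predictive power is the
limiting factor.

Default study size is 200 listeners on the full 1460-entry catalog
(≈1.5 min on one core); the bundled examples use smaller rosters purely for
brevity.

## Numerical and testing notes

- Entropy uses the 0·log 0 ≡ 0 convention; expected entropy is computed in
  the closed form −Σ w log₂ w + Σ s log₂ s over joint weights w and their
  response marginals s.
- MEI selection is exactly equivalent to a brute-force double loop over
  candidates × responses; the suite asserts equality on 100 random small
  catalogs.
- Parameter-recovery guarantees hold for *well-separated* catalogs: with
  modal responses, a catalog containing near-duplicate entries that differ
  mainly in boundary widths can legitimately rank a sharper near-duplicate
  above the generator, so the 100%-recovery check runs on a structured
  catalog with 3-dB-spaced thresholds and a common width.  The stochastic
  recovery rate is reported, not gated (≈0.9 under those conditions).
- Determinism: every stochastic component (catalog generation, listener
  sampling and responses, presentation orders, URD draws) is driven by an
  explicit seed; identical seeds give byte-identical outputs.

## Known limitations

- The synthetic catalog reproduces the population *structure* (threshold
  spread, compressed dynamic ranges, recruitment-like knees), not the
  empirical joint distribution of any human cohort; statistics computed on
  simulated sessions therefore validate the machinery, not human numbers.
- Listeners are memoryless; sequential bias from large level transitions is
  acknowledged but unmodeled.
- The default phon map is a labeled placeholder; quantitative phon-space
  claims require supplying a fitted conversion.
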