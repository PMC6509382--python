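# Methods

This note records the scientific conventions, defaults and numerical
choices behind each stage of the pipeline, and what the synthetic
validation experiments do and do not establish.

## Telemetry screening and seasons

Input fixes are planar projected coordinates in metres (projection happens
upstream; all distances are Euclidean). Screening is a two-rule filter:
(1) a *spike* rule removing single fixes that imply an out-and-back
excursion — both adjacent steps longer than `max_step` (default 10,000 m)
with the flanking fixes within `max_step` of each other; then (2) a
sequential *speed* rule removing fixes implying more than `max_speed`
(default 15,000 m/hr) relative to the previous retained fix. The spike
pass runs first so a teleport-and-return costs one fix, not two. The
defaults are deliberately permissive — the filter targets gross
positional errors, not behaviour — and both thresholds are configurable.
Screening is idempotent on its own output.

Seasons are fixed calendar windows with inclusive endpoints: winter
15 Jan–3 Mar and summer 15 Jul–1 Sep. Taken inclusively the printed dates
give a 48-day winter (non-leap years) and a 49-day summer; we follow the
dates rather than forcing both windows to an equal day count. Fixes
outside both windows are discarded; the year key is the calendar year
containing the window.

## Rounds

Association analysis needs "simultaneous" fixes. Rounds anchor on the
whole hour: a fix joins the round of its nearest hour if it is within the
5-min tolerance; off-schedule fixes are greedily clustered among
themselves (the earliest fix anchors a cluster). Hour anchoring
accommodates mixed 1-hr and 2-hr collar schedules without ever merging
distinct schedule points; two fixes 8 min apart never share a round. If
an animal contributes two fixes to one round the fix nearer the anchor is
kept.

## Social networks

Within a round, group membership is the transitive closure of the
pairwise "within 50 m" relation (the chain rule); the association
distance is configurable. The dyadic weight is the simple ratio index
over rounds in which at least one member of the dyad appears. Note the
bookkeeping consequence: a dyad in which only one animal was ever
observed has a positive denominator (`y_A > 0`) and hence an explicit
SRI = 0 edge, whereas a dyad with no observations at all has an undefined
index and no edge. Keeping the distinction preserves strength sums and
makes "never seen together" distinguishable from "never sampled".

The network builder vectorizes all rounds into one sparse
connected-components pass (each round an isolated block of a larger
graph); a brute-force BFS + counting oracle in the test suite checks it
exactly, including float-identical SRI values.

## Home ranges and overlap

Utilization distributions are fixed-kernel estimates with an isotropic
bivariate normal kernel and the reference bandwidth
`h = σ·n^(−1/6)`, `σ² = (var(x)+var(y))/2` (sample variances), the
convention of the kernel home-range literature. A minimum of 5 fixes is
required; coincident-fix groups (σ = 0) are excluded. The evaluation grid
defaults to cell size `h/4` with a `3h` margin around the bounding box;
estimation fails loudly if more than 1 % of kernel mass falls outside the
grid. Within a herd-season-year all animals share one grid (with the
largest individual bandwidth setting the resolution) so pairwise overlap
needs no resampling; cross-year fidelity re-estimates the two years'
distributions on a joint grid. Fix order is canonicalized before
estimation so results are bit-identical under row reordering — this is
what makes the permutation-invariance checks exact.

The 95 % home range is the smallest set of highest-density cells holding
95 % of the mass; its area is the cell count times cell area. UDOI is
computed by default from distributions conditioned on (restricted to and
renormalized over) their 95 % home ranges, with the intersection-area
term taken over the two home ranges; this keeps the calibration property
that identical uniform distributions give exactly 1. A full-grid variant
(`level=None`, home range = support) is available; on smooth
distributions halving the cell size moves UDOI by well under 5 %.

Site fidelity uses consecutive year pairs only (year Y vs Y+1, same
season); non-consecutive pairs are not counted, so a gap year simply
yields no record.

## Permutation null

The null reorders each animal's calendar days uniformly at random within
a season-year, preserving within-day order and times of day. Day blocks
are calendar dates; partial days at window edges are blocks like any
other. This conserves each animal's full spatial distribution — the test
suite asserts the per-animal (time-of-day, x, y) multiset and every
spatial-network strength are *exactly* unchanged — while erasing
cross-animal temporal alignment. Each herd-season-year network draws its
permutations from its own deterministic substream (master seed + a CRC of
the network key), so ensembles are reproducible and insensitive to
network iteration order. The ensemble's fast path re-derives round
membership from (permuted day, time-of-day) indices; a test verifies it
against explicitly shuffling timestamps and rebuilding from scratch.

Coefficient nulls refit the seasonal strength model to every iteration's
strengths. The log offset is computed once from the pooled observed and
null strengths (falling back to 1.0 in the degenerate no-association
case) so coefficients are comparable across iterations. An observed
coefficient is flagged nonrandom when it falls outside the empirical
2.5–97.5 percentile interval of the draws.

## Mixed models

All responses are log-transformed with an offset of half the smallest
positive value of that response (strengths and overlap indices can be
exactly zero; the offset is scale-respecting and configurable). The four
models share the structure: season fixed; random intercepts for herd,
animal-within-herd, and year (the year *pair* for the fidelity model);
Gaussian REML. Random effects enter as variance components over a single
trivial group, the crossed-random-effects formulation. p-values use the
normal approximation to the Wald t (labelled `t-as-z`); no
denominator-degrees-of-freedom approximation is attempted.

Variance components in these designs routinely sit on the zero boundary.
When the REML profile is singular the offending component is
unidentifiable; the fitter drops components progressively and, at the
limit, falls back to OLS — which is the exact boundary solution with all
random-effect variances at zero — rather than failing. Per-iteration
null fits are dropped only when no finite estimates exist at all; the
ensemble errors if fewer than 95 % of iterations yield a fit.

The social-strength model pairs each animal-season-year's observed
strength with that animal's null-mean strength and tests the
season × source interaction; the home-range-area model adds observed
social strength (log) as a covariate. Animals with any summer home range
over 4,000 km² are removed from *all* analyses before modelling.

## Synthetic data

The generator's purpose is to produce telemetry with the statistical
structure the analysis assumes, under experimenter control. Movement is a
biased correlated random walk: per scheduled fix, step length ~
Gamma(shape 2, mean `step_scale`) and heading ~ von Mises around the
direction of a weighted target mixing the seasonal range centre
(weight 1), the nearest resource patch (`patch_attraction`), and the
nearest conspecific's current position (`social_attraction`), the minimal
mechanism that yields chain-rule groups. Landscapes are square with
uniformly placed disc patches; `patch_count = 0` encodes the homogeneous
(summer-like) case. Interannual fidelity is the probability of keeping
last year's range centre versus drawing a fresh one uniformly.

Defaults encode the seasonal contrast of the study system: a 10 km
landscape per herd, 10 animals per herd, 2-hr fixes, `step_scale` 250 m
(a few hundred metres per 2-hr interval, typical of a foraging ungulate),
turning concentration κ = 4; winter is patchy (15 patches of 100 m
radius) with `social_attraction` 2 and fidelity 0.1, summer homogeneous,
socially independent, fidelity 0.9. Herds occupy disjoint landscapes and
are simulated independently. Agents of one herd-season are stepped
synchronously from a single per-herd substream (conspecific attraction
couples them within a time step), with substreams spawned deterministically
from the master seed, so every dataset is bit-reproducible.

What the generator does *not* emulate: real landscapes (rasters,
barriers, snow dynamics), behavioural states, calf constraints,
collar-error distributions, or density feedback. Passing the validation
experiments therefore shows the *pipeline* recovers planted structure of
the kind the analysis assumes; it does not validate the ecological model
itself against field data.

## Validation experiment sizes

The calibration experiment uses 3 herds × 10 socially independent agents
over one 48-day winter of 2-hr fixes, 200 shuffles, 20 seeds, and checks
that observed strength falls inside the null 95 % band for 95 ± 5 % of
animals (quantile ties count as inside; with sparse proximity many
null distributions are degenerate at zero, which is itself the correct
null behaviour for low-density, independent movement). The effect-recovery
experiment uses 2 herds × 8 agents × 2 years with 100 shuffles per seed
and requires, in at least 8 of 10 seeds: a negative winter fidelity
coefficient, positive winter spatial- and social-strength coefficients,
and an observed social season coefficient outside the null CI — and, in
the attraction-free control, inside it. These sizes keep the full
validation suite to a few minutes while leaving each check comfortably
powered.
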