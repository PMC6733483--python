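# Methods

## Data model and conventions

All timestamps are stored timezone-naive UTC. The calendar day of a
detection — the unit of every residence index — is computed in a
configurable local offset (default UTC+3, suiting a Red Sea site); the
day-boundary convention matters at the margins because a detection at
21:30 UTC falls on the next local day. All intervals are half-open
`[start, end)`: a detection exactly at a deployment's end, or at a
receiver recovery time, is outside. Argos quality tokens `0–3` are
stored as `C0–C3` so classes are never mistaken for counts.

Retagged animals are merged under one animal id; analyses are per
animal, never per tag. Day spans are inclusive of both endpoints, so an
animal tagged and detected on one day has a one-day monitoring period
and R_max = 1; this convention shifts indices by O(1/days) relative to
the exclusive alternative and is applied uniformly.

## Quality control

Receiver clock drift is modeled as linear: zero offset at
initialization, growing to the offset measured at download. The
correction subtracts the interpolated offset; inverting an emitted
(drifted) timestamp this way leaves a residual of order
offset²/deployment-span — microseconds for realistic offsets. Detections
outside every calibration interval pass through unchanged with a
warning rather than being silently shifted or dropped.

The post-tagging exclusion window (default 24 h, configurable) is
half-open per tagging event: a retagged animal gets a fresh window for
the new tag only. Tag-loss truncation applies when an animal is later
resighted without its tag or found dead: the deployment is ended one
second after the last recorded detection array-wide (one second, not
zero, so the final detection itself survives the half-open deployment
filter). Every stage reports input/retained/dropped counts; the QC
chain is idempotent and each stage's output is a subset of its input.

## Effort

A station-day is active if any part of the day intersects an active
interval (any-overlap rule — the simplest auditable convention; a
majority-coverage rule would differ only on deployment/recovery days).
The effort table is a pure function of station metadata. For the
occupancy models, stations map onto two effort covariates — active
inshore-side and offshore-side receiver counts per day — via a
config-driven region grouping whose default treats only the
offshore-reef region as "offshore".

## Residence indices

R_min divides detected days by days from tagging to study end (the
maximum possible monitoring period), R_max by days from tagging to last
detection (the minimum). R_max is reported missing, not zero, for
never-detected animals: its denominator does not exist, and coding it
as 0 would conflate "never detected" with "present throughout". Both
indices are always computed together, since either alone is biased —
R_min by tag loss, R_max by survivorship of the detection record. If a
detection's local date falls just past the nominal study end (a
boundary effect of the local-day offset), the maximum monitoring period
is extended to cover it so R_min ≤ R_max always holds.

R_spatial excludes from a station's denominator the array-detection
days on which that station was inactive — the animal could not have
been heard there — and is undefined when no array-detection day
overlaps the station's active days.

Mann–Whitney comparisons are two-sided. For small problems
(n₁·n₂ ≤ 400) the p-value comes from the exact null distribution: the
tie-free counting distribution when all values are distinct, full
enumeration of group relabelings when there are ties and the number of
relabelings is tractable (≤ 2·10⁵). All-tied data yield p = 1 by
symmetry. Larger problems use the tie-corrected normal approximation.
Bonferroni division is the default multiplicity control to match
standard practice in station-wise telemetry comparisons.

## Occupancy models

Histories are cut into 42-day bins anchored at the study start; the
final partial bin is kept and flagged. Week-of-year is real-valued at
the bin midpoint with period 52; lag is days from the animal's first
capture to the bin midpoint, a monotone per-animal covariate. Effort
covariates are bin means (receiver counts) or bin sums (survey
effort-units).

The model is a penalized binomial additive model fitted by penalized
IRLS (statsmodels `GLMGam`): a cyclic cubic spline over week-of-year
(basis dimension 10, anchored on the full 0–52 period so the
value-and-slope boundary constraint applies regardless of the data
span), a cubic B-spline over lag (dimension 8, reduced when lag has few
distinct values), and ridge-penalized group intercepts for animal id
and first-capture cohort — the penalized-likelihood representation of
Gaussian random intercepts. Both spline bases carry sum-to-zero
centering constraints; without them the cyclic basis is confounded with
the intercept and the penalized fit is singular. The B-spline penalty's
null space is linear, so an infinitely penalized lag term is a straight
line, not a constant.

Penalty weights for the four penalized blocks are chosen by
deterministic coordinate-wise search over a log-spaced grid
(10⁻², 1, 10², 10⁴), minimizing the effective-degrees-of-freedom AIC,
two sweeps. The search runs once on the fullest candidate and the
selected weights are shared across the candidate set: the penalized
blocks are identical in every candidate — only unpenalized linear terms
differ — which keeps AIC comparisons consistent and the sweep cheap.
Degenerate fits (quasi-separation driving |AIC| or the effective
degrees of freedom to absurd values) are flagged non-converged; on a
perfect-separation error the fit is retried with penalties stiffened
100-fold before giving up. An all-zero (or all-one) outcome vector gets
a closed-form intercept-only fit with a Haldane-corrected logit.

Candidates are every subset of the dataset's linear terms — 2⁴ = 16
acoustic (size, sex, inshore effort, offshore effort), 2³ = 8 visual
(size, sex, survey effort) — with the smooths and random effects always
present. Selection is minimum AIC; ties break toward fewer linear
terms, then lexical order. Sex is encoded with an explicit
undetermined level so unsexed animals are never dropped. Recapture
curves set random effects to zero (population-typical animal), clip lag
into the fitted range to avoid spline extrapolation, and are strictly
inside (0, 1) by construction.

## Track fusion and behavior rules

The speed filter is the greedy forward pass: walk the time-sorted
series keeping a point only if the great-circle speed from the last
kept point is ≤ 4 m/s (first point always kept). It is deterministic,
idempotent and order-preserving; the full backward-forward filter of
Austin/McConnell style is deliberately out of scope but pluggable.
Distances use the haversine formula on a 6371 km sphere.

Acoustic pseudo-positions are placed at the centroid of the stations
heard that day and time-stamped local noon; visual encounters likewise
at the survey site. Same-instant duplicates collapse to the more
accurate class. The behavior classifier is a total rule set over the
fused track: displacement never ≥ 100 km → local-only; basin exit with
no later home evidence → emigrant-left-basin; otherwise counted by the
calendar years after the first departure year with home evidence
(≥ 2 → multi-year return, 1 → interannual return, same-year only →
excursion-return, none → emigrant). The 100 km "local" radius sits
between the observed near-site wandering scale (tens of km) and
genuine migrations (hundreds to thousands of km); "home evidence" is
any filtered position, detection-day or encounter within that radius.

## Simulator

Presence follows a von-Mises-shaped annual cycle,
P(at site) = p_peak · exp(κ(cos θ − 1)) with θ the angular distance of
the week from the peak week — κ = 0 gives uniform year-round presence,
the default κ = 4 with peak week 14 concentrates presence in boreal
spring. Defaults mirror the emulated study design: 63 stations in seven
regions (six exposed-side stations reconcile the region counts with the
stated array total), ~85 animals tagged in spring of the first five
study years, six study years, 540 m / 230 m nominal ranges,
Uniform(60, 180) s transmitter delays, 1% daily outage rate, 0.002
daily tag-loss hazard, weekly spring surveys, class-stratified Argos
noise with 8% class-Z junk.

Detection is binomially thinned per transmission with a logistic
distance curve calibrated so P(detect) = 0.5 exactly at the nominal
range (e-folding scale 150 m). A present animal occupies its daily
position for 2 h of transmissions — without this duty cycle an animal
parked inside the station cluster logs thousands of detections per day,
an order of magnitude beyond realistic array totals; the per-
transmission probability itself is untouched. Scripted behaviors place
each animal's site years and off-season latitude trajectory so that
every behavior label is recoverable from its emitted data: off-site
years keep dispersers several hundred km away so they generate no
spurious return evidence. One global seed spawns independent substreams
(array, animals, presence, detections, outages, Argos, surveys, clocks,
tag loss), so output files are byte-identical across runs and a single
component can be regenerated alone.

What the simulator does not emulate: water-column and weather effects
on detection range, within-day movement (one position per day plus the
duty cycle), photo-identification error (encounters are exact),
Argos serial correlation, and coastline geometry (no land mask is
bundled). Passing tests therefore certify the pipeline's arithmetic
and inferential machinery on data whose structure matches the study
design, not the field behavior of any real array.

## Problem sizes used in tests

The shared test scenario uses 12 animals over 2 years; the index
bracket property runs on 85 animals over 6 years; seasonal-recovery
checks fit 50 animals over 4 years (≈ 1 200 animal-bins, fits in well
under a minute); Mann–Whitney calibration uses 1 000 null replicates of
12 vs 12. These sizes were chosen as the smallest at which the checked
effects are comfortably identified.
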