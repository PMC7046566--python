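# Methods

## Case definition and deduplication

A hip fracture is an admission coded ICD-10 S72.0 (femoral neck), S72.1
(pertrochanteric) or S72.2 (subtrochanteric); any other code is rejected
at parse time with a reason code, as are rows with unparseable dates,
unknown sex labels or admissions outside the observation window. "Same
fracture site" is operationalised as an identical ICD-10 code for the
same patient — the three codes are the only site information a registry
extract of this kind carries. The exclusion window is 90 days
(configurable); "three months" has no canonical day count, and 90 is
the convention adopted here. The window rolls forward from the most
recently *retained* admission: in a readmission chain at days 0 / 60 /
130, day 60 is dropped (within 90 d of day 0) and day 130 is retained
(more than 90 d after the retained day 0). The alternative — measuring
from the last admission, retained or not — would let an arbitrarily
long chain of readmissions collapse into a single fracture. Deduplication
is idempotent and invariant to input order; output order is
deterministic by (patient, date, code).

Age at admission assigns the 5-year band (40–44 … 85–89, 90+); patients
aging across a band boundary mid-study are banded per admission, because
admission-time age is what registry extracts carry. Non-residents are
not filtered out.

## Denominators

Only insured individuals can appear in an insurance-fund registry, so
person-years are `population × coverage_fraction × years_observed` per
stratum, with coverage free to vary by age and sex. The packaged
catchment table's "person_years" column is the coverage-corrected
population summed over the three observation years; the arithmetic of
the published rates (367 / 219,107 × 10⁵ ≈ 167) only works under that
person-years reading, which is why the column is labelled explicitly.
The printed per-stratum person-years sum to 219,107 (men) and 273,017
(women), one unit off the published aggregate rows (219,106 / 273,018,
a print-rounding artefact); the packaged data keep the per-stratum
values and recompute aggregates from them.

## Incidence and intervals

Rates are events/PY × 10⁵, Poisson-modelled. The interval is the
Garwood exact chi-square interval (conservative: true coverage ≥ the
nominal level, approaching it as counts grow). The source table never
names its interval method; Garwood was adopted because it reproduces the
published bounds at both a large count (367 events: 151–186) and a small
one (83 events: 2310–3595), which a Wald/normal approximation does not.
This is the single most consequential reverse-engineering choice in the
package. One published cell (men 90+, upper bound) computes to 2671
against a printed 2672 — last-digit rounding in the source.

Rounding is confined to the report layer (half-up to integers for rates
and bounds, one decimal for ratios); serialised tables carry full
precision and round-trip exactly. The female/male summary ratio is
reported in two labelled variants — count ratio and pooled rate ratio —
because they genuinely differ when the sexes' person-years differ, and
published summary ratios of this kind do not always say which was used
(the below-65 published value matches the rate ratio; the 65+ value
matches neither variant, and no agreement is forced).

## Hazard curves

Incidence converts to hazards by rate/10⁵; within-band hazards are
constant (no smoothing), matching the 5-year resolution of the data.
The open 90+ band is extended as a constant to a terminal age of 110,
which bounds lifetime integrals at negligible cost — survival beyond
110 under any realistic mortality is vanishing. Life tables are read
either as mx-style hazards (used verbatim) or qx-style per-band death
probabilities (converted by h = −ln(1−qx)/Δ; qx ≥ 1 outside the
terminal band is fatal). Major-osteoporotic-fracture hazards are a
segment-wise product of hip hazards with a user-supplied MOF:hip ratio
table by sex and band; ratio values are an input (the customary
Swedish ratio surface is not redistributable here), and only positivity
is enforced — at younger ages forearm fractures outnumber hip fractures
many-fold, so ratios below or above 1 are both legitimate.

## First-fracture probability

The competing-risk integral is evaluated in closed form over the
piecewise-constant segments (formula in the README). Start ages off a
band boundary pro-rate the first segment. The zero-hazard case
f + d = 0 contributes exactly zero mass with survival unchanged. The
result object decomposes the probability by age interval and reports
the no-event survival at horizon; `probability + survival ≤ 1`, the
remainder being death before fracture. An independent Monte-Carlo
simulator (per-segment competing exponential waiting times, Bernoulli
split f/(f+d) for event type) serves as the arbiter of correctness; the
closed form agrees within three standard errors at 2×10⁵ trajectories
across a 50-case random battery, and the mortality-free limit equals
1 − exp(−∫f) to 10⁻¹².

Clinical-risk-factor machinery (FRAX beta coefficients, prior-fracture
and BMI conditioning, post-fracture mortality excess) is out of scope:
those coefficients are proprietary and unpublished, so probabilities
here describe a reference individual of given age and sex. Published
10-year probability tables conditioned on prior fracture are therefore
not recomputable from this package, by design.

## Burden projection

Expected counts apply annual stratum rates to a pyramid slice;
projection across years assumes age- and sex-specific rates stay
stable, the standard planning assumption. Scope defaults to 50+
(configurable). The engine is exactly linear in rates and population,
and percent increases are invariant to uniform rate rescaling — the
properties the tests pin down. No uncertainty propagation from the rate
intervals is attempted (none is conventionally reported for such
projections); a bootstrap would be the natural extension. Secular-trend
scenarios are deliberately not modelled.

## Synthetic data: what it emulates and what it does not

The generator draws stratum counts as Poisson at
`true_rate × population × coverage × years`, scatters admissions
uniformly over the window, assigns uniform ages within band and uniform
hip codes, and injects same-code readmissions 10–80 days after a
fraction (default 5%) of records — inside the 90-day window by
construction, so deduplication must remove them exactly, every seed.
Default true rates are calibrated to the packaged catchment surveillance
so magnitudes are realistic; this is calibration, not a national truth
claim. Default coverage rises gently with age around the ≈0.81 overall
level. Mortality is Gompertz–Makeham h(x) = a + b·cˣ with defaults
calibrated to mid-2010s South-East-European life expectancy at birth
(women ≈78 y: a = 3×10⁻⁴, b = 1.55×10⁻⁵, c = 1.11; men ≈71 y:
a = 9×10⁻⁴, b = 4.85×10⁻⁵, c = 1.10), evaluated at band midpoints.
Pyramids drift geometrically per band (default: +1%/yr at 70+,
−0.5%/yr below) to emulate an aging medium-variant projection.

Real registries additionally contain coding errors, transfer
readmissions across facilities, residence churn and coverage that
varies in time; none of that is modelled. Passing parameter-recovery
tests therefore demonstrates the estimator chain is correct under the
stated sampling model, not that any particular registry is accurate.
All generators are pure functions of (truth bundle, seed) with named
substreams, so regeneration is byte-identical.

## Problem sizes and numerical choices

The interval-coverage check pools 500 replicates × 22 strata (pooled
Garwood coverage at the calibrated means is analytically ≈0.960, so the
[0.93, 0.97] band is a stable target at this replication). The
Monte-Carlo battery uses 50 random curve/age/horizon cases at 2×10⁵
trajectories, the size at which 3 standard errors resolves ≈0.3% of
probability. Chi-square quantiles come from scipy; the test suite
cross-checks them against an independent bisection on the regularized
incomplete gamma. Ties and degenerate inputs: zero events give a zero
lower bound exactly; zero total hazard contributes zero probability
mass; empty strata render as zeros, not blanks.

## Known limitations

Catchment-to-country extrapolation is an assumption the package cannot
test; registry completeness (non-hospitalised fractures) is outside the
data; lifetime probabilities depend on the mortality table supplied and
the packaged fixture is a two-parameter-family approximation, not an
official national life table; MOF imputation inherits whatever ratio
surface the user supplies.
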