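# Methods

## Growth model

Tumours (primary and metastatic) are spheres of identical 10 µm cells
growing exponentially in volume: `V(t) = V₀ · 2^(t/TVDT)`, equivalently
`d(t) = d₀ · 2^(t/(3·TVDT))` in diameter, where TVDT is the tumour
volume doubling time in days. The model is deliberately purely
exponential: a linear-phase coefficient θ is carried in the constants
block for completeness but never activated, because every published
worked value this package reproduces follows from the exponential
regime alone. Gompertzian deceleration at large volumes, non-spherical
geometry and treatment effects on kinetics are out of scope.

The doubling number of a sphere of diameter *d* is
`N(d) = 3·log₂(d/0.01 mm)`; a diameter doubling is exactly three volume
doublings. The Schwartz two-exam estimator
`TVDT = Δt / (3·log₂(d₂/d₁))` is the exact inverse of the growth law, a
property enforced to 1e-9 relative error by tests.

## Kinetic anchors and the seeding-constant pair

| constant | default | meaning |
|---|---|---|
| cell diameter | 0.01 mm | a single tumour cell |
| PT seeding diameter | 1.0 mm | PT size at which metastatic seeding begins (N ≈ 19.932) |
| seeding doubling index | 20 | PT doubling at which the first metastatic cell appears |
| MTS detection diameter | 9.0 mm | clinical detectability threshold of a metastasis (N ≈ 29.441) |
| lethal doubling count | 40 | lethal burden, 2⁴⁰ ≈ 1.1 × 10¹² cells (≈ 102 mm sphere) |
| whole-history doublings | 60 | 20 + 40; closes the natural-history budget |
| days per year | 365.25 | all day↔year conversions |

Two near-equal seeding constants coexist on purpose. The pre-surgery
latency (non-visible MTS-I) is anchored at the PT's exact 1 mm doubling
count, 19.932; the post-surgery latency (non-visible MTS-II) at the
integer index 20. This is the unique pair that reproduces the published
2-decimal period cells simultaneously (e.g. 4.34 y = 11.750·135/365.25
needs 19.932, while 6.56 y = 17.760·135/365.25 needs 20); both live in
`ModelConstants` as table-parity values. Swapping either breaks the
other set of cells, so neither is a free parameter.

The detection diameter is 9 mm for metastases even though the PT's own
visibility is described elsewhere as 1–5 mm; the PT visibility threshold
enters no computed quantity and is not stored.

The 60-doubling identity `N_pt + [N(9) − (N_pt − 20)] + [40 − N(9)] = 60`
cancels algebraically in `N_pt`, and the test suite asserts it to 1e-9
for random diameters — it is an internal consistency check, not an
empirical claim.

## Scenarios and diagnostic columns

Per TVDT band `[T_min, T_max]` two bracketing scenarios are computed for
a PT resected at `d_pt`:

* **earliest** — the lesion is already 1 mm at surgery and grows at
  `T_min`: MTS-II = (N(9) − 19.932)·T_min;
* **latest** — a single cell seeded at the PT's 20th doubling grows at
  `T_max`: MTS-II = (N(9) − (N_pt − 20))·T_max.

The **seeded-at-surgery window** spreads MTS-II at fixed TVDT between
those seeding assumptions; its width `(N_pt − 19.932)·T` is the "(+)"
extension of the diagnosis period.

A **diagnostic column** for a PT subtype chains, fastest first, the
rapid band's full window, each slower band's latest-scenario window up
to the PT's own band, and (except for the slowest subtype, whose own
band needs no extension) one "(+)" window at the PT band's maximum
TVDT. Diagnosis periods are successive differences of window upper
ends; their sum is the considered-healthy horizon.

Two chaining modes: **unrounded** (default; full precision throughout,
rounding half-up to 2 decimals only at presentation) and
**printed-parity** (endpoints rounded to 2 decimals before differencing
and summing). The published totals are sums of rounded cells, so parity
mode reproduces them digit for digit (10.64/13.07/15.49/18.32/12.87 y
for the 15.1 mm case) while unrounded totals differ by under 0.01 y.
Two display quirks are accepted rather than modelled: the same quantity
can round differently in adjacent published rows (6.56 vs 6.57), and the
"(+)" rows' MTS-I/visible upper cells follow no constant set derivable
from the model — they are carried as stored display strings, rendered
only in printed-parity mode and flagged unreconstructed in the source.

## Subtype bands and classification

The five bands (triple-negative V through luminal A I) ship as a YAML
registry inside the package, overridable per run. Band edges are closed
integer-day intervals partitioning [10, 270]; real-valued TVDTs are
rounded to the nearest day before lookup, since the bands are only ever
stated in whole days. TVDTs in (270, 310] are inside the model's
validity range but slower than every band: they map to band I with a
warning. Receptor classification (HR/HER2/Ki-67 with the 14% Ki-67
cutoff) is total over all combinations; triple-negative with Ki-67 < 14
has no dedicated group and is assigned to V with a warning. When a
measured TVDT and receptor status disagree, the measured kinetics win
and the mismatch is reported (an optional strict mode errors instead) —
the kinetics, not the immunophenotype, drive the schedule.

The per-band mean metastasis TVDT ranges are the integer intervals
inside half the display band, i.e. (ceil(lo/2), floor(hi/2)) —
metastases may grow up to about twice as fast as the PT.

## Screening schedules

Each chained window becomes a schedule entry at its band's screening
interval (3/5/6/8/12 months; a "(+)" window inherits the interval of the
next slower band's block, where the published layout places it; a prose
variant uses 9 months for band I). Exams start at the window opening and
step by whole calendar months (month arithmetic clamped to month ends),
staying inside the window — the residual gap to the window end is always
under one interval and the next window's first exam closes it. An
exact-day stepping mode (30.44 d/month) is available. The
considered-healthy date is the surgery date plus the column total at
365.25 d/y, rounded to the day. Exports: JSON, CSV records, RFC 5545
iCalendar.

## Synthetic cohorts

The generator emulates the study conditions end to end: per record a
band drawn uniformly, a TVDT uniform within the band's PT range, a first
diameter uniform in [5, 15] mm, an inter-exam gap uniform in [60, 365]
days, a second diameter given by the growth law times multiplicative
lognormal noise (σ = 0.05 by default — a package choice typical of
caliper/ultrasound sizing, not a literature value), and receptor status
consistent with the band. Everything is reproducible under a fixed seed.

What passing tests show: with σ = 0 the estimator recovers the drawn
TVDT to machine precision and band classification returns the drawn band
whenever the TVDT is at least a day from a band edge. With σ = 0.05 the
TVDT sampling error `≈ σ·3/ln2 · TVDT²/Δt` often exceeds the 30–40 day
width of the slow bands at short exam gaps, so band recovery is limited
by design of the sampling scheme, not by the estimator: the measured
rate at n = 500, seed 42 is 245/500 with 40 records whose noisy growth
is non-positive or out of range, frozen as a regression value. What the
generator does not emulate: reader-dependent measurement bias,
non-exponential growth, inter-metastasis seeding, dormancy, or
treatment-altered kinetics — so passing tests validate the calculator
chain, not clinical performance.

## Numerical choices

Rounding is half-up (decimal, not banker's) at 2 decimals, applied only
at presentation or in printed-parity chaining. TVDT validity is
[10, 310] days; values within one part in 10⁹ of a bound are snapped
onto it so that round-tripping a boundary rate through the estimator
cannot fail on a float ulp. Degenerate inputs raise typed errors:
non-growing or same-day exam pairs (`EstimationError`), diameters below
one cell or PTs below the seeding size (`DomainError`), TVDTs outside
validity (`OutOfModelError`); malformed I/O rows are collected with
line numbers while valid rows proceed. A band whose minimum equals its
maximum still yields both scenarios (they differ only in the seeding
assumption).

## Problem sizes

Default verification sizes: 1,000 random (d_pt, TVDT) pairs for the
day-stepped threshold-crossing oracle, 100 diameters for the 60-doubling
identity, 500-record noisy and 200-record noiseless cohorts, 100
round-trip pairs — all chosen so the whole suite runs in seconds while
exercising every band and scenario branch.

## Known limitations

T4 tumours are outside the model. TVDT_MTS is assumed equal to the
band's TVDT_PT bounds rather than separately measured per lesion.
Guideline visits (ESMO/ASCO/NCCN) are not merged into the personalised
plan. The "(+)" rows' visible-period upper cells are display-only (see
above). Multi-lesion cases are handled by running the calculator per
lesion TVDT, not by a joint model.
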