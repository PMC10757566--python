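# Methods

`aneushear` implements the analysis layer that sits downstream of a 3D
hemodynamic solve of a cerebral aneurysm: physiological outlet boundary
conditions (three-element Windkessel, tuned to clinical pressure targets),
wall-shear-stress postprocessing on labeled surface meshes, a
mesh-convergence protocol, and matched-pair nonparametric statistics. The 3D
Navier–Stokes solve itself is out of scope; a synthetic-data generator with
analytically known ground truth stands in for imaging-derived geometry and
CFD solutions, so every stage can be verified end to end.

All internal quantities are CGS (cm, s, dyne, barye); mmHg and mm appear only
at interfaces with the fixed conversion 1 mmHg = 1333.22 barye.

## Windkessel (RCR) outlet model

Each outlet is a proximal resistance `R_p` in series with a parallel
compliance `C` / distal resistance `R_d` pair draining to a reference
pressure `P_ref` (default 0, configurable):

    C dP_c/dt = Q(t) − (P_c − P_ref)/R_d,      P(t) = P_c + R_p Q(t)

The literature this pipeline follows specifies the RCR circuit but not the
ODE; the standard three-element closure above is adopted. Total resistance is
split over outlets inversely to their areas, `R_i = R_total·A_total/A_i`,
which preserves the parallel combination identically; the proximal:distal
ratio is fixed at 1:9 (`proximal_fraction = 0.1`). Total compliance is
distributed proportionally to `1/R_i`, so all outlets share one time constant
and the multi-outlet set reduces *exactly* to a single equivalent RCR — the
reduction used both for simulation and tuning, since only global inlet
pressures are targeted.

Integration uses an adaptive stiff-capable solver (LSODA) with maximum step
`T/200` (default `T/400`) and a dense uniform sampling of 400 points per
cycle from which per-cycle systolic/diastolic values are read. The initial
compliance pressure is set to the mean-flow steady state `Q̄·R_d + P_ref`,
which shortens the transient without affecting the limit cycle. A *limit
cycle* is declared when systolic and diastolic each change by ≤ 5% (default)
between the last two cycles.

**Tuning.** Targets are systolic 120 and diastolic 80 mmHg within 5%
(defaults). Two facts decouple the problem: (i) over a closed cycle the
compliance stores no net volume, so the cycle-mean pressure is exactly
`Q̄·(R_p+R_d) + P_ref` independent of `C`; (ii) pulse pressure is a monotone
decreasing function of `C` at fixed resistance. The tuner therefore
alternates a mean-pressure update of `R_total` against the proxy
`(systolic + 2·diastolic)/3` with a secant step on `log C` against the pulse
pressure, starting `C` from the closed-form sinusoidal impedance
`|R_p + R_d/(1 + iωR_dC)|` evaluated at the fundamental harmonic. On the
default waveform this converges in 2–3 iterations; each iteration is recorded
in an audit log. A waveform with zero pulsatility makes any nonzero pulse
target unreachable and raises a tuning-infeasibility error. The tuner is
fully deterministic. Which pressure node (inlet vs outlet) the clinical
targets refer to is not specified upstream; the lumped inlet-equivalent node
is used.

## Wall-shear metrics

Per point over one cycle of period `T`:

    TAWSS = (1/T) ∫₀ᵀ |WSS(t)| dt
    OSI   = ½ (1 − |∫₀ᵀ WSS dt| / ∫₀ᵀ |WSS| dt)

Time integration is trapezoid on the stored (possibly non-uniform) grid;
where `∫|WSS|dt = 0` the OSI is defined as 0. Region summaries are
area-weighted over triangles: a triangle's area comes from the cross-product
formula, its field value is the mean of its three vertex values, and its
region is the majority vote of its vertex labels (ties resolve to parent, so
ambiguous seam triangles favor the reference region). Minima and maxima are
taken over region points. Whether spatial means should be area-weighted or
plain vertex averages was an open choice; area weighting was adopted because
it is mesh-density independent.

Low-shear metrics are dome-area percentages under strict `<` thresholds
(ties are not low; measure-zero on continuous fields):

- `MTLSA_X` — dome area fraction with TAWSS below `X`% of the parent mean
  (reported for X ∈ {50, 70, 90}; monotone non-decreasing in X by
  construction);
- `LSA` — dome area fraction below (parent mean − 1 parent SD), where the SD
  is the area-weighted *population* SD of per-triangle parent TAWSS (the
  weighting convention was unspecified upstream; area-weighted chosen for
  consistency with the means). A non-positive threshold gives LSA = 0.

Points labeled "excluded" (e.g. a manually clipped impingement zone)
contribute to no region; the label is supported but empty by default.

## Mesh-convergence protocol

A refinement study is a strictly decreasing sequence of maximum edge sizes
with the dome mean TAWSS measured at each. The stopping rule declares
convergence at the first refinement within 5% (default) of the *previous*
refinement. For reporting, the residual against the *final* refinement and
the mesh size normalized by the final size are also emitted, because
published convergence plots use the final-value convention while the stopping
rule uses the previous-step one; the final record has residual exactly 0 and
normalized size exactly 1. Refinement planning multiplies the edge size by
0.9 (≈10% decrement) per iteration. The module performs no remeshing; it
consumes (edge size, metric) pairs produced externally or by regenerating the
synthetic patient at each resolution.

## Cohort statistics

**Growth classification.** An aneurysm is *growing* when ≥ 2 of its 3
orthogonal diameters increased by ≥ 1 mm between scans, else *stable*.
Volume estimates use the ellipsoid formula `π/6·d₁d₂d₃` (the estimation
formula was unspecified upstream; ellipsoid is the standard reading of
three orthogonal diameters).

**Normality gate.** Shapiro–Wilk on the paired differences of each metric;
if any metric rejects at α = 0.05 the nonparametric route is recommended.
Constant difference vectors have no defined normality; they are flagged
degenerate and treated as non-normal.

**Paired test.** The upstream description "paired Wilcoxon rank sum test" is
read as the Wilcoxon *signed-rank* test on paired differences — the only
paired Wilcoxon test. Zero differences are dropped before ranking
(Wilcoxon's original treatment; the Pratt variant is available via
`zero_method="pratt"`). Absolute differences are mid-ranked, and for up to 20
effective pairs the two-sided p-value is exact over all `2^n` sign
assignments, computed by a generating-function convolution over doubled
ranks (so mid-ranks become integers); the two-sided convention is
`2·min(P(W⁺≤w), P(W⁺≥w))` capped at 1, matching the exact-mode convention of
standard statistical software. Beyond 20 pairs a normal approximation with
tie and continuity corrections is used (never needed at the cohort sizes
this pipeline targets). The cohort report flags metrics at α = 0.1, the
significance convention of the study design; no multiplicity correction is
applied (deliberately, matching the reporting style) — with 10 metrics at
α = 0.1 the family-wise false-flag probability under the null is therefore
≈ 1 − 0.9¹⁰ ≈ 0.65, and single spurious flags in a null cohort are expected
behavior, not a defect.

## Synthetic-data generator

The generator emulates the *statistical and geometric structure* of the
pipeline's inputs, not CFD physics.

**Waveform.** A truncated Fourier series (8 harmonics by default) of a
wrapped Gaussian pulse centered at 15% of the cycle with width 6–8% — a fast
systolic upstroke resembling internal-carotid flow — shifted and scaled so
the trapezoid cycle mean equals the requested mean flow exactly and
(max−min)/mean equals the requested pulsatility index exactly on the sample
grid. Defaults: mean flow 4 cm³/s (a representative ICA value; the upstream
waveforms derive from literature sources whose tables are not reproduced),
pulsatility index 1.0, 60 bpm, 201 samples.

**Surface and WSS field.** A parent tube (radius 0.2 cm ≈ ICA caliber,
length 2 cm) plus a hemispherical dome (radius 0.3 cm ≈ a 6 mm aneurysm),
structured-triangulated at a requested edge size (default 0.03 cm, the scale
of the convergence studies this emulates). The dome is built as independent
longitude-sector strips with duplicated seam points, so per-sector value
assignment yields triangles whose vertices share one value: a two-level
TAWSS field (a fraction of dome area at `dome_low_level`× the parent mean,
default 0.1; the rest at the parent mean) then has *exact* area fractions by
whole-sector bookkeeping. The sector count is rounded up to a multiple of
the low fraction's denominator, so rational fractions like 0.3 are realized
exactly. The geometric price — the dome surface is topologically split into
strips and not attached to the tube — is irrelevant to every metric
computed, which depend only on triangle areas, labels and vertex values.
The parent TAWSS level is anchored to the Poiseuille closed form
`τ = 4μQ/(πR³)` (≈ 25.46 dyne/cm² at the defaults) and modulated smoothly to
a requested spatial coefficient of variation (default 0.2). WSS magnitudes
are constant in time so the per-point TAWSS equals the assigned level under
trapezoid integration; temporal dynamics enter through a prescribed
direction reversal on the dome: the sign flips at the grid index whose
closed-form inverse realizes the OSI target (exact for targets 0 and 0.5
with the default 40 time samples; otherwise the nearest realizable value,
which the ground-truth record reports). Parent shear is unidirectional
(OSI 0).

**Cohorts.** Matched pairs with the stable member drawn around a baseline
template (defaults: stable-group means of the study's metric table) plus
between-pair noise, and the growing member equal to its stable partner plus
independent noise on every metric plus an additive effect on one named
metric. Default per-metric noise SDs follow the reported cohort spreads; for
the MTLSA metrics the growing-group spreads (~17–28 points) are used because
the stable-group values as printed (≈ 0.3) are implausibly small for
percentage metrics. All values are clipped to valid ranges ([0, 100]% for
areas, [0, 0.5] for OSI, ≥ 0 for TAWSS). Generation is bitwise reproducible
under a seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatially coherent CFD shear patterns (impingement
jets, secondary vortices), neck/dome geometry variability, measurement error
in region labeling, and within-patient correlation structure beyond the
single additive effect. One statistical caveat is deliberate: for metrics
whose baseline sits near a range boundary (e.g. minimum OSI near 0), additive
noise plus clipping makes the null differences asymmetric, which mildly
inflates the signed-rank type-I rate for those metrics. Calibration is
therefore assessed on interior metrics (e.g. MTLSA_70 at baseline ≈ 56 with
noise SD 10, keeping values inside [0, 100]), where the empirical rejection
rate at α = 0.1 over 500 null cohorts of 11 pairs falls within 3 binomial
standard errors of α.

## Numerical and design choices

- Trapezoid rule everywhere a sampled integral is needed; the stored grid is
  authoritative (no resampling inside the implementation — refinement-based
  oracles live in the test suite only).
- Windkessel: LSODA, rtol 1e-8 / atol 1e-6 barye, max step T/200; tuning
  iteration cap 100 with best-so-far reporting on failure; internal
  limit-cycle tolerance 1% during tuning (stricter than the 5% acceptance
  check so the reported values are well settled).
- Strict `<` at low-shear thresholds; ties count as not low.
- Exact signed-rank enumeration up to n = 20 (the DP is O(n·Σrank) and
  instantaneous at cohort scale); two-sided doubling convention.
- Surface files are ASCII VTK XML PolyData written with shortest round-trip
  float representations, so write→read is bitwise; a per-timestep directory
  dialect with a `manifest.csv` is accepted for compatibility with common
  CFD exports. A `length_unit_cm` field-data scalar declares the coordinate
  unit; when absent, cm is assumed with a logged warning.
- Test-suite and acceptance problem sizes: coarse meshes (edge 0.06–0.08 cm,
  8–20 time samples) for construction/measurement consistency, 50 random
  fields for the integration oracle, 500 null cohorts for calibration, and
  5-cycle traces for the integrator cross-check — sizes chosen so the whole
  suite verifies every contract in well under a minute of compute while the
  checks remain at full strength (the consistency bounds are 1e-10 relative
  regardless of mesh size).

## Known limitations

- The 0D surrogate applies clinical pressure targets at the lumped
  inlet-equivalent node; a 3D model distinguishes inlet and outlet nodes.
- The exact multi-outlet reduction relies on all outlets sharing one time
  constant (guaranteed by the inverse-area split with 1/R-proportional
  compliance); heterogeneous per-outlet RCR sets would need per-outlet state.
- Synthetic OSI targets between 0 and 0.5 are realized to grid resolution,
  not exactly; the achieved value is recorded in the ground truth.
- The signed-rank test assumes symmetric null differences; boundary-clipped
  metrics violate this mildly (see above).
- LSA/MTLSA depend on the parent-region definition; region labels are taken
  as given and no automatic dome/neck detection is attempted.
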