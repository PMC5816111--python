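# Methods

This note documents the models, parameter choices and numerical decisions
behind `iodair`.  Everything quantitative here is computed by the package
itself (the test suite and `scripts/acceptance.py` exercise each claim).

## Two-stage charcoal sampling

Air passes a Petryanov filter and then two identical KI-impregnated
charcoal cassettes.  Assuming equal absorption yield per cassette, the
activity trapped on stage *n* is C_A·qⁿ⁻¹ with q the per-stage
breakthrough, so the activity that entered the cartridge is the geometric
sum C_total = C_A/(1 − q) and the two-stage efficiency is ε = 1 − q².
These two relations are mutually consistent — (C_A + C_B)/C_total = 1 − q²
identically — which the property suite checks across q ∈ [0, 1).

The breakthrough ratio is defined as q = C_B/C_A (downstream over
upstream), the ratio of successive geometric terms; q > 1 is rejected as a
sampling failure.  Uncertainty on A_total = C_A²/(C_A − C_B) is propagated
to first order; a 10⁵-draw resampling test shows agreement with the full
distribution within 5% for relative counting errors up to 10%.

Decay correction, when requested, back-corrects to the **mid-point of the
sampling interval** — the unbiased single reference time for a sample
integrated over a day — and neglects decay during the (hours-long) count,
which is negligible against the 8.03-d half-life.  Campaign summaries
report the arithmetic mean ± sample standard deviation of daily values,
i.e. day-to-day variability, not propagated counting error.

## Exposure scenarios

Reference regimens encode a radioiodine department's duty roster:

| parameter | technician | nurse |
|---|---|---|
| gas concentration (Bq m⁻³) | 490 | 170 |
| aerosol concentration (Bq m⁻³) | 7 | 18 |
| hours per intake | 6 | 12 |
| intakes per year | 50 | 30 |
| spacing (d) | 7 | 3 |

Breathing rates are sitting-exercise reference values, 0.54 m³ h⁻¹ (male)
and 0.39 m³ h⁻¹ (female), applied to both professions.  Each work period
is modelled as an **instantaneous bolus** at its start: for an 8.03-d
nuclide with ≥ 3-d spacing, a bolus differs from a 6–12-h continuous
inhalation by < 2% in committed dose, and boluses keep the linear system
piecewise-homogeneous.  The nurse's 30 shifts are placed in one contiguous
90-d block; committed annual doses depend only on the event count, so the
block's position matters only for trajectory plots.

## Deposition

Regional deposition fractions are a parameter file, not code.  Defaults:
5 µm AMAD sitting-worker values per sex (total 0.7600 male / 0.7369
female; the rest is exhaled) and elemental iodine vapour at 100%
deposition (ET₁ 0.10, ET₂ 0.40, BB 0.50, sex-independent; the bronchial
vapour deposit is assigned to the fast-clearing BB compartment and vapour
does not reach bb or AI).  Conservation (deposited + exhaled = inhaled) is
enforced exactly.  Treating the aerosol at a fixed 5 µm AMAD and the gas
as elemental iodine is deliberately conservative (dose-overestimating).

## Biokinetics

One linear system couples three classical sub-models (all rates live in
`data/transfer_rates.csv`, one row per transfer with provenance):

* **Respiratory-tract clearance** — particle transport AI → bb → BB → ET₂
  → stomach at the standard HRTM rates (0.02, 2, 10, 100 d⁻¹; slow
  compartments 0.03 d⁻¹; ET₁ → environment 1 d⁻¹), plus fast Type-F
  dissolution of every thoracic/ET₂ deposit to blood at 100 d⁻¹ (10-min
  half-time; ICRP default for soluble iodine).  Inhaled vapour is already
  dissolved and undergoes only the fast absorption, not particle
  transport.  The three AI sub-compartments are merged at the dominant
  0.02 d⁻¹ rate and the small sequestered fractions are folded into the
  fast compartments: with 100 d⁻¹ dissolution, particle-transport detail
  is numerically irrelevant for iodine (absorption wins by three orders of
  magnitude).
* **GI transit** — stomach → small intestine at 24 d⁻¹; iodide is fully
  absorbed from the small intestine (6 d⁻¹ to blood, f₁ = 1); the colon
  (1 d⁻¹ to faeces) carries only the organically bound excretion path.
* **Systemic iodine** — the classical iodide/organic recycling model:
  blood iodide clears at ln 2/0.25 d ≈ 2.77 d⁻¹, 30% to thyroid and 70%
  to the urinary bladder (voided at 12 d⁻¹); thyroid iodine is secreted as
  organic iodine at ln 2/80 d; extrathyroidal organic iodine turns over at
  ln 2/12 d, 90% deiodinated back to blood iodide and 10% to faeces.
  This is the direct ancestor of the modern physiological iodine models
  and reproduces reference inhalation dose coefficients for ¹³¹I within a
  few percent; richer parameterizations (e.g. explicit salivary/gastric
  secretion loops) are drop-in via the rate file.  The shipped rates are
  sex-independent; sex enters through breathing rates, deposition and
  organ masses.

¹³¹I decay (λ = ln 2/8.03 d⁻¹) applies uniformly to every body
compartment, flowing into a `decayed` bookkeeping sink; with the `urine`,
`faeces` and `environment` sinks every column of the rate matrix sums to
zero, so total activity is conserved by construction and the balance
*compartments + excreted + decayed = intake* is checked to 1e−8.

**Solver.**  The solution of dA/dt = M·A between boluses is the matrix
exponential, exact for a linear system; propagators are cached per step
length.  A high-accuracy adaptive ODE integration serves as the test
oracle (agreement ≤ 1e−6), as does the Bateman closed form on a
two-compartment chain (≤ 1e−8).  Committed time-integrated activities use
Ũ(T) = −M_b⁻¹(A₀ − e^{M_b T}A₀) on the body sub-matrix, which is always
invertible because every compartment decays; the default commitment
period is 50 y (occupational convention), indistinguishable from 1 y for
this nuclide (Ũ(1 y)/Ũ(50 y) ≥ 0.9999, asserted).

**Plateau activity.**  Under repeated intakes the thyroid content
approaches a quasi-equilibrium sawtooth.  The reported plateau is the
thyroid activity at the **midpoint of an inter-intake interval after ≥ 10
intakes** — the least-biased single summary of the cycle, evaluated once
the per-intake contributions have converged (the weekly decrement factor
is e^{−0.095·7} ≈ 0.51, so 10–12 intakes suffice to < 0.5%).

## Dosimetry

H_T = Σ_S Ũ_S·S_w(T←S, sex), E = Σ_T w_T·H_T with the ICRP 103 weights
(remainder w = 0.12 as the arithmetic mean of the 13 remainder tissues,
two of which — extrathoracic airways and small-intestine wall — have
specific source terms here; the systemic organic-iodine pool maps to a
uniform whole-body source).

The default S-coefficient table is **derived in-package** from: ¹³¹I mean
energies per decay (electrons 0.1917 MeV, photons 0.3817 MeV), reference
organ masses (thyroid 20/17 g, lungs 1.2/0.95 kg, body 73/60 kg, walled-
organ contents per sex), electron absorbed fraction 1 in compact organs
and 0.5 for surface (airway) deposits and walled-organ contents (the
ICRP 30 wall convention), and a photon absorbed-fraction model
0.0306·(m/20 g)^0.3 for self-irradiation (0.031 for a 20-g thyroid at
364 keV) with body-averaged photon cross-fire (whole-body absorbed
fraction 0.34/0.33).  Ignoring proximity enhancement in cross-fire biases
non-thyroid doses slightly low, but these contribute only ~1.5% of E for
iodine; the E/H_thyroid ratio stays within [0.040, 0.042] across all
scenarios (asserted within [0.038, 0.045]).  The derivation function and
the table are interchangeable: user CSVs are drop-in.

**Calibration mode.**  For regression against reference SEECAL/SAAM-II
based assessments, `calibrated=True` scales the entire S-table by one
factor so the male-gas effective dose coefficient equals the reference
1.3 mSv / 79 380 Bq = 1.638e−8 Sv Bq⁻¹.  The factor computed from the
default table is ≈ 1.036, i.e. the first-principles derivation lands
within 4% unaided.  Calibration is explicit, never silent; it rescales
doses only and leaves every activity, every ratio between sexes,
professions and tissues, and the plateau activities untouched.

Per-sex "effective doses" follow the workplace-survey convention of
quoting males and females separately (formally, E is sex-averaged;
`sex_averaged_effective` provides that too).  Report display rounds to
two significant figures.

## Synthetic campaigns

The generator emulates the two structural regimes of real monitoring
data: a **hot-room pulse** (exponential decline from a delivery-day peak;
spanning 492 → 28 Bq m⁻³ over 6 d implies a decay rate ln(492/28)/6 ≈
0.478 d⁻¹) and a **stationary** ward profile (log-normal day-to-day
scatter around a mean).  Per day, the true collected activity is split
(1−q)·A on the first cassette and q(1−q)·A on the second; the tail q²·A
escapes (two-stage hardware, no third stage).  Counting noise is Gaussian
with σ = fraction × activity, matching the one-sigma counting-statistics
framing of real tables; negative draws are clamped at zero.  Fixed seeds
give bit-identical campaigns.

What it does *not* emulate: spectrum shape and detector effects, aerosol
size distributions, room-ventilation dynamics, correlations between gas
and aerosol fractions.  Passing round-trip and calibration tests
therefore demonstrates the correctness of the reduction algebra and the
statistical calibration of the estimators, not the physics of any
particular room.

## Problem sizes and numerical choices

The compartment system is 18×18 (14 body compartments + 4 sinks); annual
scenarios involve ≤ 50 boluses.  Trajectories default to 24 samples per
inter-intake interval; plateau runs use 12 intakes.  The acceptance
script's doses use the calibrated table; the plateau value is raw
biokinetics.  Degenerate inputs fail loudly: zero first-cassette
activity, breakthrough > 1, diverging series (q ≥ 1), negative elapsed
times, deposition fractions summing above 1, non-finite rates, missing
S-table entries (named by pair), and tissue weights not summing to 1.

## Known limitations

* The systemic model is the classical recycling description, not a full
  physiological multi-organ iodine model; salivary/gastric secretion
  loops are absent (their effect is folded into the blood-clearance
  split).  All rates are editable configuration.
* S-coefficients use a simple absorbed-fraction model rather than
  phantom-based specific absorbed fractions; the calibration mode exists
  precisely to absorb this residual (~4%) scale uncertainty.
* Doses are point values; no uncertainty propagation beyond the
  air-sampling stage.
* Occupational adults only; no patient or age-dependent dosimetry; no
  iodine-speciation (organic vs inorganic) distinction on the charcoal.
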