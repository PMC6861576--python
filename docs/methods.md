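# Methods

This note records the models benzilkit implements, the conventions and
numerical choices behind them, and what the packaged data and synthetic
generators do and do not cover. Quantities and symbols follow standard
conceptual-DFT / DSSC / NLO usage.

## Data model and units

Every analysis consumes `MoleculeSummary` records or flat tables. Units are
fixed by the schema: energies in eV, wavelengths in nm, wavenumbers in cm⁻¹,
dipoles in Debye, torsional energies in kJ/mol (hartree inputs are converted
on load with 2625.50 kJ/mol per hartree), NLO scalars in esu. Loaders
validate all invariants (E_HOMO < E_LUMO, IP > EA, positive wavenumbers,
weights in (0,100] summing ≤ 100, docking ranks contiguous and sorted) and
report violations with the molecule or block that caused them; nothing
downstream re-checks units or ordering.

`ip_vertical`/`ea_vertical` are stored independently of the orbital
energies. The study data make this necessary: the descriptor table's IP
(8.748 eV for BZL) is not −E_HOMO from the photovoltaic table (6.596 eV) —
the descriptor inputs are evidently vertical ΔSCF-style values, the
photovoltaic chain uses the Koopmans reading. Keeping both as independent
inputs lets each table be reproduced simultaneously; the package never
derives one from the other.

## Reactivity descriptors

`compute_descriptors(ip, ea)` evaluates χ = (IP+EA)/2, μ = −χ,
η = (IP−EA)/2, S = 1/η, ω = μ²/2η and the IP−EA gap in full double
precision; `ip ≤ ea` is rejected (hardness must be positive). The identity
suite (χ = −μ, S·η = 1, 2ηω = μ², gap = 2η) is enforced to 1e−12 relative
in tests, which is why no rounding happens inside the computation.

Reports round to three decimals, and the reference descriptor table follows
the older report convention in which S and ω are computed *from the rounded*
χ, μ, η (e.g. ω(BZL) = 7.407²/(2·1.342) = 20.441, where full precision gives
20.446). `rounding_chain_descriptors` reproduces that chain explicitly,
using decimal arithmetic with half-up rounding so the half-way cases
(χ = 7.2845 → 7.285) behave as a human with a calculator would. Table
reproduction runs through this path; all analysis runs through the
full-precision path. Two gaps are exposed under distinct names — `gap_ipea`
(= 2η, from IP−EA) and `orbital_gap` (= E_LUMO − E_HOMO) — because the two
differ by >1 eV for these molecules.

## Photovoltaic screening

LHE = 1 − 10⁻ᶠ; E(0,0) = K/λmax; E_dye = −E(HOMO);
E*_dye = E_dye − E(0,0); ΔG_inject = E*_dye + E_CB.

* K defaults to 1240 eV·nm, not the exact hc/e = 1239.84: the reference
  table's six-decimal E(0,0) cells reproduce only under 1240 (e.g.
  1240/286.99 = 4.320708). The exact constant is available as
  `EV_NM_EXACT`.
* E_CB defaults to −4.00 eV (TiO₂). Sign convention: ΔG = E*_dye + E_CB,
  equivalently E*_dye − |E_CB|; stated explicitly because the DSSC
  literature writes this several ways. More negative ΔG ⇒ more spontaneous
  injection.
* `select_best_sensitizer` orders by most-negative ΔG_inject, breaking ties
  by higher LHE and then id.
* Numerical domain: LHE saturates to exactly 1.0 in double precision for
  f ≳ 16; the strict upper bound is meaningful only below that (irrelevant
  for physical oscillator strengths of order 1).

## NLO scalars

Only scalar μ, α, β, γ are published for this series, so the tensor
combination rules follow the standard quantum-chemistry output conventions:
β_total is the norm of the contracted vector β_i = β_iii + β_ijj + β_ikk
over the 10 Kleinman-symmetric components; γ̄ is the isotropic average
(γ_xxxx + γ_yyyy + γ_zzzz + 2(γ_xxyy + γ_xxzz + γ_yyzz))/5; au→esu factors
are 1.4819×10⁻²⁵ (α), 8.6393×10⁻³³ (β), 5.0367×10⁻⁴⁰ (γ). Tensor paths are
exercised by synthetic data and checked against explicit-summation and
tensor-rotation oracles (both scalars are rotation invariants).

The urea reference β defaults to 0.13×10⁻³⁰ esu — the unique two-significant-
figure value consistent with all five published fold-enhancements
(15, 31, 29, 52, 64) — and is configurable (`--beta-ref`). Fold ratios are
rounded half away from zero. γ is called "second hyperpolarizability"
throughout the API to avoid collision with β.

## Vibrational statistics

Harmonic wavenumbers are scaled once by 0.9613 (the standard empirical
factor for this level of theory); re-scaling a scaled list is a state
error. The packaged assignment tables are treated as already scaled — their
C–H stretches near 3100 cm⁻¹ are incompatible with unscaled harmonics — so
`apply_scaling` exists for raw-input workflows.

Pairing is row-wise ("assigned") for curated tables; "nearest" mode matches
greedily by ascending |calc − obs| within a window (default 30 cm⁻¹), each
mode and band used at most once. Pairing must happen *after* scaling — a
regression test pins this, since the two orders only commute when the
window is scaled too. RMSD is computed per technique (IR and Raman
separately). The published per-molecule RMSDs are soft targets: the pair
inclusion rules behind them are not stated, and this package's transcription
gives 26 IR pairs for benzil with RMSD 5.02 cm⁻¹ against the published
5.1 — agreement within the 0.3 cm⁻¹ band used in tests, not cell-exact.

## Torsional profiles

Profiles are grid-sampled (10° default) relaxed scans over one period of
the central dihedral. `to_relative` shifts the minimum to zero; extrema are
reported at grid resolution with ties broken toward the smaller angle — no
interpolation, matching the "at about 40°" precision of the source data.
Barrier = E(max) − E(min). The raw scan energies for the study molecules
were never published, so the packaged torsion data are metadata (barrier
heights, extremum angles); analysis correctness is established on synthetic
cosine wells E(θ) = A/2·(1 − cos k(θ − θ₀)) whose barrier is A by
construction, including wells built to the published amplitudes
(DFB 17.4132 > DCB 16.4048 > BZL 16.3175 > DBB 8.3755 > DMB 8.2860 kJ/mol),
whose recovered ordering matches the published one.

## Docking summaries

Score tables are opaque "score units" (no kcal/mol conversion is offered
because none is documented). Parsing enforces contiguous ranks and that
rank 1 carries the block's minimum global energy. "High" contact energy is
read as most negative (stabilising); because the rank-1 and block-minimum
ACE can genuinely differ (3WMT–DMB: −7.12 vs −9.73), `ace_summary` reports
both rather than letting the ambiguity leak into results. The QSAR response
vector is the rank-1 ACE per complex, rebuilt from the parsed tables rather
than copied from the regression table — the two agree cell-for-cell.

## QSAR

BE is regressed on IP, EA, S, ω plus an intercept; χ, μ, η are excluded as
linear/derived combinations of the included descriptors. With five
molecules the system is square: a nonsingular design is solved exactly
(`numpy.linalg.solve`) and interpolates the training responses to <1e−8;
overdetermined designs use least squares, whose residuals are orthogonal to
the design columns. Singular designs raise an error naming the collinear
columns (via the SVD null vector); condition numbers above 1e8 warn. The
design here has condition number ≈1.2×10⁵ — ill-scaled but far from
singular.

The externally reported integer coefficients are shipped as a comparison
fixture only. Rounding exact-solve coefficients to integers destroys an
interpolating fit — applying them to the descriptor rows mispredicts BE by
up to ~14 score units — so the package *reports* that discrepancy
(`printed_model_max_abs_error`, sign agreement per coefficient) and never
adopts the printed values as the model of record.

## Synthetic data

Each generator draws from its own named stream,
`default_rng([seed, crc32(name)])`, so output is a pure function of its
config and adding a generator never perturbs another's stream. Defaults
emulate the study conditions: five molecules, IP ∈ [7.5, 9.0] eV strictly
above EA ∈ [5.0, 6.5] eV, single transitions at λ ∈ [250, 320] nm with
f ∈ [0.4, 1.2], 200 modes over [150, 3200] cm⁻¹ with observed bands =
scaled calc + N(0, σ = 5 cm⁻¹), cosine torsional wells of 5–20 kJ/mol, and
sorted docking blocks of ten conformations. Ground-truth descriptor values
are recorded at draw time for recovery tests.

What the synthetic data deliberately does not emulate: real mode-assignment
ambiguity (observed bands are aligned with their modes by construction),
anharmonicity or resonances, multi-transition UV spectra, non-cosine
torsional shapes, and correlated docking score columns. Passing the
synthetic suite therefore demonstrates the *analysis* chain is correct
under controlled truth, not that the upstream electronic-structure data are
accurate.

## Problem sizes and determinism

Everything is desk-scale: the study series is five molecules, the largest
fixture is 150 docking rows, and synthetic property sweeps use n = 200
modes and 50 random torsion draws; the full test suite runs in a few
seconds on one CPU. All randomness (tests and generators) is explicitly
seeded; hypothesis runs derandomised. `scripts/acceptance.py` is
deterministic end-to-end — its `--seed` only initialises auxiliary random
state.

## Known limitations

* No parsing of raw quantum-chemistry log files, and no 3-D structure
  formats; summaries must arrive in the documented JSON/CSV schema.
* Frequency-dependent hyperpolarizabilities, local (Fukui) reactivity,
  open-circuit-voltage modelling, spectral lineshapes and anharmonic
  corrections are out of scope.
* The rounding-chain reproduction of the descriptor table encodes an
  inference about how that table was produced; the full-precision path is
  authoritative for new data.
* The published 4-decimal LHE for the dibromo dye (0.9079) is one ulp below
  the computed 0.907955; the package reports the computed value.
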