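# Methods

## The assay being modeled

A single-dose phenotypic screen for immunopotentiators: GFP-labeled cancer
cells seeded in 384-well plates, alone or with anti-CD3/IL2-activated PBMCs
at a 1:1 cancer:PBMC ratio, treated at 10 µM, with per-well GFP intensity
read on a 4-h grid for 96 h and viabilities evaluated at 72 h. The package
implements the analysis chain (QC → viability → Bliss scoring → ranking →
DEG set logic) on any conforming plate tables, and a simulator that
generates such tables with known ground truth.

## Simulator

### Dynamics

Cancer signal G(t) in a well evolves as

    dG/dt = r·G·(1 − G/K) − (d_drug(c) + k_eff)·G,   G(0) = g0

with logistic growth (rate `r`, carrying capacity `K`) and two first-order
kill terms:

- direct drug kill `d_drug(c) = d_max·cʰ/(cʰ + EC50_dʰ)` (Hill exponent
  `h`, default 1);
- immune kill `k_eff = k_imm · donor_factor · ratio_scale · (1 +
  p_max·cʰ/(cʰ + EC50_pʰ))`, present only in co-culture wells.

PBMC-only wells emit a constant background level, since the effector cells
carry no reporter. Integration is forward Euler at `dt = 0.5 h`, chosen so
runs are bit-for-bit reproducible and cheap; the integration error is far
below the 5% measurement noise the model adds anyway.

### Parameters, defaults and why

| parameter | default | meaning / rationale |
|---|---|---|
| `g0` | 1000 AU | initial cancer signal (1,000 cells/well seeding) |
| `r` | 0.035 /h | intrinsic growth rate; doubling ~20 h, typical for a fast CRC line |
| `K` | 20·g0 | carrying capacity; wells approach confluence near the assay end |
| `pbmc_background` | 50 AU | unlabeled-PBMC well signal, ~5% of initial cancer signal |
| `k_imm` | 0.0105 /h | immune kill rate, calibrated once (see below) |
| `donor_factors` | D1 1.10, D2 0.92, D3 0.97 | per-donor killing variation |
| `noise_cv` | 0.05 | CV of multiplicative lognormal noise, a typical plate-reader CV |
| `dt` | 0.5 h | Euler step |
| `grid` | 0..96 h by 4 | observation times |

`k_imm` was calibrated once against the noise-free model so that the
untreated co-culture:monoculture signal ratio at 72 h is ≈ 0.55, the level
of immune-mediated killing the assay is designed around; the donor
multipliers then spread per-donor viabilities over ≈ 0.52/0.58/0.56
(mean 55%). The cancer:PBMC seeding ratio enters only as a linear
multiplier on `k_imm` (4:1 effector excess → 4× kill rate); no more
detailed effector-to-target dependence is modeled.

Noise is lognormal with mean 1: `σ² = ln(1 + CV²)`, `µ = −σ²/2`,
independent across wells and timepoints. Intensities are positive and
heteroscedastic, and a CV parameterization maps directly onto Z-factor
behavior.

### What the simulator does and does not emulate

It reproduces: logistic growth, ~50–55% untreated co-culture viability,
donor-to-donor spread, direct-vs-potentiating drug action, multiplicative
noise, the 4-h/96-h sampling design. It does **not** model immune-cell
population dynamics, cytokine feedback, spatial effects, plate-edge or
drift artifacts, or PBMC autofluorescence changing over time. Passing tests
therefore validate the *analysis chain's arithmetic and operating
characteristics under the stated noise model*, not the biology of any real
screen.

## Viability

Percent-of-control at a grid time: well signal divided by the arithmetic
mean of ≥ 2 control wells. `OWN_CULTURE` baseline divides by the same
culture type's controls (vehicle controls by default — which control the
original screens used is ambiguous, so both are supported); `MONOCULTURE`
divides everything by the untreated cancer-monoculture mean, which gives
the activated PBMCs a well-defined single-agent viability. Viabilities are
never clipped (values > 1 mean stimulation or noise); no PBMC background
subtraction by default, available as a flag. Donor averages are reported
with half-away-from-zero rounding to integer percent.

## Assay QC

Z = 1 − 3(σ₁+σ₂)/|μ₁−μ₂| on raw intensity of untreated wells, sample SD
(n−1). Z_M compares cancer monoculture vs PBMC monoculture; Z_P co-culture
vs PBMC monoculture. Group orientation is irrelevant (absolute value).
Equal means raise an explicit undefined-Z error rather than returning ±∞.
The evaluation-time rule makes the informal practice explicit: among times
with Z_M ≥ 0.5, take the Z_P-maximizing time, ties to the later time. A
pipeline may still fix the evaluation time a priori (72 h default); the
QC-selected time is then only logged.

## Bliss immunopotentiation score

With all viabilities relative to untreated cancer monoculture,
`B = V_drug(mono)·V_PBMC − V_combination`. This baseline convention makes
B = 0 *exact* for inert compounds and gives "drug 2" (the PBMCs) a
well-defined viability. Replicate wells are averaged before scoring (score
of means — stabler at n = 1–3 replicates). Viabilities > 1 enter uncapped;
capping would bias B toward zero. Ranking is descending B, ties by
ascending combination viability, then compound id; the top-N cut is purely
score-based (no literature curation layer).

A caveat worth stating precisely: Bliss multiplicativity (V₁·V₂ = V₁₂ for
non-interacting effects) is exact for log-linear kinetics. Under logistic
growth the saturation term breaks log-additivity, so a *purely cytotoxic*
compound scores a small positive residual rather than exactly zero — to
first order ≈ 0.25·g0/K ≈ 0.012 at the defaults, shrinking as K grows,
with a floor of ~8e-4 from the Euler discretization (per-step error
∝ dt²·d·k). This residual is an order of magnitude below a genuine
potentiator's score (≈ 0.45 at p_max = 3), so ranking still isolates
potentiation; tests pin both the residual's size and its decay toward the
log-linear regime.

## Operating characteristics

`screen_operating_characteristics` repeatedly simulates a screen with a
known planted fraction of potentiators, scores and ranks it, and records
the sensitivity (planted compounds recovered in the top N) and false
discovery (top-N members not planted). Non-planted compounds are inert by
default so that the p_max = 0 null is exchangeable with the planted set
(recovery then matches the top_n/n random-ranking rate); a
`frac_cytotoxic` option plants direct cytotoxins among the nulls. The
default scenario — 320 compounds, 5% potentiators at p_max = 3, 5% CV,
top 25, 50 replicates — runs in a few seconds and recovers essentially all
planted potentiators; its false-discovery rate is dominated by top_n (25)
exceeding the number planted (16), not by misranking.

## DEG set logic

Fold changes use the signed linear convention (+2 doubled, −2 halved; the
open interval (−1, 1) is unrepresentable and rejected), with a loader
option converting log2 input. The threshold rule is inclusive (|FC| ≥ 2):
on continuous data the boundary has measure zero and the closed rule is
stable under rounding — stated prominently because it affects counts.
Directions: `ANY` (either), `UP`, `DOWN`, `CONCORDANT` (same direction in
every set considered). For unique-gene queries, "absent elsewhere" means
absent in *any* direction. Venn counts support 2–3 sets; under
`CONCORDANT`, genes whose direction differs across the sets containing
them are excluded from the diagram entirely, so region sums can fall below
the union size (they equal it for the other directions). Upstream
microarray normalization and any significance filter are out of scope; the
module starts from a fold-change table.

## Numerical and design choices

- Time grids are plate-set-wide and verified at load; off-grid requests
  raise rather than interpolate.
- Negative intensities and NaN are rejected at I/O; nothing is clipped at
  read time — downstream stages decide their own handling.
- Well labels are row-letter + zero-padded column ("B03"); parsing is a
  bijection with 0-based (row, col) indices, property-tested.
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; identical config + seed reproduce
  byte-identical pipeline outputs.
- Scale invariance: viability, Z and B are invariant under a global
  rescaling of raw signals; the simulator preserves this (scaling g0, K
  and background together scales every trace).

## Problem sizes

Test and reproduction runs use desk-scale versions of the screen: 64
control wells per group for QC (the full four-experiment QC size), 320
compounds × 50 replicates for operating characteristics, ≤ 200-gene random
fixtures for set-logic oracles. These sizes make the whole suite run in
well under a minute while keeping Monte-Carlo error small relative to the
asserted margins.

## Known limitations

- The kill model is phenomenological; EC50s and kill rates are not fitted
  to any real compound.
- Z_P in the simulator stays roughly flat over time because co-culture
  signal keeps growing under the calibrated kill rate; a declining Z_P
  (killing overpowering growth) appears only at higher `k_imm`, which is
  how the corresponding test exercises it.
- Hit validation in practice involves re-testing and literature judgment;
  here ranking is purely score-based.
- The expression-set stage reproduces set logic, not any specific
  published gene counts, which would require the original microarray data
  and normalization pipeline.
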