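# Methods

## Scope

`lqtsim` implements a cellular in-silico pipeline for torsadogenic-risk
assessment: (1) the O'Hara–Rudy (ORd) human ventricular myocyte model with
multiplicative scaling hooks on six currents, (2) periodic pacing and
biomarker extraction, (3) a genetic algorithm (GA) that fits the scalings to
clinical long-QT (LQT) repolarisation targets under intracellular
concentration constraints, (4) Hill-equation multi-channel drug block, and
(5) a linear decision-boundary classifier separating torsadogenic (TdP
positive) from non-torsadogenic drugs in the plane of baseline-normalised
APD50 and diastolic [Ca²⁺]ᵢ.

## Cell model

The ORd endocardial and epicardial variants are transcribed as a 41-state ODE
system (voltage; myoplasmic/subspace Na⁺, K⁺, Ca²⁺; SR Ca²⁺; Hodgkin–Huxley
gates; CaMK activation).  Scaling factors `ks, kr, cal, ncx, nak, nal`
multiply G_Ks, G_Kr, P_CaL, G_NCX, P_NaK and G_NaL linearly, so each current
is exactly proportional to its factor at fixed state; CaMK-phosphorylated
current components inherit the scaling of their parent current.  A separate
factor `na` multiplies the fast-sodium conductance G_Na; it exists because
drugs block I_Na, but it is never an optimisation parameter.  The
`nal_lqt3` factor is carried with the scaling set and is inert except under
the simulated LQT3 condition, where the effective late-sodium multiplier is
`nal × nal_lqt3` (multiplicative composition; validated by reproducing the
reference LQT3 APD90 prolongation of the optimised models, see below).

LQT conditions: LQT1 halves `ks`, LQT2 halves `kr` (heterozygote nonsense
mutations ≈ 50 % conductance loss), LQT3 applies the `nal_lqt3` gain.

### Initial conditions

Shipped 1 Hz steady states (JSON package data, one per variant) were produced
by pacing each variant 3000 beats at 1 Hz with this package's integrator from
a crude resting guess; `scripts/make_steady_states.py` regenerates them.
They satisfy strict self-consistency: one further paced beat changes APD90 by
< 0.01 ms, and 10 s of unstimulated integration drifts the resting potential
by well under 2 mV.

### Validation

The transcription is validated against well-established deterministic outputs
of this pipeline rather than against a second implementation: control
endocardial APD90 at 1 Hz steady state (268.1 ms vs the 267.97 ms target),
the conductance sensitivity panel (halving G_Kr: +117 ms APD90; halving
G_Ks: +8 ms; halving G_NaK: +1.7 mM [Na⁺]ᵢ), and the LQT responses of the
two reference optimised scaling sets, which agree with the reference relative
prolongations to within ~0.2 percentage points across all six conditions.
Together these exercise every major current and the Ca²⁺/Na⁺ handling.

## Numerics

The integrator advances gate-like states (ordinary gates, the `nca` channel
mode fraction and the two SR-release fluxes — all linear in the state) by
exact exponential (Rush–Larsen) updates and the nonlinear states (voltage,
concentrations, CaMKt) by forward Euler.  The time step is two-level: 0.005
ms while |dV/dt| > 0.5 mV/ms (stimulus, upstroke, fast repolarisation) and
0.03 ms elsewhere.  Halving both steps moves the steady-state APD90 by ~0.1
ms, an order of magnitude below the tightest acceptance tolerance (±3 ms).
Integration is bit-for-bit deterministic.  The stimulus is the published ORd
protocol: a rectangular −80 µA/µF, 0.5 ms pulse each cycle, included in the
K⁺ balance.  Traces are recorded on a fixed 0.25 ms grid.

Safe limits replace the singular exponential flux expressions near V = 0.
Divergence (non-finite state or |V| > 200 mV) raises an error carrying the
beat index.

## Biomarkers

All biomarkers are measured on the final recorded beat after 500 pre-pacing
beats (every perturbation starts from the shipped baseline steady state):

- APD_f: time from maximum upstroke velocity (dV/dt max) until voltage first
  falls below `V_peak − f (V_peak − V_dia)`, with linear interpolation at the
  crossing; `V_dia` is the pre-stimulus voltage of that beat.  Measuring
  from stimulus onset instead would change APD by ≲1 ms.
- diastolic/systolic [Ca²⁺]ᵢ: min/max of the cytosolic calcium transient
  within the final cycle (reported in µM).
- [Na⁺]ᵢ: maximum within the final cycle (it varies < 0.01 mM within a
  beat at baseline).

## Optimisation

Objective: sum of squared APD90 deviations (ms²) from the targets
267.97 (control), 301.14 (LQT1), 312.20 (LQT2) and 311.55 ms (LQT3) — the
clinical QT-prolongation percentages mapped onto the model's control APD90.
The multi-variable objective adds a fixed 200 ms² penalty for each
control-condition concentration check outside its physiological range
(diastolic [Ca²⁺]ᵢ 0.05–0.15 µM, systolic 0.3–0.7 µM, [Na⁺]ᵢ 7–10 mM).
The penalty can apply per violated check or once in total; per-check is the
default and the alternative is a
config switch (`penalty_per_violation`).  Simulation failures (divergence,
incomplete repolarisation, loss of a resting diastolic potential) contribute
a large finite sentinel (10⁷ ms²) instead of raising, so the GA can discard
them gracefully.

GA: seven real-valued genes in log₁₀ space over [−3, 1] (0.1 % to 10-fold);
tournament selection (size 2), two-point crossover (p = 0.9), per-gene
Gaussian mutation (σ = 0.2 log-units, p = 0.1), elitism of one.  These
internals follow common practice for cardiac-model fitting and are all
exposed in the configuration.  Population 200 × 50
generations × 10 restarts is the reference protocol scale (config defaults);
it is cluster-sized at full fidelity, so tests exercise the search at
reduced scale: a simulation-free quadratic surrogate (population 50 × 40
generations recovers a known 7-parameter truth within 8 %) and a closed-loop
run (population 16 × 20 generations, 20 beats/evaluation, single `kr` gene)
that recovers a perturbed G_Kr within a few percent from the APD it
produces.  `free_genes` restricts the genome for such identifiability-limited
settings.  All randomness flows from a single integer seed; the best-of-n
protocol uses seeds `s, s+1, …` and breaks ties by lowest run index.

## Drug block and panel

Block of channel x at the effective free therapeutic plasma concentration:
`G_x → G_x (1 + EFTPC/IC50_x)⁻¹` (Hill coefficient 1); a missing IC50 means
no measured block.  Only the EFTPC/IC50 ratio matters; units must be
consistent within a record.  The panel runner paces each blocked model 500
beats, extracts biomarkers, normalises APD50 and diastolic [Ca²⁺]ᵢ by the
same model's no-drug values, and can cache per-drug results for resumption.

The packaged verapamil record (EFTPC 0.081 µM; IC50 0.143 µM for I_Kr,
0.100 µM for I_CaL, 40.4 µM for I_Na) yields block fractions G_Kr × 0.64,
G_CaL × 0.55, G_Na × 0.998.  These three fractions are sometimes quoted with
0.64 attached to G_CaL and 0.55 to G_Kr instead; that assignment is
inconsistent with the IC50 arithmetic and with the expected behaviour of the
optimised model (it would prolong APD50 there by > 20 ms instead of ≤ 5 ms),
so the package treats it as a channel-assignment swap.  Both assignments are
exported (`VERAPAMIL_BLOCK`, `VERAPAMIL_BLOCK_SWAPPED`); the contrast the
pipeline reproduces — strong AP prolongation in the baseline model, ≤ 5 ms
APD50 prolongation in the multi-variable optimised model — holds for the
IC50-derived assignment on the endocardial models, and the baseline
prolongation holds under either assignment.

## Classifier

Points (x, y) = (relative APD50, relative diastolic [Ca²⁺]ᵢ); a boundary is
a line `n·p = b` with unit normal, the positive side being the risk side.
Its error E is the sum of squared Euclidean perpendicular distances of
miscategorised points (on-line points count as negative predictions and
contribute zero).  Fitting: if the set is linearly separable, the max-margin
separating line (hard-margin linear SVM) is returned with E = 0 as the
deterministic tie-break among zero-error lines; otherwise a coarse
(angle, offset) grid — both orientations of every direction — is refined by
Nelder–Mead.  On ≤ 12-point sets the fit matches a dense brute-force grid
oracle to 10⁻⁶.

Model comparison sets E* = 2 × the minimum fitted E across models and
reports each model's acceptable region: the (angle, offset) grid samples
with E < E*.  If some model separates perfectly (min E = 0) the definition
degenerates; regions are then computed against a configurable floor
(10⁻⁴) and flagged.  An empty region is meaningful: it marks a panel whose
miscategorisation error cannot be brought below threshold by any line.

## Synthetic data

The curated 86-entry drug table (68 compounds, two sources, duplicate
entries) is external to this package, so `synthetic.synth_drug_table`
emulates its schema and risk structure: EFTPC log-uniform over 10⁻³–10 µM,
IC50s over 10⁻²–100 µM; TdP-positive records draw IC50_Kr within ~0.1–3 ×
EFTPC (strong hERG block) and weak calcium block, TdP-negative records draw
milder Kr block with CaL co-block within a decade of it (the verapamil
archetype); a configurable fraction of compounds is duplicated under a
second source with log-normally jittered IC50s.  The generator reproduces
the qualitative statistic the classifier relies on (positives have lower
median Kr Hill fractions) but makes no claim of matching the real IC50
distributions; passing panel tests therefore demonstrate the pipeline's
mechanics and orderings, not clinical performance on real compounds.
`synth_separable_points` (two Gaussian clouds straddling a known line) and
`synth_objective` (surrogate or simulated-truth targets) are the classifier
and GA fixtures.  All generators are deterministic given a seed.

## Problem sizes

Full-fidelity runs (500 beats, 1 Hz) are used for every quantity compared
against a reference value: the baseline biomarkers, the sensitivity panel, the
optimised-model LQT verification and the verapamil contrast.  The GA and
panel machinery is exercised at the reduced scales listed above, chosen so
the whole suite runs on a single CPU in minutes while preserving the
properties being demonstrated.  `scripts/acceptance.py` re-runs the
reference-value checks from scratch (five 500-beat simulations).

## Known limitations

- β-adrenergic conditions, Markov I_Kr with state-dependent block,
  mid-myocardial cells, tissue/QT-level simulation and
  populations-of-models are out of scope by design.
- Drug block is a concentration-independent conductance scaling; no
  state- or voltage-dependent binding.
- The GA defaults describe the reference protocol scale; full-fidelity
  optimisation at that scale is a cluster workload and is not run in tests.
- APD measurement assumes a resting diastolic potential; non-repolarising
  parameter regimes are reported as failures rather than biomarkers.
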