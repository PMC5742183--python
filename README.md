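# lqtsim

In-silico assessment of drug-induced Torsades-de-Pointes (TdP) risk with a
human ventricular myocyte model optimised to clinical long-QT data.

Standard ventricular cell models reproduce healthy electrophysiology but
misrepresent the congenital long-QT syndromes: simulated LQT2 (loss of
I<sub>Kr</sub>) prolongs the action potential far more, and LQT1 (loss of
I<sub>Ks</sub>) far less, than patients' QT intervals do.  A model that gets
the repolarisation reserve wrong is a shaky basis for predicting
drug-induced arrhythmia.  `lqtsim` implements the full pipeline for fixing
and exploiting this: it simulates the O'Hara–Rudy (ORd) myocyte
(endocardial/epicardial), refits six conductance scalings to clinical LQT1–3
repolarisation targets with a genetic algorithm — constraining intracellular
Ca²⁺ and Na⁺ to physiological ranges — simulates multi-channel drug block,
and classifies drugs by TdP risk with a linear decision boundary in the
(APD₅₀, diastolic [Ca²⁺]ᵢ) plane.  It is intended for safety-pharmacology
modellers and cardiac-electrophysiology methodologists.

## Model summary

- **Cell model.**  ORd ionic model (41 states) with multiplicative scalings
  k on G<sub>Ks</sub>, G<sub>Kr</sub>, P<sub>CaL</sub>, G<sub>NCX</sub>,
  P<sub>NaK</sub>, G<sub>NaL</sub>; 1 Hz pacing, 500 pre-beats per
  perturbation, biomarkers from the final beat (APD₉₀/APD₅₀ from dV/dt-max
  to fractional repolarisation; diastolic/systolic [Ca²⁺]ᵢ; max [Na⁺]ᵢ).
- **LQT conditions.**  LQT1: k<sub>s</sub>×0.5.  LQT2: k<sub>r</sub>×0.5.
  LQT3: late-sodium multiplier k<sub>NaL</sub>×k<sub>NaL,LQT3</sub>, the
  second factor being a fitted parameter.
- **Objective.**  E = Σ<sub>c∈{control,LQT1,LQT2,LQT3}</sub>
  (APD₉₀<sup>sim</sup>(c) − APD₉₀<sup>target</sup>(c))², targets 267.97,
  301.14, 312.20, 311.55 ms; the multi-variable objective adds 200 ms² per
  control-condition concentration bound violated (diastolic [Ca²⁺]ᵢ
  0.05–0.15 µM, systolic 0.3–0.7 µM, [Na⁺]ᵢ 7–10 mM).
- **GA.**  Seven genes in log₁₀ space over [0.001, 10]; tournament
  selection, two-point crossover, Gaussian mutation, elitism; best of ten
  seeded runs.
- **Drug block.**  G<sub>x,drug</sub> = G<sub>x</sub>(1 + EFTPC/IC₅₀,ₓ)⁻¹
  for x ∈ {Kr, CaL, Na} (Hill coefficient 1).
- **Classifier.**  Line in the normalised (APD₅₀, diastolic [Ca²⁺]ᵢ) plane
  minimising E = Σ d² over miscategorised points; model comparison via the
  acceptability threshold E* = 2·min E and the region of boundary parameters
  with E < E*.

See `docs/methods.md` for assumptions, numerics and design decisions.

## Worked example

```python
from lqtsim import (MULTIVAR_SCALINGS, PacingProtocol, ScalingFactors,
                    measure, pace)
from lqtsim.perturbations import LQTSubtype, lqt_variant
from lqtsim.pipeline import VERAPAMIL, evaluate_drug

protocol = PacingProtocol()          # 1 Hz, 500 beats
baseline = measure(pace("endocardial", ScalingFactors(), protocol))
print(f"baseline: APD90 {baseline.apd90:.1f} ms, APD50 {baseline.apd50:.1f} ms,"
      f" Ca {baseline.ca_dia:.3f}-{baseline.ca_sys:.3f} uM, Na {baseline.na_max:.2f} mM")

lqt2 = measure(pace("endocardial", lqt_variant(ScalingFactors(), LQTSubtype.LQT2), protocol))
print(f"baseline LQT2: +{lqt2.apd90 - baseline.apd90:.1f} ms APD90")

mv_ctl = measure(pace("endocardial", MULTIVAR_SCALINGS, protocol))
mv_lqt2 = measure(pace("endocardial", lqt_variant(MULTIVAR_SCALINGS, LQTSubtype.LQT2), protocol))
print(f"multi-var LQT2: +{100 * (mv_lqt2.apd90 / mv_ctl.apd90 - 1):.1f} % APD90")

ver = evaluate_drug("endocardial", MULTIVAR_SCALINGS, VERAPAMIL, protocol)
print(f"multi-var + verapamil: +{ver.apd50 - mv_ctl.apd50:.1f} ms APD50")
```

prints

```
baseline: APD90 268.2 ms, APD50 208.3 ms, Ca 0.085-0.357 uM, Na 7.23 mM
baseline LQT2: +117.3 ms APD90
multi-var LQT2: +22.9 % APD90
multi-var + verapamil: +3.3 ms APD50
```

The unmodified model overshoots the clinical LQT2 prolongation (+117 ms,
i.e. +44 % against the 16.6 % seen in patients); the multi-variable
optimised scaling set (`MULTIVAR_SCALINGS`) brings it to +22.9 %.  Verapamil
— a strong hERG blocker that is nonetheless not torsadogenic — barely
prolongs APD₅₀ in the optimised model (+3.3 ms), because its concurrent
L-type block collapses the calcium transient and with it the inward NCX
current.  The same block prolongs the baseline epicardial AP by tens of
milliseconds: a false positive the optimisation removes.

A command-line interface mirrors the library
(`lqtsim simulate-baseline | sensitivity | optimize | drug-panel | classify |
compare`); each subcommand takes `--variant`, `--out` and where relevant
`--scalings`, `--drugs`, `--seed` and a `key=value` pacing config.

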