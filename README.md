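# silkflight

Quasi-steady blade-element analysis of silk-moth forward flight.

Wild silk moths (Saturniidae — here *Automeris io*, *Actias luna*,
*Antheraea polyphemus*, *Hyalophora euryalus*) fly with low wingbeat
frequencies and large wings, and their bodies visibly pitch and bob once
per wingstroke.  This package implements the modelling pipeline used to
ask what those body oscillations do aerodynamically: from 3-D landmark
tracks and wing morphology, through Fourier-fitted wing/body kinematics
and a trim-equilibrium search, to per-strip aerodynamic forces, power,
and comparisons between body-kinematics configurations.  It is written
for flight-biomechanics researchers who want a tested, scriptable
implementation of the method, with a synthetic-data generator so every
stage runs end to end without any external data.

## The model

Each (combined fore+hind) wing is a rigid flat plate cut into 200
spanwise strips.  Per strip of chord *c* and width *dr*, the quasi-steady
force is

    dF_L  = 1/2 ρ C_L(α_v) v² c dr        (lift, ⊥ airflow)
    dF_D  = 1/2 ρ C_D(α_v) v² c dr        (drag, ∥ airflow)
    dF_rot = ρ C_R v c² α̇_h dr            (rotational, ⊥ wing)
    dF_adm = π/4 ρ [(φ̈ sin α + φ̇ α̇_h cos α) r c² + α̈_h c³/4] dr   (added mass, ⊥ wing)

with empirical flat-plate polynomials `C_L = 1.552 sinα_v cosα_v +
1.725 sin²α_v cosα_v`, `C_D = 0.0596 sinα_v cosα_v + 3.598 sin³α_v`
(scaled by searchable factors k_L, k_D), `C_R = π(0.75 − ê)`, the angle
of attack `α_v = arccos(−b̂·v̂)` and the wing inclination `α_h = α − β`.
Wing and body kinematics (sweep φ, deviation θ, feathering α,
stroke-plane angle β, body pitch χ, velocities u, w) are third-order
Fourier series at the wingbeat frequency f.  Steady flight is imposed by
minimizing the trim residual

    G = (F̄_x/mg)² + (F̄_z/mg − 1)² + (M̄_y/(mg r₂))²

over 14 bounded parameters (per-species measured bounds ship with the
package), multi-starting a bounded derivative-free search until 10
distinct zero-residual solutions are found.  Body-oscillation effects
are isolated by re-simulating each trimmed moth under altered body
kinematics: model 1 (as measured), model 2 (body frozen at wingstroke
means), model 3 (body anti-phased by half a period), and intermediates
1a/1b.  See `docs/methods.md` for conventions, assumptions and
limitations.

## Worked example

```python
from silkflight import simulate_wingstroke
from silkflight.synth import SynthSpec, synth_near_trim_moth
from silkflight.trim import TrimBounds, search_trim
from silkflight.models import compare_variants

moth = synth_near_trim_moth(SynthSpec(seed=1, bounds="actias_luna"))
sols = search_trim(moth, TrimBounds.from_species("actias_luna"),
                   n_solutions=3, seed=3, on_exhausted="partial")
best = min(sols, key=lambda s: s.G)
print(f"G = {best.G:.2e}")
res = simulate_wingstroke(best.config)
print(f"weight support = {res.Fz_mean / best.config.weight:.4f}")
df = compare_variants(best.config, ("model1", "model2", "model3"))
print(df[["P_mean_W", "P_mean_ratio_vs_model1"]].round(3))
```

prints (machine-dependent only in runtime, not in values):

```
G = 1.56e-10
weight support = 1.0000
         P_mean_W  P_mean_ratio_vs_model1
variant
model1      0.296                   1.000
model2      0.429                   1.451
model3      0.744                   2.515
```

The trimmed synthetic moth supports its weight (trim residual ~1e−10,
mean vertical force = mg to four decimals), and freezing its body
oscillations (model 2) or anti-phasing them (model 3) raises the mean
aerodynamic power by ~1.5× and ~2.5× — the power-saving signature of
body oscillations phase-locked to the wingstroke.

The same pipeline is scriptable from a shell:

```
silkflight synth --seed 7 --species actias_luna --near-trim --out-dir run
silkflight fit --landmarks run/landmarks.csv --out-dir run
silkflight trim --moth run/moth.json --species actias_luna --out-dir run
silkflight compare --moth run/moth.json --solutions run/trim_solutions.csv --out-dir run
```

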