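# planotaxis

Binocular-field phototaxis model and trajectory analytics for planarian
orientation behavior.

Planarians (*Dugesia japonica* and relatives) show robust negative
phototaxis despite carrying only two nondioptric pigment-cup eyes. Each
eye is shaded on one side, so its input is well approximated by a
clamped sine of the light bearing θ relative to the body axis:

    L(θ) = max(0, −sin(θ − bf/2)),   R(θ) = max(0, sin(θ + bf/2)),

where *bf* is the anterior binocular field created by the eyes'
obliqueness (≈40° in *D. japonica*). The animal turns away from the
brighter side when the input disparity exceeds a response threshold τ:

    Δφ = −sign(R − L) · gain · (|R − L| − τ)   (radians; τ = 0.5, gain = 3),

and otherwise glides straight. Thresholding creates a *front blind-like
spot* (|θ| ≲ 15° at bf = 40°, τ = 0.5) and a posterior blind field where
the light's side cannot be sensed. The missing ingredient is *wigwag*
head sway — spontaneous side-to-side head motion with angles
~Normal(0, 18.7°²) at log-normal intervals (μ = −0.15, σ = 0.44, in
seconds) — which lets an animal facing the light sample bearings outside
the blind-like spot: about 42% of sways exceed the 15° spot, so the
animal turns away within ~1.7 s. The package couples these pieces into
an event-driven arena simulator and provides the assay statistics
(mean resultant length and precision index 1/√(−2 ln R), escape value,
twin-tail separation, rose histograms, turn-vs-light regression, wigwag
extraction and maximum-likelihood distribution fits), plus a synthetic
video-tracking generator so every statistic is testable without
laboratory data.

Audience: computational ethologists and modellers studying directional
sensing with minimal sensors, and anyone needing reproducible trajectory
summaries for orientation assays.

## Worked example

```python
import planotaxis as pt

geom = pt.EyeGeometry(binocular_field=40.0)
print("input difference at 130 deg:", abs(pt.input_difference(130.0, geom)))
low, high = pt.response_band(geom, tau=0.5)
print(f"response band: ({low:.2f}, {high:.2f}) deg")
spot = pt.front_blind_half_angle(geom, tau=0.5)
print(f"front blind-like spot: +/-{spot:.2f} deg")
p = pt.exceedance_probability(15.0, 18.7)
print(f"sway exceedance: {100*p:.1f}%")
print(f"expected turn-away time: {pt.expected_turnaway_time(p, 0.7):.2f} s")

cfg = pt.SimulationConfig(seed=42)
table = pt.sweep_binocular_field([0.0, 40.0, 80.0], n=250, config=cfg)
print(table.to_string(index=False))
```

prints

```
input difference at 130 deg: 0.49999999999999994
response band: (15.43, 130.00) deg
front blind-like spot: +/-15.43 deg
sway exceedance: 42.2%
expected turn-away time: 1.66 s
 bf_deg   n  mean_escape  sd_escape
    0.0 250     0.839043   0.232292
   40.0 250     0.908678   0.076010
   80.0 250     0.884119   0.088225
```

Reading the output: a 40° binocular field puts the response threshold
crossing at a light bearing of 130° (input disparity exactly 0.5) and
the anterior ambiguity at ±15°. In the simulated escape sweep the mean
escape value (net displacement away from the light per unit path; 1 =
ideal straight escape) peaks at bf = 40°, while the cohort without a
binocular field fluctuates far more (sd 0.23 vs 0.08) because some of
its agents wander toward the light before their sway lets them sense its
side — the binocular field and the sway amplitude are jointly tuned.

## Command line

```
planotaxis simulate -c config.yaml -o out/        # cohort -> TSV + summary CSV
planotaxis sweep -c config.yaml --bf 0 --bf 40 --bf 80 --n 250 -o out/
planotaxis analyze out/trajectories.tsv -o analysis/
planotaxis fixtures --n-animals 10 -o fixtures/   # synthetic tracking + ground truth
```

Every command writes a `manifest.json` (config snapshot, seed, version,
outputs) next to its outputs. See `src/planotaxis/config.py` for the
config schema; `docs/methods.md` for the model, parameter defaults and
design choices.

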