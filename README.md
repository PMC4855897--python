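# dispersal-ssf

Habitat selection during ungulate dispersal, analysed at two scales from
GPS telemetry — with a synthetic world that makes every stage testable
against known ground truth.

Dispersal is hard to study: even in a large collared cohort only a
handful of animals (almost all young males) relocate permanently, yet
corridor planning routinely assumes that habitat selection measured
inside home ranges extrapolates to dispersal movement. This package
implements the analysis chain used to test that assumption on elk
(*Cervus elaphus*) telemetry, as a reusable, fully tested pipeline:

1. **Movement typing** — net squared displacement
   NSD(t) = ‖x(t) − x(0)‖² is fitted with four nonlinear models
   (resident: NSD = c; dispersal: NSD = δ/(1 + e^{(θ−t)/φ});
   migration: a mirrored double logistic; nomadism: NSD = bt), ranked by
   AICc, and the winning shape codified into
   migrant / resident / disperser / exploratory / other. Dispersal
   windows are resolved to the day by inverting the fitted logistic at
   2.5% and 97.5% of δ; dispersers are paired in time with matched
   residents.
2. **Behavioural segmentation** — movement rates are compared across the
   before / during / after / rest-of-year periods with a random-intercept
   mixed model, and the during-dispersal rate distribution is split by a
   broken-stick (segmented) regression on binned log-frequencies into
   short (foraging/resting) and long (directed travel) steps at
   ψ × 120 min (e.g. ψ = 7.118 m min⁻¹ → 854 m).
3. **Fine-scale SSF** — each observed step is matched with 10 random
   steps drawn from leave-one-individual-out step-length (50 m) and
   turn-angle (10°) histograms, and selection
   ŵ(x) = exp(β₁x₁ + … + β_px_p) over scaled terrain ruggedness (+²),
   NDVI, distance to roads and canopy (+²) is estimated by conditional
   logistic regression, pooled across individuals by REML random-effects
   combination, and validated by k-fold cross-validation against a
   within-stratum permutation null (useful ⇔ mean r_S > 0.65 and above
   chance).
4. **Broad-scale CRW test** — each dispersal route is compared with 10
   correlated-random-walk alternatives built from the individual's own
   long-step kernels; per-individual binomial GLMs are averaged and each
   covariate tested with an exact one-sample Wilcoxon signed-rank test.

Because the original telemetry is not public, the package ships a
first-class synthetic world: landscapes (elevation/ruggedness, monthly
NDVI, roads, canopy as plain-text rasters) and multi-individual
trajectories generated by a discrete-choice SSF under known selection
coefficients, with resident / migrant / disperser / exploratory NSD
signatures, 2-h fixes thinned by realistic collar fix success
(81.7% / 66.2%), and out-and-back position outliers. Every estimator is
tested by parameter recovery and calibration against this ground truth.

## Worked example

```python
import numpy as np
import dispersal_ssf as ds

land = ds.generate_landscape((120_000, 120_000), rng_seed=1,
                             terrain_cell=150, ndvi_cell=500)
traj, truth = ds.simulate_trajectory(land, "disperser",
                                     rng=np.random.default_rng(11))

screened, removed = ds.screen_outliers(traj)
nsd = ds.compute_nsd(screened)
cls = ds.classify_trajectory(nsd, "elk-001", require_span=None)
event = ds.extract_dispersal_event(nsd, cls.winning_fit, screened)
print(cls.assigned_type, cls.rationale)
print(f"dispersal days {event.start_day:.0f}-{event.end_day:.0f} "
      f"({event.duration_days:.0f} d), {event.straight_line_km:.1f} km; "
      f"true duration {truth['dispersal_duration_days']:.0f} d")
```

prints

```
disperser ['dispersal_wins_sustained_plateau']
dispersal days 63-76 (13 d), 59.1 km; true duration 13 d
```

— the NSD graph is classified as a completed dispersal, the fitted
logistic puts the event at days 63–76 (matching the simulated 13-day
duration exactly), and the straight-line displacement inside the
extracted window is reported in km. The full chain — simulate, screen,
classify, segment, fit the eight SSF models, run the CRW test, and write
CSV reports plus a reproducibility manifest — runs with one command:

```bash
dispersal-ssf run-all --seed 3 --out runs/demo
```

Subcommands `simulate`, `screen`, `classify`, `segment`, `ssf` and `crw`
expose the individual stages on the same CSV/ASCII-grid formats.

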