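# myxotrack

Multiscale single-cell analysis of predatory bacterial swarms.

*Myxococcus xanthus* hunts prey bacteria collectively: thousands of gliding
cells organize into dense swarms, crowded "loner" cells at the colony
front, and small isolated scout groups that venture ahead of the invasion
front. `myxotrack` quantifies this behaviour from time-lapse microscopy
segmentations — per-frame integer label masks for the predator and a
fluorescence channel for the prey lawn — and ships a synthetic
predation-scene simulator that generates both, with full ground truth, so
every stage of the analysis can be validated without raw microscopy data.

It is a library for people who study collective motility and predation in
surface-dwelling bacteria: each analysis stage is an importable module, the
`examples/` scripts show one capability each, and a thin `myxotrack` CLI
runs the pipeline end to end.

## What it computes

- **Tracking** — frame-to-frame linking of cell masks scored by a weighted
  combination of mask overlap, area and backbone length. Weights come from
  the Analytic Hierarchy Process: for a positive reciprocal
  pairwise-comparison matrix *A*, the weight vector *w* is the normalized
  principal eigenvector, *A w = λ_max w*. Links are assigned one-to-one per
  frame pair by the Hungarian algorithm and chained into tracks; mask
  fusions terminate incoming tracks.
- **Spatial context** — per cell and frame: the skeleton ("backbone") of
  the mask, split at branchpoints; the Voronoi polygon area *V* (px²) of
  its backbone midpoint, clipped to the field (1/*V* is local density); and
  the cluster size *N* = (summed member mask area) / (mean single-cell
  area), where clusters are connected components after dilating the binary
  masks with a 10 × 10 px kernel (~1 × 1 µm).
- **Classification** — each cell-frame gets a population class from
  (*V*, *N*): loner if log₁₀ *V* ≤ 4.5 and *N* ≤ 2; scout if log₁₀ *V* ≥ 4.5
  and *N* ≤ 20; swarm if log₁₀ *V* ≤ 4.5 and *N* > 2. Motile cells are those
  with end-to-end track displacement strictly above 2 px.
- **Motion statistics** — instantaneous speed over a ±5-frame window;
  gyration radius (mean distance of trajectory points from their centroid);
  and the MSD directionality exponent α, the log–log slope of the
  time-averaged mean squared displacement over its first five lags:
  α < 1 confined, α = 1 Brownian, α > 1 directed.
- **Transition kinetics** — class series smoothed by a 10-frame rolling
  modal filter; 3 × 3 transition matrices over change events; triangle
  embedding of class trajectories.
- **Trail analysis** — trajectories rasterized into trail maps; structural
  similarity (SSIM, 3-px window) between the binarized scout and non-scout
  maps; connected shared-trail segments and their areas.
- **Prey consumption** — prey fluorescence normalized by the Gaussian
  excitation profile, split into predation / middle / safe bands along the
  invasion axis; the predation-to-safe intensity ratio cancels bleaching and
  an exponential fit gives the lysis decay time τ.

## Worked example

```sh
python examples/motion_regimes.py
```

```
confined (R = 3 px)          mean alpha = 0.751 (sd 0.067, n = 300)
brownian (sd = 1 px)         mean alpha = 0.990 (sd 0.095, n = 300)
directed (v = 1 px/frame)    mean alpha = 1.995 (sd 0.001, n = 300)
```

Three simulated ensembles of 300 trajectories each recover the three
motion regimes from their MSD exponents: walkers confined to a 3-px disk
are strongly subdiffusive, unbiased random walks sit at α ≈ 1, and
persistent directed motion is near-ballistic.

```sh
python examples/prey_decay.py
```

```
fitted illumination sigma: 45.0 px (true 45.0)
predation zone: intensity falls to 0.139 of frame 0
middle    zone: intensity falls to 0.656 of frame 0
safe      zone: intensity falls to 0.674 of frame 0

predation-zone decay time tau = 50.0 frames (true 1/lysis = 50)
safe zone non-decaying after bleach correction: True
```

On a simulated scene with lysis rate 0.02 frame⁻¹ confined to the invaded
band, the pipeline recovers the excitation profile, sees the predation zone
decay far faster than the safe zone (which only bleaches), and recovers
τ = 1/rate exactly after bleach correction.

The other examples cover scene simulation (`simulate_scene.py`), tracking
plus classification (`track_and_classify.py`), transition kinetics
(`transition_kinetics.py`), trail sharing (`trail_sharing.py`) and the full
pipeline with its artifact manifest (`run_pipeline.py`). The CLI mirrors
the pipeline: `myxotrack all --config config.yaml --seed 7 --out out/`.

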