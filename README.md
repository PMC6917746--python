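# embryoflow

Pan-embryo, multi-scale analysis of zebrafish gastrulation from single-cell
tracking data: germlayer-resolved trajectory statistics, internalization
analysis, gridded tissue flow fields, epiboly/convergence decomposition,
inter-layer correlation and residual-motion maps — plus the image-side
preprocessing (two-sphere fitting, shell-masked storage, nucleus detection,
rigid time-lapse registration, channel subtraction) that turns light-sheet
stacks into such tables, and a synthetic embryo simulator so every stage is
testable without microscope data.

## Who this is for

Developmental biologists and image analysts working with in-toto light-sheet
recordings of gastrulating embryos, who have per-cell tracking tables (e.g.
from TGMM) with germlayer labels and want quantitative, embryo-centric
summaries of how cells and tissues move.

## The model

The embryo is treated as a sphere with an embryo-centric spherical frame:
radius *r*, longitude *θ* ∈ (−π, π] with 0 at the dorsal midline (the
shield), and latitude *ϕ* ∈ [−π/2, π/2] with −π/2 at the animal pole.
Gastrulation movements then have natural coordinates: **epiboly** is motion
along meridians (animal → vegetal, increasing *ϕ*), **dorsal convergence**
is motion along parallels toward *θ* = 0, and **internalization** is radial
inward motion at the margin followed by animal-ward drift.

Core statistics:

* **Straightness index** of a trajectory *x*(1..N):
  `SI = ‖x(N) − x(1)‖ / Σₖ ‖x(k+1) − x(k)‖ ∈ [0, 1]` — 1 for ballistic,
  → 0 for random or closed paths. Computed on short non-overlapping windows
  (10 frames ≈ 20 min) and correlated with position (r, θ, ϕ), with 90%
  bivariate-normal prediction ellipses per germlayer.
* **Flow fields**: consecutive-frame displacements are unit-normalized in a
  conformal Mercator projection (u = θ, v = arctanh sin ϕ), averaged on a
  40 × 40 grid over 10 time intervals, with observation counts as weights.
* **Movement decomposition**: the local flow direction **v** is projected
  onto unit reference fields for pure epiboly and pure convergence,
  s = **v**·**ref**, mapped to a proportion
  `p = 1 − (2/π)·arccos(s)` for s > 0 (else 0), and summarized per interval
  as the observation-weighted mean `o(t) = Σ p·w / Σ w`.
* **Circular correlation** between two layers' flow directions α, β over
  shared grid sites: `ρ = Σw sin α sin β / √(Σw sin²α · Σw sin²β)`.
* **Relative layer motion**: per mesendoderm cell, its 10-min motion vector
  minus the mean motion of its six nearest epiblast neighbours, in
  spherical components (µm), gridded and density-summarized.

## Worked example

```python
import numpy as np
from embryoflow import EmbryoSimConfig, SphericalFrame, simulate_embryo_tracks
from embryoflow import flows, tracks

cfg = EmbryoSimConfig(n_cells=300, t_end=14.0, seed=1)
observed, truth = simulate_embryo_tracks(cfg)
frame = SphericalFrame.canonical(cfg.embryo_radius)

si = [tracks.straightness_index(t) for t in observed]
print(f"tracks: {len(observed)}, median SI: {np.nanmedian(si):.3f}")

field = flows.build_flow_field(observed, frame)
dec = flows.decompose_movement(field)
for t, (oe, oc) in enumerate(zip(dec.o_epi, dec.o_conv)):
    print(f"interval {t}: o_epi={oe:.2f}  o_conv={oc:.2f}")
```

Output:

```
tracks: 300, median SI: 0.529
interval 0: o_epi=0.95  o_conv=0.03
interval 1: o_epi=0.94  o_conv=0.06
interval 2: o_epi=0.77  o_conv=0.15
interval 3: o_epi=0.74  o_conv=0.17
interval 4: o_epi=0.63  o_conv=0.25
interval 5: o_epi=0.43  o_conv=0.37
interval 6: o_epi=0.23  o_conv=0.61
interval 7: o_epi=0.11  o_conv=0.71
interval 8: o_epi=0.05  o_conv=0.82
interval 9: o_epi=0.05  o_conv=0.84
```

The simulator's default flow profiles have epiboly peaking early (5–9 hpf)
and convergence late (8–12 hpf); the decomposition recovers exactly that
hand-over: the epiboly proportion `o_epi` dominates the first half of the
run and the convergence proportion `o_conv` the second. The median
window-level SI of ≈ 0.5 reflects directed flow plus the configured 1 µm
positional noise.

The full pipeline also runs from the shell:

```sh
embryoflow all --seed 1 --out run1        # simulate → preprocess → tracks → flows → export
embryoflow simulate --seed 1 --out run2   # single stage
```

Each run writes a `manifest.json` with SHA-256 hashes of every output;
identical config + seed gives identical hashes.

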