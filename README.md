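# tumblecm

Inference of bacterial run-and-tumble motility parameters and chemotactic
strategy from 2D single-cell trajectories, using absolute conditional
moments of the heading angle.

## The problem

Swimming bacteria such as *E. coli* alternate nearly straight **runs**,
perturbed only by rotational Brownian motion, with brief **tumbles** that
reorient the cell by a random angle β. Classical analyses first *detect*
tumbles with a heuristic recognizer (thresholds on speed dips and turn-rate
peaks) and then build statistics from the detected events; the thresholds
are hand-tuned. `tumblecm` instead infers the motility parameters directly,
without event detection, and derives a principled recognizer afterwards.

The heading angle Θ(t) is modeled as rotational diffusion plus shot noise:

    dΘ = dB + dN,     dB ~ N(0, 2 D_rot dt),
    dN = Poisson(λ dt) tumbles with angles ±|β|, |β| ~ P(|β|) on [0, π].

For a finite lag Δt the *n*-th absolute conditional moment

    m^n(θ) = ⟨ |Θ(t+Δt) − Θ(t)|_a^n / Δt | Θ(t) = θ ⟩,
    |α|_a = min(|α|, 2π − |α|),

has a closed form to leading order in λΔt and D_rotΔt, e.g.

    m¹ = λ⟨|β|⟩ + 2(1 − λΔt)√(D_rot/(πΔt)),
    m² = 2 D_rot + λ⟨β²⟩,
    m⁴ ≈ λ(⟨β⁴⟩ + 12 D_rot Δt ⟨β²⟩),   …

Matching these to moments measured from tracked positions (a least-squares
fit) yields the tumble rate λ, the rotational diffusion coefficient D_rot,
and the parameters of the tumble-angle distribution — a truncated-gamma
family γ(σ, k) for *E. coli*-like tumbling or a reversal-peaked family for
*P. putida*-like swimming. Conditioning the moments on the heading θ
relative to a chemical gradient resolves the chemotactic strategy:

* **rate bias** (classical chemotaxis): λ(θ) = a₁ + a₂cos θ, lowest
  up-gradient;
* **angle bias**: the mean tumble angle ⟨|β|⟩(θ) shrinks up-gradient, which
  shows up as CM ratios m^n(θ)/m^n(π) *increasing* with the order n.

The same fitted densities give a Neyman–Pearson tumble recognizer: a lag
step is called a tumble when its turn magnitude exceeds the critical angle
dΘ_crit fixed by the chosen miss probability α₁, with the false-alarm
probability α₂ reported alongside.

## Worked example

Simulate an ensemble with known ground truth and re-infer its parameters:

```python
import numpy as np
from tumblecm import (GammaTumbleDist, SimConfig, simulate_ensemble,
                      headings_from_trajectories, empirical_cms,
                      fit_parameters, np_thresholds, ThermalStep)

dist = GammaTumbleDist(sigma=0.64, k=2.73)   # mean 85.4 deg, std 41.8 deg
cfg = SimConfig(lambda0=0.39, d_rot=0.06, tumble_dist=dist,
                n_tracks=500, duration=10.0, seed=20170123)
headings = headings_from_trajectories(simulate_ensemble(cfg))
fit = fit_parameters(empirical_cms(headings, dt=0.1, orders=(1, 2, 3, 4)))
print(fit.as_dict())
```

prints (numbers produced by this exact snippet):

```
{'lambda': 0.394633..., 'd_rot': 0.060102..., 'sigma': 0.729892...,
 'k': 2.431949..., 'mean_angle': 1.468567...}
```

i.e. λ recovered within 1.2%, D_rot within 0.2%, and the mean tumble angle
1.469 rad = 84.1° within 1.5% of the generating 85.4°. (σ and k individually
trade off along a ridge of nearly constant mean; the mean angle is the
robustly identified combination.) Building the
recognizer from the fitted law at the standard operating point:

```python
thr = np_thresholds(dist, ThermalStep(d_rot=0.05, dt=0.5), alpha1=0.05)
print(round(np.degrees(thr.dtheta_crit)), round(thr.r_crit, 1), round(thr.alpha2, 2))
# 24 2.3 0.06
```

A turn larger than 24° is called a tumble; 5% of true tumbles are missed
and 6% of purely thermal steps are mislabeled.

The same workflow is available from the shell:

```bash
tumblecm simulate --n-tracks 500 --seed 1 --out-dir sim/
tumblecm infer --tracks sim/tracks.csv --dt 0.1 --orders 1,2,3,4 \
               --seed 1 --out-dir results/
tumblecm recognize --tracks sim/tracks.csv --params-json results/params.json \
               --out calls.csv
tumblecm ratios --tracks sim/tracks.csv --theta 0.0 --seed 1 --out ratios.csv
```

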