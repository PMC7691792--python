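# lcanet

Response geometry, selectivity, and adversarial robustness of
lateral-inhibition sparse-coding networks — a synthetic-data analysis
pipeline for computational neuroscientists and ML researchers studying
population nonlinearities.

## The question

A standard feedforward layer applies a pointwise nonlinearity to a linear
projection, `aₖ = g(Φₖᵀs)`. Its iso-response surfaces — the sets of stimuli
producing equal activation — are flat hyperplanes orthogonal to the weight
vector, so a stimulus can drift arbitrarily far from the neuron's preferred
feature without changing its response. A sparse-coding network computes its
code instead through recurrent competition: the locally competitive
algorithm (LCA) evolves membrane potentials

    u̇ = (1/τ)(Φᵀs − G̃ a − u),   a = T_λ(u),

where the lateral inhibition `G̃ = ΦᵀΦ` (diagonal removed) couples every
neuron to its overlapping neighbors and `T_λ` is a nonnegative soft
threshold. At its fixed point this minimizes the sparse-coding energy
`½‖s − Φa‖² + λ‖a‖₁` over `a ≥ 0`. The resulting *population* nonlinearity
curves the iso-response surfaces outward (exo-origin), which this package
measures and connects to two consequences:

* **selectivity** — sharper orientation tuning (lower circular variance)
  and far fewer "selected images" than a control with *identical*
  feedforward weights;
* **robustness** — gradient-based adversarial attacks, which travel
  orthogonally to iso-response contours, are forced toward the weight
  vectors and need larger perturbations to reach a target confidence.

All inputs are synthetic and seeded: sparse patches drawn from a
ground-truth Gabor generative model `s = Φ*a + ε`, sinusoidal grating
batteries, and a labelled bar-composite image set for attack experiments.
See `docs/methods.md` for the full model, parameter and protocol account.

## Worked example

```python
import numpy as np
from lcanet import (Dictionary, LCAEncoder, LCAParams, LinearEncoder,
                    make_gabor_dictionary, make_grating_battery)
from lcanet.geometry import make_comparison_plane, response_grid, fit_curvature
from lcanet.selectivity import population_circular_variance

dictionary = Dictionary.from_columns(make_gabor_dictionary(8, 8, 128, seed=42))
lca = LCAEncoder(dictionary, LCAParams(lam=0.2, n_steps=150, step=0.05))
linear = LinearEncoder(dictionary)          # identical-weights control

# iso-response curvature in the plane of two overlapping neurons
overlaps = np.abs(dictionary.lateral()[0])
plane = make_comparison_plane(dictionary, 0, int(np.argmax(overlaps)))
for name, enc in [("lca", lca), ("linear", linear)]:
    rec = fit_curvature(response_grid(enc, plane), level=0.5)
    print(f"{name:6s} c_iso={rec.c_iso:+.4f}  c_att={rec.c_att:+.4f}")

# orientation selectivity on a shared grating battery
battery = make_grating_battery(8, 8, n_orientations=32, n_phases=8,
                               frequencies=(0.1, 0.2, 0.3))
for name, enc in [("lca", lca), ("linear", linear)]:
    cv = population_circular_variance(enc, battery)["cv"]
    print(f"{name:6s} median CV = {cv.median():.3f}")
```

Output:

```
lca    c_iso=+0.2000  c_att=+0.0548
linear c_iso=+0.0000  c_att=-0.0000
```

The LCA neuron's half-maximum contour bends away from the origin
(`c_iso > 0`, exo-origin: displacing the stimulus toward the competing
neuron attenuates the response, so staying on-contour requires more drive)
and its response falls off away from the weight-vector axis (`c_att > 0`);
the identical-weights linear control is flat in both senses.

```
lca    median CV = 0.391
linear median CV = 0.505
```

Circular variance is 0 for a perfectly orientation-locked neuron and 1 for
an untuned one: the same filters are markedly more sharply tuned when read
out through lateral competition (the gap widens further for trained
dictionaries — the acceptance run reports medians of 0.31 versus 0.58).

The end-to-end studies are also available from the shell:

```
lcanet curvature   --seed 1 --out-dir runs/curv
lcanet selectivity --seed 1 --out-dir runs/sel
lcanet robustness  --seed 1 --out-dir runs/rob
lcanet synth --kind patches --n 1000 --output stimuli
```

Each writes CSV/JSON tables stamped with the config hash and seed; YAML
configs (`--config`) override the desk-scale defaults, including a
`paper_scale_config()` preset (16×16 patches, 100 neurons, 300 planes per
method, 100,000 probe images).

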