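# morphsel

Geometric morphometrics and multivariate selection analysis for
landmark-based shape traits, built around the two-episode (pre- vs
post-copulatory) sexual-selection design used in studies of insect
genital evolution — for example, selection on the aedeagus of the
broad-horned flour beetle *Gnatocerus cornutus*, where mating success
(binary: did a courted female copulate?) and fertilization success
(offspring sired after a single mating) are scored on separate males
sharing one morphological space.

## Who this is for

Evolutionary biologists estimating the strength and form of selection
on size and shape: you have digitized 2-D landmark outlines (TPS
files, with semilandmarks declared in a slider file), a body-size
measurement, and per-individual fitness in one or more selective
episodes, and you want standardized selection gradients with
permutation inference, the canonical rotation of the nonlinear
gradients, episode comparisons, and fitness-surface plots.

## The model

Shape is quantified by generalized Procrustes superimposition (with
semilandmarks sliding along the outline to minimize thin-plate-spline
bending energy), centroid size
`CS = sqrt(sum_i |x_i - centroid|^2)`, and relative warps (principal
components of the aligned coordinates). Selection on the standardized
trait vector **z** = (PW, CS, RW1, RW2, RW3) is estimated in the
Lande–Arnold framework from relative fitness *w* (fitness divided by
its episode mean):

- directional gradients **β** from the first-order regression
  `w = a + β'z + e`;
- quadratic/correlational gradients **γ** from the full second-order
  regression `w = a + b'z + ½ z'γ z + e`, with the quadratic
  coefficients doubled so the γ diagonal is on the
  stabilizing/disruptive scale;
- significance by randomization: fitness shuffled across individuals
  (9999 permutations by default), two-tailed p per coefficient with an
  add-one correction;
- canonical analysis: γ = M' Λ M locates the major axes **m**_i of
  nonlinear selection, with curvature λ_i and directional gradient
  θ_i per axis estimated by double regression on the rotated scores;
  eigenvalue significance uses a rank-matched permutation test (each
  shuffle re-estimates and re-diagonalizes its own γ);
- episode differences by sequential model building: partial *F*-tests
  on episode × term interactions, block by block (linear, then
  quadratic, then correlational);
- fitness surfaces by penalized thin-plate splines with
  GCV-selected smoothing over pairs of canonical axes.

A synthetic-data generator emulates the full study design (outline
landmarks with low-rank shape covariance plus digitizing noise, body
size weakly correlated with genital size, logistic binary mating
success at a 49% rate, zero-inflated offspring counts) with known
ground truth, so every stage is testable without access to raw
specimen data.

## Worked example

Generate a synthetic study at the design sample sizes (500 mating
trials, 508 fertilization trials), align all specimens into one shape
space, and estimate selection during mating:

```python
import numpy as np, pandas as pd
from morphsel import GeneralizedProcrustes, SelectionGradientModel, centroid_size
from morphsel.simulate import default_truth, generate_study

mating, fert = generate_study(default_truth(), seed=42)
coords = np.concatenate([mating.landmarks.coords, fert.landmarks.coords])
fit = GeneralizedProcrustes(coords).fit()          # pooled alignment
scores = fit.relative_warps()
traits = pd.DataFrame({
    "pw": np.concatenate([mating.traits["pw"], fert.traits["pw"]]),
    "cs": centroid_size(coords),
    "rw1": scores.scores[:, 0],
    "rw2": scores.scores[:, 1],
    "rw3": scores.scores[:, 2],
})
res = SelectionGradientModel(
    traits.iloc[:mating.n], mating.fitness, episode="mating"
).fit(n_perm=9999, seed=1)
print(res.summary())
print(res.canonical(n_perm=9999, seed=2).summary())
```

This prints (abridged):

```
Selection gradient estimates (mating episode)
n = 500, permutations = 9999

   trait      beta       SE        p
      pw   -0.0382   0.0453   0.4074
      ...

gamma (lower triangle; diagonal doubled):
               pw       cs      rw1      rw2      rw3
      pw  -0.166*
      cs   0.125*  -0.254*
      ...

Canonical analysis of gamma
 axis       pw       cs      rw1      rw2      rw3    theta   lambda
   m1   -0.010    0.511    0.767    0.298   -0.248  -0.034    0.096
   ...
   m5   -0.426    0.742   -0.464    0.086    0.214   0.098*  -0.481***
sum(lambda) = -0.792 = trace(gamma)
```

The three leading relative warps of this synthetic study carry ~85% of
the shape variance (the generator plants three axes over a digitizing
noise floor), and the recovered γ is stabilizing along its trailing
canonical axes — the structure the generator planted. Negative λ with
small θ means a fitness peak at intermediate phenotypes on that axis.

The package also installs a `morphsel` command with subcommands
`simulate`, `align`, `gradients`, `canonical`, `compare`, `surfaces`,
`repeatability` and `run-all`; see `morphsel --help`.

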