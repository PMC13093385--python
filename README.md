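# pedaccum

Pedigree-accumulation estimation of parental abundance.

For semelparous species such as Pacific salmon, the adults that actually
spawned are nearly impossible to census directly: spawning kills them, and
sampling beforehand disturbs the very event of interest. But every juvenile
in a cohort is genetically "marked" by exactly two parents, so a single
within-cohort sample of offspring with reconstructed sibship carries
information about how many parents (**N_P**) produced the cohort — new
unique parents accumulate with sample size the way new species accumulate
in a richness survey. `pedaccum` estimates N_P from such a sample with three
estimators, and ships the simulation machinery needed to validate them:

* **Chao1** — the bias-corrected nonparametric lower-bound estimator
  driven by singleton and doubleton parents:
  `N̂ = N_DET + [a₁(a₁−1) / (2(a₂+1))]·(N_OBS−1)/N_OBS`,
  with its classic variance and a log-transform 95% CI.
* **iChao1** — Chao1 plus a tripleton/quadrupleton correction
  (`+ a₃/(4a₄)·max(a₁ − a₂a₃/(2a₄), 0)`), always ≥ Chao1, with a
  delta-method variance.
* **A hierarchical Bayesian data-augmentation model** — the detection
  vector *y* (offspring counts per detected parent) is padded with zeros to
  length `L = 50·N_DET` and modeled as
  `z_j ~ Bernoulli(ψ)`, `y_j ~ Binomial(N_OBS, z_j·p)`, `N_P = Σ z_j`,
  with flat Beta priors on the occupancy ψ and detection probability p.
  The fully conjugate posterior is sampled by an exact Gibbs scheme with
  Gelman–Rubin convergence checks and 95% highest-posterior-density
  intervals.

The package also provides a salmonid-style breeding-cohort simulator
(Poisson mate numbers, uniform 2500–6500 per-female fecundity), injectors
for Type I (false-positive) and Type II (false-negative) sibship
reconstruction errors, and a benchmarking harness computing bias, CV, RMSE
and interval coverage over scenario grids.

## Worked example

```python
import numpy as np
import pedaccum as pa

scen = pa.BreedingScenario(n_females=25, n_males=25, seed=7)   # true N_P = 50
rng = np.random.default_rng(7)
ped = pa.simulate_breeding(scen, rng)
sample = pa.sample_offspring(ped, 30, rng)                     # 30 juveniles
d = pa.build_detection_vector(sample)

print(pa.chao1(d).summary())
print(pa.ParentAugmentationModel(d).fit(seed=7).summary())
```

```
chao1 parental-abundance estimate
------------------------------------------
detected parents (N_DET)           34
offspring sampled (N_OBS)          30
N_P estimate                   48.790
variance                      118.320
95% CI                     [38.076, 87.663]
Bayesian data-augmentation abundance estimate
----------------------------------------------
detected parents (N_DET)           34
offspring sampled (N_OBS)          30
augmented length (L)             1700
N_P posterior median            46.00
95% HPD                    [37.0, 60.0]
psi median                     0.0270
p median                       0.0439
R-hat: n_p=0.999, psi=1.006, p=1.008
converged (max R-hat < 1.1): True
```

Thirty sampled offspring named 34 distinct parents; the true abundance is
50. Chao1 extrapolates the 18 singleton parents to 48.8 with a wide
right-skewed CI; the Bayesian posterior median is 46 with a tighter HPD
interval — both intervals contain the truth. `psi` is the fraction of the
1700 augmented slots estimated occupied, and `p` the per-offspring chance
of detecting a given real parent.

The same pipeline is available from the shell:

```bash
pedaccum simulate --n-females 25 --n-males 25 --n-obs 30 --seed 7 --out sample.tsv
pedaccum detect --input sample.tsv --out y.txt
pedaccum estimate chao --input y.txt
pedaccum estimate bayes --input y.txt --seed 7
pedaccum run-grid --config grid.yaml --out-dir results/
```

Users with a real reconstructed pedigree can skip the simulator: feed a
3-column TSV (`offspring_id`, `mother_id`, `father_id`) to `detect`, or a
one-count-per-line detection-vector file straight to `estimate`.

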