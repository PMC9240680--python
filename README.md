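# dentdist

Shark teeth are among the most abundant vertebrate fossils, and because tooth
size scales with body size, the size–frequency distribution of teeth
accumulated at a locality (its *dental distribution*) records the size
structure of the population that shed them. `dentdist` implements a
process-based framework for reading ecology out of such assemblages: a
deterministic two-site, size-structured metapopulation simulation of sand
tiger sharks (a coastal nursery and a pelagic adult habitat) that predicts
the dental distribution each site accumulates, and an inference layer that
fits simulated to observed distributions to decide whether a locality was a
**nursery (juvenile site) or an adult site** and to estimate two dispersal
traits:

* **ξ_j** — the juvenile dispersal window (grams): how strictly first
  dispersal from the nursery is tied to the maturation mass m_j;
* **ξ_a** — the adult dispersal window (days): how tightly synchronised the
  annual adult migration back to the nursery is.

Individuals grow by the temperature-dependent West law
dm/dt = a(T)·m^{3/4}(1 − (m/M)^{1/4}), reproduce at the nursery, die at a
constant rate, disperse through a logistic mass gate and annual
wrapped-Gaussian pulses, and shed teeth at a constant per-capita rate. A
simulated or observed distribution is summarised by seven shape parameters
w₁..w₇ (mean, variance, quartiles, mode count, Δmode) and compared with

    ε_{j,a}(ξ_j, ξ_a) = Σ_{k=1..7} |w_k^sim(ξ_j, ξ_a) − w_k^obs| / w_k^obs ,

grid-searched over (ξ_j, ξ_a) for both site-identity hypotheses; the lower
minimum classifies the site and locates the best-fit dispersal strategy.
See `docs/methods.md` for the full model description, defaults and
limitations.

The package is aimed at palaeoecologists and shark ecologists working with
tooth assemblages (or length records convertible to crown heights via the
built-in allometry), and ships a synthetic-data module so the whole pipeline
is testable without any data download.

## Worked example

Generate a synthetic "observed" assemblage of 2 000 teeth from the adult
site of a simulation with known windows (ξ_j = 795 g, ξ_a = 11 d), then fit
it blind on a 5×5 grid:

```bash
dentdist synth --xi-j 795 --xi-a 11 --site adult --n 2000 --seed 42 \
        --out example/observed.csv
dentdist fit --input example/observed.csv --out example/fit --grid-size 5
```

which prints

```
wrote 2000 teeth to example/observed.csv
sim-adult: adult eps_j=5.548 eps_a=1.521 xi_j=795 g xi_a=11 d
```

The fit recovers the generating truth: the assemblage is classified as an
**adult** site (its best simulated-adult match, ε_a = 1.52, beats the best
simulated-juvenile match, ε_j = 5.55, by far more than the 15% ambiguity
margin), and the best-fit windows land on the generating grid node — a
fairly strict juvenile dispersal window of 795 g and an adult window of
11 days. `example/fit/` contains the full error surfaces with
10%-of-minimum contour bands (`error_surface.csv`) and the machine-readable
decision (`fit_result.json`).

The same `fit` command accepts real measurement CSVs (columns `site,
specimen_id, tooth_position, crown_height_mm`; non-anterior positions are
filtered and reported), and `dentdist shapes` / `dentdist bootstrap` report
the seven shape parameters and their bootstrap uncertainties for any such
file. Library use mirrors the CLI:

```python
from dentdist import default_config, fit_observed, read_tooth_csv

teeth = read_tooth_csv("example/observed.csv")
result, surface = fit_observed(teeth.to_distribution(), default_config())
print(result.site_identity, result.best_xi_j, result.best_xi_a)
```

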