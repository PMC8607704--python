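# popproxy

**Multi-proxy prioritisation of wild population pairs for aquaculture
domestication trials.**

Bringing a new fish species into aquaculture benefits hugely from picking the
right wild source population, but comparing every candidate population in
common-garden bioassays is impossibly expensive. `popproxy` implements a
screening strategy built around cheap, large-scale *proxies* of
inter-populational divergence in key traits for aquaculture (KTA — survival,
growth, deformity and swim-bladder inflation rates, behaviour):

* **genetic distance** — pairwise Φ<sub>ST</sub> (two-level AMOVA fixation
  index) from aligned haplotypes,
* **habitat divergence** — PCA of z-scored environmental variables
  (Kaiser–Guttman axis retention) followed by Bray–Curtis distance on the
  retained scores,
* **geographic distance** — Vincenty geodesics on the WGS84 ellipsoid,
* **hydrologic distance** — circuit-theory effective resistance on a river
  conductance raster (river cells conduct 1 + *k*, plain land 1), computed
  from the graph-Laplacian pseudoinverse R<sub>ij</sub> = L⁺<sub>ii</sub> +
  L⁺<sub>jj</sub> − 2 L⁺<sub>ij</sub>.

The statistical core asks which proxies actually track trait divergence, and
then turns the answer into a shortlist of population pairs:

1. **Differentiation screen** — traits without significant inter-population
   differentiation (ANOVA or Kruskal–Wallis after Shapiro–Wilk/Levene
   assumption checks) are excluded.
2. **MRDM-CA** — each trait distance matrix is regressed on the standardised
   proxy matrices (multiple regression on distance matrices, permutation
   inference on R²), and the R² is decomposed by commonality analysis into
   unique (U) and common (C) contributions per proxy. Total suppressors
   (classical: U counter-balanced by negative C; cross-over: β and r of
   opposite sign) are removed iteratively. A proxy is significant when the
   final model's BH-adjusted permutation p < 0.05 and its U > 0.05.
3. **Prioritisation** — all matrices are min–max standardised to [0, 1],
   averaged over replicates to population-pair level and summed per pair
   across proxies; the sums are clustered by exact 1-D k-means (k from the
   Elbow rule) and clusters lettered A, B, C… by descending mean. Cluster A
   is the shortlist for bioassays.

A synthetic-data module generates complete studies (7 populations × 3 tanks
by default) with *known* proxy–trait couplings, so every stage is testable
end-to-end without any external data.

## Worked example

Simulate a study and run the full analysis (defaults: 1000 MRDM
permutations, 9999 Mantel permutations, river conductance bonus k = 100):

```python
from popproxy import RunConfig, run_pipeline

report = run_pipeline(RunConfig(simulate=True, output_dir="demo", seed=42))
for trait, model in report["models"].items():
    print(trait, "R2=%.3f" % model["r_squared"],
          "p_adj=%.3f" % model["p_adjusted"], "sig:", model["significant_proxies"])
```

prints

```
survival_rate R2=0.242 p_adj=0.001 sig: ['genetic', 'geographic']
specific_growth_rate R2=0.792 p_adj=0.001 sig: []
activity R2=0.532 p_adj=0.001 sig: ['habitat']
```

The simulated ground truth couples survival to the genetic proxy, growth to
the hydrologic proxy and activity to habitat. Survival and activity are
called correctly. Growth shows the method's honest behaviour under
collinearity: the synthetic river follows the latitudinal transect, so the
hydrologic and geographic matrices are nearly interchangeable — the model R²
is high but the shared variance (C ≈ 0.76) swamps either proxy's unique
contribution (U < 0.02), and neither clears the U > 0.05 bar.

The prioritisation table (`demo/prioritisation.csv`) ranks all 21 population
pairs:

```
 pair  genetic  habitat  geographic  hydrologic  proxy_sum proxy_cluster
P7-P1 0.848485 0.518250    1.000000    1.000000    3.36673             A
P6-P1 0.569378 0.996298    0.757122    0.855291    3.17809             A
P7-P2 0.958573 0.261801    0.974414    0.961643    3.15643             A
...
```

Pairs in cluster A combine high divergence across all proxies and are the
ones a domestication program would take into bioassays.

The same run is available from the shell:

```sh
popproxy simulate --output-dir study --seed 42
popproxy all --input-dir study --output-dir demo --seed 42
```

The built-in example dataset (`popproxy.datasets`) carries the seven
European perch (*Perca fluviatilis*) study lakes — WGS84 coordinates and the
published 21-pair prioritisation table — used throughout the tests.

## Layout

```
src/popproxy/
  matrices.py    labelled distance matrices (the pipeline currency)
  traits.py      KTA metrics from raw per-tank observations
  screen.py      inter-population differentiation screen
  distances.py   the five distance builders
  inference.py   MRDM, commonality analysis, suppressors, Mantel, BH
  prioritise.py  standardise / pair-average / sum / cluster / letter
  synthetic.py   seeded synthetic studies with known couplings
  datasets.py    built-in perch-lake example data
  io.py          readers, writers, RunConfig, run_pipeline
  cli.py         popproxy simulate|traits|screen|distances|infer|prioritise|all
docs/methods.md  model assumptions, parameter choices, limitations
```
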