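# stmrf

Bayesian spatiotemporal disease mapping for areal count panels on
**disconnected** adjacency graphs — e.g. district-level under-five
mortality across several countries that share no border, observed over a
handful of survey waves.

## The model

For area *i* (of *S*, in *C* connected components) and period *t* (of *T*),
observed deaths follow a Poisson law with an expected-count offset,

```
O_it | ω_it  ~  Poisson(e_it · ω_it),        e_it = N_it · (ΣO / ΣN)
log ω_it = η_it = β₀ + x_itᵀβ + v_i + u_i + γ_t + φ_t + ψ_it
```

where `x_it` are standardized district-level covariate proportions and the
random effects are

| term | meaning | prior | rank |
|------|---------|-------|------|
| `v`  | structured spatial effect | ICAR, structure `D − A` | `S − C` |
| `u`  | spatial heterogeneity | iid normal | `S` |
| `γ`  | structured temporal trend | first-order random walk (RW1) | `T − 1` |
| `φ`  | unstructured period effect | iid normal | `T` |
| `ψ`  | space–time interaction | Knorr-Held type I–IV, `W_ψ = W_γ ⊗ W_v` for type IV | `(T−1)(S−C)` for IV |

Intrinsic priors get one sum-to-zero constraint per null-space dimension
(per connected component for the ICAR; the standard Knorr-Held constraint
set for the interactions).  Posterior inference is a Laplace-approximation
scheme for latent Gaussian models (Gaussian approximation at the
conditional mode, weighted exploration of the hyperparameter posterior,
mixture marginals), cross-validated against a built-in
Metropolis-within-Gibbs sampler.  Model comparison uses DIC and WAIC;
variance partitioning attributes the latent log-risk variability to the
spatial / temporal / interaction / heterogeneity families; coefficient
reports include the percent change in relative risk per 1 sd,
`100·(exp(β) − 1)`.

Because real survey microdata of this kind are access-controlled, the
package ships a first-class synthetic generator
(`stmrf.generate_graph`, `stmrf.generate_panel`) that emulates the study
design — four disconnected lattice "countries" totalling 37 districts,
four survey waves, autocorrelated covariate proportions, and counts drawn
from the model above with every latent quantity recorded.

## Worked example

```python
import stmrf

graph = stmrf.generate_graph()                  # 4 countries, 37 districts
panel, truth = stmrf.generate_panel(graph, T=4, k=3, seed=1)

spec = stmrf.ModelSpec(interaction="IV")
post = stmrf.fit(spec, panel, graph, seed=0)
print(post.hyper.round(3))

from stmrf.diagnostics import compare_models, variance_partition
main = stmrf.fit(stmrf.ModelSpec(interaction=None), panel, graph, seed=0)
comp = compare_models({"main": main, "IV": post}, panel, seed=0)
print(comp.table[["DIC", "delta_DIC", "significant"]].round(1))
print({k: round(v, 2) for k, v in variance_partition(post).items()})
```

Output:

```
                  mean   q2.5  q97.5
param
variance[v]      0.242  0.156  0.393
variance[u]      0.006  0.001  0.031
variance[gamma]  0.001  0.000  0.005
variance[phi]    0.047  0.017  0.166
variance[psi]    0.052  0.039  0.072
         DIC  delta_DIC  significant
main  2513.8     1072.1         True
IV    1441.7        0.0        False
{'spatial': 0.61, 'heterogeneity': 0.0, 'temporal': 0.3, 'interaction': 0.09}
```

The hyperparameter table shows the posterior of each random-effect
variance (the generating interaction variance was 0.05 — recovered as
0.052).  The type-IV model beats the main-effects model by ΔDIC ≈ 1072,
far beyond the >3 rule of thumb, as it should on data generated with a
type-IV interaction.  The partition attributes most latent variability to
the spatial and temporal fields for this draw.

The same pipeline is scriptable from a shell:

```sh
stmrf simulate --out-dir sim            # panel.csv, edges.csv, truth.json
stmrf fit --panel sim/panel.csv --edges sim/edges.csv --interaction IV
stmrf report --panel sim/panel.csv --edges sim/edges.csv --models none,IV
```

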