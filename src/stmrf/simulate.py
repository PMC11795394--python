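"""Synthetic disconnected-country panels with known ground truth.

Emulates survey-aggregated district panels: a handful of countries with no
shared border (disconnected rook-contiguity lattices), a few survey waves,
district-level covariate proportions with spatial and temporal
autocorrelation, and Poisson death counts driven by spatial (ICAR + iid),
temporal (RW1 + iid) and space-time interaction random effects.  Every
latent quantity is recorded so downstream inference can be scored against
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import AdjacencyGraph, build_adjacency, icar_structure
from .gmrf import (
    constraint_set,
    interaction_structure,
    rw1_structure,
    sample_constrained_gmrf,
)
from .panel import PanelData, compute_expected_counts, standardize_covariates

__all__ = [
    "SyntheticTruth",
    "generate_graph",
    "generate_panel",
    "DEFAULT_COMPONENT_SIZES",
    "DEFAULT_COVARIATES",
    "DEFAULT_HYPER",
    "DEFAULT_BETA",
]

#: four disconnected countries totalling 37 districts
DEFAULT_COMPONENT_SIZES = (11, 10, 9, 7)

#: district-level covariate proportions typical of household-survey panels
DEFAULT_COVARIATES = (
    "child_nourished", "female_child", "diet_diversity", "birth_order",
    "women_literacy", "young_mother", "women_autonomy", "sanitation",
    "safe_water", "clean_fuel", "media_exposure", "mother_working",
    "father_working", "rural", "health_facility", "poor_wealth",
)

#: generating variances: temporal trend dominant, modest spatial structure,
#: small unstructured noise — the regime typical of declining-mortality panels
DEFAULT_HYPER = {
    "sigma2_u": 0.02,
    "delta2_v": 0.10,
    "sigma2_gamma": 0.30,
    "sigma2_phi": 0.02,
    "sigma2_psi": 0.05,
}

#: protective water/sanitation/fuel/literacy/facility effects, adverse
#: rurality and poverty, on the log relative-risk scale per 1 sd
DEFAULT_BETA = {
    "women_literacy": -0.2, "sanitation": -0.3, "safe_water": -0.2,
    "clean_fuel": -0.2, "health_facility": -0.2, "rural": 0.4,
    "poor_wealth": 0.4,
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated panel (bit-reproducible from seed)."""

    beta0: float
    beta: np.ndarray
    effects: dict          # name -> vector (empty for inactive families)
    hyper: dict            # generating variances actually used
    interaction: str | None
    eta: np.ndarray        # (T*S,) latent log relative risk
    seed: int
    S: int
    T: int
    k: int


def _truncated_grid_edges(n: int, offset: int, ncols: int | None = None):
    """Rook edges of the first n cells of a row-major grid (stays connected)."""
    if ncols is None:
        ncols = max(1, math.ceil(math.sqrt(n)))
    edges = []
    for a in range(n):
        r, c = divmod(a, ncols)
        if c + 1 < ncols and a + 1 < n and (a + 1) // ncols == r:
            edges.append((offset + a, offset + a + 1))
        if a + ncols < n:
            edges.append((offset + a, offset + a + ncols))
    return edges


def generate_graph(n_components: int = 4,
                   component_shape=DEFAULT_COMPONENT_SIZES) -> AdjacencyGraph:
    """Disjoint rook-contiguity lattices, one per country.

    ``component_shape`` gives each component either as an integer size
    (realised as a truncated near-square grid) or as a (rows, cols) tuple.
    Defaults to 4 components of sizes 11+10+9+7 = 37 districts.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    shapes = list(component_shape)[:n_components]
    if len(shapes) < n_components:
        shapes = shapes + [shapes[-1]] * (n_components - len(shapes))

    ids, edges, offset = [], [], 0
    for c, shape in enumerate(shapes):
        if isinstance(shape, tuple):
            rows, cols = shape
            n = rows * cols
            edges += _truncated_grid_edges(n, offset, ncols=cols)
        else:
            n = int(shape)
            edges += _truncated_grid_edges(n, offset)
        ids += [f"c{c}_d{a}" for a in range(n)]
        offset += n
    id_edges = [(ids[a], ids[b]) for a, b in edges]
    return build_adjacency(id_edges, ids)


def _covariates(graph: AdjacencyGraph, T: int, k: int, rho: float,
                rng: np.random.Generator) -> np.ndarray:
    """Raw covariate proportions with AR(1) temporal and country-level
    spatial correlation (the source of spatial confounding)."""
    S = graph.n_areas
    labels = graph.component_labels
    raw = np.zeros((T * S, k))
    for j in range(k):
        comp_shift = rng.normal(0.0, 0.6, size=graph.n_components)
        area = rng.normal(0.0, 0.4, size=S) + comp_shift[labels]
        z = rng.standard_normal(S)
        for t in range(T):
            if t:
                z = rho * z + math.sqrt(1.0 - rho * rho) * rng.standard_normal(S)
            # squash to (0, 1) so the stored values read as proportions
            raw[t * S:(t + 1) * S, j] = 1.0 / (1.0 + np.exp(-(area + z)))
    return raw


def generate_panel(
    graph: AdjacencyGraph,
    T: int = 4,
    k: int = 16,
    *,
    beta0: float = 0.0,
    beta=None,
    hyper: dict | None = None,
    interaction: str | None = "IV",
    n_range: tuple = (500, 8000),
    base_rate: float = 0.09,
    rho: float = 0.7,
    covariate_names=None,
    seed: int = 0,
):
    """Generate one panel and its ground truth.

    Random effects are drawn from their constrained GMRF priors (a variance
    of exactly 0 switches a family off); counts follow a two-pass scheme so
    the generator and the analysis share the same expected-count
    definition: provisional counts at the configured baseline rate fix the
    pooled global rate, then ``O ~ Poisson(e * exp(eta))`` with ``e`` from
    internal standardization of that provisional draw.

    Parameters
    ----------
    beta : array of length k, optional
        Covariate effects per 1 sd; defaults to the protective/adverse
        pattern in :data:`DEFAULT_BETA` (zero elsewhere).
    hyper : dict, optional
        Generating variances; defaults to :data:`DEFAULT_HYPER`.
    n_range : (lo, hi)
        Uniform range of the per-cell at-risk totals (surveyed children).
    base_rate : float
        Baseline event probability anchoring the pooled rate (0.09 —
        under-five mortality of about 90 per 1,000).
    """
    if T < 2:
        raise ValueError("need T >= 2 (the RW1 trend requires it)")
    S = graph.n_areas
    hy = dict(DEFAULT_HYPER)
    if hyper:
        hy.update(hyper)
    if covariate_names is None:
        covariate_names = tuple(DEFAULT_COVARIATES[:k]) if k <= len(DEFAULT_COVARIATES) \
            else tuple(DEFAULT_COVARIATES) + tuple(f"x{j}" for j in range(len(DEFAULT_COVARIATES), k))
    if beta is None:
        beta = np.array([DEFAULT_BETA.get(name, 0.0) for name in covariate_names])
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (k,):
        raise ValueError("beta length must equal k")

    rng = np.random.default_rng(seed)

    raw = _covariates(graph, T, k, rho, rng)
    if k:
        X, mns, sds = standardize_covariates(raw, names=list(covariate_names))
    else:
        X, mns, sds = raw, np.zeros(0), np.ones(0)

    effects = {}

    # spatial: ICAR (optionally per-component variance) + iid heterogeneity
    icar = icar_structure(graph)
    dv = np.atleast_1d(np.asarray(hy["delta2_v"], dtype=float))
    if np.all(dv == 0):
        v = np.zeros(S)
    else:
        v = sample_constrained_gmrf(icar, 1.0, constraint_set(icar), rng)
        if dv.size == 1:
            v = v * math.sqrt(dv[0])
        else:  # per-country spatial variance (blocks factorize)
            v = v * np.sqrt(dv[graph.component_labels])
    effects["v"] = v

    su = float(hy["sigma2_u"])
    effects["u"] = rng.normal(0.0, math.sqrt(su), size=S) if su > 0 else np.zeros(S)

    sg = float(hy["sigma2_gamma"])
    if sg > 0:
        rw1 = rw1_structure(T)
        g = sample_constrained_gmrf(rw1, sg, constraint_set(rw1), rng)
    else:
        g = np.zeros(T)
    effects["gamma"] = g

    sp_ = float(hy["sigma2_phi"])
    effects["phi"] = rng.normal(0.0, math.sqrt(sp_), size=T) if sp_ > 0 else np.zeros(T)

    spsi = float(hy["sigma2_psi"])
    if interaction is not None and spsi > 0:
        istr = interaction_structure(interaction, T, graph)
        psi = sample_constrained_gmrf(istr, spsi, constraint_set(istr), rng)
    else:
        psi = np.zeros(T * S)
    effects["psi"] = psi

    # time-major linear predictor
    eta = beta0 + X @ beta if k else np.full(T * S, beta0)
    eta = eta + np.tile(v + effects["u"], T)
    eta = eta + np.repeat(g + effects["phi"], S)
    eta = eta + psi

    N = rng.integers(n_range[0], n_range[1] + 1, size=(S, T))
    omega = np.exp(eta).reshape(T, S).T  # back to (S, T)

    # two-pass internal standardization: provisional counts pin the pooled rate
    O_prov = rng.poisson(N * base_rate * omega)
    O_prov = np.minimum(O_prov, N)
    e = compute_expected_counts(O_prov, N)
    O = np.minimum(rng.poisson(e * omega), N)
    e = compute_expected_counts(O, N)  # analysis-consistent e (conserves sum O)

    panel = PanelData(O=O.astype(int), N=N.astype(int), e=e, X=X,
                      area_ids=graph.area_ids,
                      covariate_names=tuple(covariate_names),
                      x_means=mns, x_sds=sds)
    truth = SyntheticTruth(beta0=beta0, beta=beta, effects=effects,
                           hyper=hy, interaction=interaction, eta=eta,
                           seed=seed, S=S, T=T, k=k)
    return panel, truth
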