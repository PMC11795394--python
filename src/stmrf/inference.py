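"""Approximate Bayesian inference for the latent Gaussian panel model.

The model is a Poisson likelihood with offset over a latent Gaussian field
x = (intercept(s), beta, v, u, gamma, phi, psi) whose prior precision is
block diagonal in intrinsic GMRF structures.  Inference follows the
Laplace-approximation recipe for latent Gaussian models:

1. all sum-to-zero (and optional orthogonality-to-X) constraints are
   absorbed by working in the constrained subspace z, x = Z z, with Z an
   orthonormal basis of the constraint null space — equivalent to
   conditioning by kriging but numerically exact;
2. for fixed hyperparameters theta (log precisions of the random-effect
   families) the conditional posterior of z is replaced by its Gaussian
   (Newton) approximation at the mode;
3. the hyperparameter posterior p(theta | y) is approximated by the
   Laplace ratio at the conditional mode and explored on a small grid
   around its numerically-located mode (tensor grid for 1-2 parameters,
   centre-plus-axial design beyond);
4. latent marginals are Gaussian mixtures over the weighted grid.

A Metropolis-within-Gibbs sampler over the same constrained
parameterization serves as a slow, asymptotically exact cross-check on
small instances.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .graph import AdjacencyGraph, icar_structure
from .gmrf import ConstraintSet, HyperParams, interaction_structure, rw1_structure
from .panel import PanelData

__all__ = [
    "ModelSpec",
    "PosteriorSummary",
    "GaussianApprox",
    "HyperGrid",
    "gaussian_approximation",
    "hyper_posterior_grid",
    "fit",
    "mcmc_oracle",
    "apply_orthogonality",
    "draw_latent",
]

log = logging.getLogger("stmrf")

#: vague Gaussian prior precision on intercepts and covariate coefficients
FIXED_EFFECT_PRECISION = 1e-4

#: Newton convergence: max abs update and iteration cap
NEWTON_TOL = 1e-6
NEWTON_MAXIT = 50


@dataclass(frozen=True)
class ModelSpec:
    """Which effects enter the model and how they are configured.

    ``interaction`` is one of None, "I".."IV".  The split flags give
    per-connected-component (per-country) intercepts, covariate effects and
    ICAR variances.  ``hyper_a``, ``hyper_b`` parameterize the log-gamma
    prior on every log precision (Gamma(a, b) on the precision itself).
    ``orthogonalize`` adds X-orthogonality constraints to v and psi
    (restricted spatial regression against confounding); off by default.
    """

    use_v: bool = True
    use_u: bool = True
    use_gamma: bool = True
    use_phi: bool = True
    interaction: str | None = "IV"
    split_intercept: bool = False
    split_covariates: bool = False
    split_spatial_variance: bool = False
    orthogonalize: bool = False
    hyper_a: float = 1.0
    hyper_b: float = 5e-4

    def active_effects(self):
        out = []
        if self.use_v:
            out.append("v")
        if self.use_u:
            out.append("u")
        if self.use_gamma:
            out.append("gamma")
        if self.use_phi:
            out.append("phi")
        if self.interaction is not None:
            out.append("psi")
        return out


@dataclass
class GaussianApprox:
    """Gaussian approximation to p(x | y, theta) at fixed hyperparameters."""

    x_mode: np.ndarray
    z_mode: np.ndarray
    H: np.ndarray            # precision of z at the mode
    logdet_H: float
    loglik: float            # Poisson log likelihood at the mode (with constants)
    n_iter: int
    constraint_residual: float


@dataclass
class HyperGrid:
    """Weighted exploration grid over log precisions."""

    names: list
    theta: np.ndarray        # (G, d)
    log_post: np.ndarray     # unnormalized log p(theta | y)
    weights: np.ndarray      # normalized to 1
    mode: np.ndarray         # (d,)
    mode_sd: np.ndarray      # curvature-based scale per dimension


@dataclass
class PosteriorSummary:
    """Posterior marginal summaries of one model fit."""

    fixed_effects: pd.DataFrame
    hyper: pd.DataFrame
    effect_means: dict
    effect_sds: dict
    eta_mean: np.ndarray
    eta_sd: np.ndarray
    grid: HyperGrid
    diagnostics: dict
    data_hash: str
    spec: ModelSpec
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def omega_mean(self) -> np.ndarray:
        """Fitted relative risk exp(eta-hat) per cell (time-major)."""
        return np.exp(self.eta_mean)

    def cell_table(self, panel: PanelData) -> pd.DataFrame:
        """Per-cell fitted log relative risk (posterior log odds) and RR."""
        S, T = panel.S, panel.T
        rows = []
        for t in range(T):
            for i in range(S):
                c = t * S + i
                rows.append({
                    "area_id": panel.area_ids[i], "time_index": t,
                    "eta_mean": self.eta_mean[c], "eta_sd": self.eta_sd[c],
                    "omega": math.exp(self.eta_mean[c]),
                    "omega_lo": math.exp(self.eta_mean[c] - 1.96 * self.eta_sd[c]),
                    "omega_hi": math.exp(self.eta_mean[c] + 1.96 * self.eta_sd[c]),
                })
        return pd.DataFrame(rows)


def apply_orthogonality(X: np.ndarray, effect_map: np.ndarray,
                        base: ConstraintSet | None = None) -> ConstraintSet:
    """Constraint rows making a mapped effect orthogonal to the covariates.

    Adds X' M rows (one per covariate) so that X' (M @ effect) = 0 —
    restricted spatial regression.  Raises on rank-deficient X.
    """
    X = np.asarray(X)
    if X.size and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient; cannot orthogonalize")
    rows = X.T @ effect_map
    if base is not None and base.n_constraints:
        rows = np.vstack([base.matrix, rows])
    # orthonormalize the row space to drop linearly dependent rows
    basis = scipy.linalg.orth(rows.T, rcond=1e-10)
    return ConstraintSet(matrix=basis.T, rhs=np.zeros(basis.shape[1]))


# ---------------------------------------------------------------------------
# internal model assembly


class _Block:
    """One latent block: design columns, constraints, prior structure."""

    def __init__(self, name, ncols, design, constraints, structures):
        # structures: list of (hyper_name_suffix, W (ncols x ncols), rank)
        # or None for the fixed-effect block (ridge prior, no hyper)
        self.name = name
        self.design = design                    # (n_cells, ncols)
        self.constraints = constraints          # (m, ncols) rows or None
        self.structures = structures
        if constraints is not None and constraints.shape[0]:
            self.Z = scipy.linalg.null_space(constraints, rcond=1e-10)
        else:
            self.Z = np.eye(ncols)
        self.nz = self.Z.shape[1]


class _Model:
    """Assembled constrained latent Gaussian model for one panel."""

    def __init__(self, spec: ModelSpec, panel: PanelData, graph: AdjacencyGraph):
        if graph.n_areas != panel.S:
            raise ValueError("graph/panel area mismatch")
        if spec.interaction is not None and panel.T < 2:
            raise ValueError("interaction model needs T >= 2")
        self.spec, self.panel, self.graph = spec, panel, graph
        S, T, k = panel.S, panel.T, panel.k
        C = graph.n_components
        labels = graph.component_labels
        cell_comp = np.tile(labels, T)          # component of each cell

        self.O_flat = panel.flat(panel.O).astype(float)
        self.e_flat = panel.flat(panel.e).astype(float)
        self.mask = panel.mask
        from scipy.special import gammaln
        m = self.mask
        self._ll_const = float(
            (self.O_flat[m] * np.log(self.e_flat[m])
             - gammaln(self.O_flat[m] + 1.0)).sum())

        blocks = []
        # fixed effects: intercept(s) + covariates, optionally per component
        n_int = C if spec.split_intercept else 1
        D_int = (np.eye(C)[cell_comp] if spec.split_intercept
                 else np.ones((S * T, 1)))
        int_names = ([f"intercept[comp{c}]" for c in range(C)]
                     if spec.split_intercept else ["intercept"])
        if spec.split_covariates and k:
            D_beta = np.hstack([panel.X * (cell_comp == c)[:, None]
                                for c in range(C)])
            beta_names = [f"{nm}[comp{c}]" for c in range(C)
                          for nm in panel.covariate_names]
        else:
            D_beta = panel.X
            beta_names = list(panel.covariate_names)
        D_fixed = np.hstack([D_int, D_beta]) if k else D_int
        self.fixed_names = int_names + (beta_names if k else [])
        blocks.append(_Block("fixed", D_fixed.shape[1], D_fixed, None, None))

        M_space = np.tile(np.eye(S), (T, 1))          # 1_T (x) I_S
        M_time = np.repeat(np.eye(T), S, axis=0)      # I_T (x) 1_S

        if spec.use_v:
            icar = icar_structure(graph)
            cons = icar.null_basis.T
            if spec.orthogonalize and k:
                cons = apply_orthogonality(panel.X, M_space,
                                           ConstraintSet(cons, np.zeros(cons.shape[0]))).matrix
            if spec.split_spatial_variance:
                structs = []
                for c in range(C):
                    sel = labels == c
                    Wc = np.zeros((S, S))
                    Wc[np.ix_(sel, sel)] = icar.matrix[np.ix_(sel, sel)]
                    structs.append((f"v[comp{c}]", Wc, int(sel.sum()) - 1))
            else:
                structs = [("v", icar.matrix, icar.rank)]
            blocks.append(_Block("v", S, M_space, cons, structs))
        if spec.use_u:
            blocks.append(_Block("u", S, M_space, None,
                                 [("u", np.eye(S), S)]))
        if spec.use_gamma:
            rw1 = rw1_structure(T)
            blocks.append(_Block("gamma", T, M_time, rw1.null_basis.T,
                                 [("gamma", rw1.matrix, rw1.rank)]))
        if spec.use_phi:
            blocks.append(_Block("phi", T, M_time, None,
                                 [("phi", np.eye(T), T)]))
        if spec.interaction is not None:
            istr = interaction_structure(spec.interaction, T, graph)
            cons = istr.null_basis.T
            if spec.orthogonalize and k:
                cons = apply_orthogonality(panel.X, np.eye(S * T),
                                           ConstraintSet(cons, np.zeros(cons.shape[0]))).matrix
            blocks.append(_Block("psi", S * T, np.eye(S * T), cons,
                                 [("psi", istr.matrix, istr.rank)]))

        self.blocks = blocks
        # z layout
        self.z_slices, pos = {}, 0
        for b in blocks:
            self.z_slices[b.name] = slice(pos, pos + b.nz)
            pos += b.nz
        self.nz = pos
        self.n_latent = sum(b.design.shape[1] for b in blocks)
        self.x_slices, xpos = {}, 0
        for b in blocks:
            self.x_slices[b.name] = slice(xpos, xpos + b.design.shape[1])
            xpos += b.design.shape[1]

        # projected design and per-hyper projected structures
        self.Dz = np.hstack([b.design @ b.Z for b in blocks])
        self.hyper_entries = []   # (name, block, Qz within block, rank)
        for b in blocks:
            if b.structures is None:
                continue
            for hname, W, rank in b.structures:
                Qz = b.Z.T @ W @ b.Z
                self.hyper_entries.append((hname, b.name, Qz, rank))
        self.hyper_names = [h[0] for h in self.hyper_entries]
        self.n_hyper = len(self.hyper_entries)

        # fixed-effect ridge (constant part of the prior precision)
        self.Q_ridge = np.zeros((self.nz, self.nz))
        sl = self.z_slices["fixed"]
        self.Q_ridge[sl, sl] = FIXED_EFFECT_PRECISION * np.eye(blocks[0].nz)

    # -- prior pieces ------------------------------------------------------

    def Q_z(self, theta: np.ndarray) -> np.ndarray:
        Q = self.Q_ridge.copy()
        for tj, (hname, bname, Qz, rank) in zip(theta, self.hyper_entries):
            sl = self.z_slices[bname]
            Q[sl, sl] += math.exp(tj) * Qz
        return Q

    def log_gdet_prior(self, theta: np.ndarray) -> float:
        return 0.5 * sum(r * tj for tj, (_, _, _, r)
                         in zip(theta, self.hyper_entries))

    def log_hyper_prior(self, theta: np.ndarray) -> float:
        a, b = self.spec.hyper_a, self.spec.hyper_b
        return float(np.sum(a * theta - b * np.exp(theta)))

    # -- likelihood --------------------------------------------------------

    def loglik_quad(self, z: np.ndarray) -> float:
        """Poisson log likelihood without constants (for optimisation)."""
        eta = self.Dz @ z
        m = self.mask
        with np.errstate(over="ignore"):
            val = self.O_flat[m] @ eta[m] - self.e_flat[m] @ np.exp(eta[m])
        return float(val)

    def loglik_full(self, eta: np.ndarray) -> float:
        m = self.mask
        with np.errstate(over="ignore"):
            return float((self.O_flat[m] * eta[m]
                          - self.e_flat[m] * np.exp(eta[m])).sum()
                         + self._ll_const)

    # -- Newton ------------------------------------------------------------

    def newton(self, theta: np.ndarray, z0: np.ndarray | None = None):
        Q = self.Q_z(theta)
        z = np.zeros(self.nz) if z0 is None else z0.copy()
        m = self.mask
        Dm = self.Dz[m]
        Om, em = self.O_flat[m], self.e_flat[m]

        def objective(zv):
            eta = Dm @ zv
            if eta.max(initial=0.0) > 60:
                return -np.inf
            return float(Om @ eta - em @ np.exp(eta)) - 0.5 * zv @ Q @ zv

        f = objective(z)
        trace = []
        for it in range(NEWTON_MAXIT):
            eta = np.clip(Dm @ z, -60, 60)
            mu = em * np.exp(eta)
            grad = Dm.T @ (Om - mu) - Q @ z
            H = Q + Dm.T @ (mu[:, None] * Dm)
            try:
                cf = scipy.linalg.cho_factor(H, lower=True)
            except np.linalg.LinAlgError as err:
                raise RuntimeError(f"singular Newton system at iteration {it}") from err
            delta = scipy.linalg.cho_solve(cf, grad)
            step = 1.0
            for _ in range(40):
                f_new = objective(z + step * delta)
                if np.isfinite(f_new) and f_new >= f - 1e-12:
                    break
                step *= 0.5
            else:
                break  # no ascent possible: already at (numerical) mode
            z = z + step * delta
            df, f = f_new - f, f_new
            trace.append((it, float(np.abs(step * delta).max()), float(f)))
            if np.abs(step * delta).max() < NEWTON_TOL:
                break
        else:
            raise RuntimeError(f"Newton did not converge in {NEWTON_MAXIT} "
                               f"iterations; trace tail: {trace[-5:]}")
        eta = np.clip(Dm @ z, -60, 60)
        mu = em * np.exp(eta)
        H = Q + Dm.T @ (mu[:, None] * Dm)
        return z, H, it + 1

    def log_posterior_theta(self, theta: np.ndarray,
                            z0: np.ndarray | None = None):
        """Laplace approximation to log p(theta | y) + const."""
        z, H, nit = self.newton(theta, z0)
        Q = self.Q_z(theta)
        sign, logdet_H = np.linalg.slogdet(H)
        lp = (self.loglik_quad(z)
              - 0.5 * z @ Q @ z
              + self.log_gdet_prior(theta)
              + self.log_hyper_prior(theta)
              - 0.5 * logdet_H)
        return lp, z, H, nit

    def x_from_z(self, z: np.ndarray) -> np.ndarray:
        x = np.empty(self.n_latent)
        for b in self.blocks:
            x[self.x_slices[b.name]] = b.Z @ z[self.z_slices[b.name]]
        return x

    def xvar_from_cov(self, Sz: np.ndarray) -> np.ndarray:
        var = np.empty(self.n_latent)
        for b in self.blocks:
            sl = self.z_slices[b.name]
            var[self.x_slices[b.name]] = np.einsum(
                "ij,jk,ik->i", b.Z, Sz[sl, sl], b.Z)
        return var

    def max_constraint_residual(self, x: np.ndarray) -> float:
        worst = 0.0
        for b in self.blocks:
            if b.constraints is not None and b.constraints.shape[0]:
                r = np.abs(b.constraints @ x[self.x_slices[b.name]]).max()
                worst = max(worst, float(r))
        return worst


def _data_hash(panel: PanelData) -> str:
    h = hashlib.sha256()
    for arr in (panel.O, panel.N, panel.e, panel.X):
        h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# public operations


def gaussian_approximation(spec: ModelSpec, panel: PanelData,
                           graph: AdjacencyGraph, hyper) -> GaussianApprox:
    """Newton mode and curvature of p(x | y, theta) at fixed variances.

    ``hyper`` maps family names ("v", "u", "gamma", "phi", "psi" — or the
    per-component "v[compC]" when the spatial variance is split) to
    variances, or is a :class:`~stmrf.gmrf.HyperParams`.
    """
    model = _Model(spec, panel, graph)
    theta = _theta_from_hyper(model, hyper)
    z, H, nit = model.newton(theta)
    x = model.x_from_z(z)
    sign, logdet = np.linalg.slogdet(H)
    eta = model.Dz @ z
    return GaussianApprox(
        x_mode=x, z_mode=z, H=H, logdet_H=float(logdet),
        loglik=model.loglik_full(eta), n_iter=nit,
        constraint_residual=model.max_constraint_residual(x),
    )


def _theta_from_hyper(model: _Model, hyper) -> np.ndarray:
    if isinstance(hyper, HyperParams):
        mapping = {"u": hyper.sigma2_u, "gamma": hyper.sigma2_gamma,
                   "phi": hyper.sigma2_phi, "psi": hyper.sigma2_psi}
        dv = np.atleast_1d(np.asarray(hyper.delta2_v, dtype=float))
        if dv.size == 1:
            mapping["v"] = float(dv[0])
        else:
            for c, val in enumerate(dv):
                mapping[f"v[comp{c}]"] = float(val)
    else:
        mapping = dict(hyper)
    theta = np.empty(model.n_hyper)
    for j, name in enumerate(model.hyper_names):
        if name not in mapping:
            raise ValueError(f"missing variance for hyper block {name!r}")
        theta[j] = -math.log(float(mapping[name]))
    return theta


def hyper_posterior_grid(spec: ModelSpec, panel: PanelData,
                         graph: AdjacencyGraph, *, n_per_dim: int = 5,
                         step: float = 0.85, model: "_Model | None" = None,
                         max_tensor_dim: int | None = None) -> HyperGrid:
    """Locate the mode of p(theta | y) and build a weighted grid around it.

    A tensor grid of ``n_per_dim`` points per dimension (spaced ``step``
    curvature-sds apart) where affordable — few hyperparameters, or a small
    latent field; otherwise a centre-plus-axial design with points at
    +-1.2 and +-2.4 sds (the usual accuracy/cost trade for latent Gaussian
    models).  ``max_tensor_dim`` overrides the automatic choice.
    """
    if model is None:
        model = _Model(spec, panel, graph)
    d = model.n_hyper
    if max_tensor_dim is None:
        max_tensor_dim = d if (n_per_dim**d <= 700 and model.nz <= 100) else 2
    if d == 0:
        lp, z, H, _ = model.log_posterior_theta(np.zeros(0))
        return HyperGrid(names=[], theta=np.zeros((1, 0)),
                         log_post=np.array([lp]), weights=np.array([1.0]),
                         mode=np.zeros(0), mode_sd=np.zeros(0))

    warm = {"z": None}

    def neg(theta):
        try:
            lp, z, _, _ = model.log_posterior_theta(theta, warm["z"])
        except RuntimeError:
            return 1e10
        warm["z"] = z
        return -lp

    from scipy.optimize import minimize
    x0 = np.zeros(d)
    simplex = np.vstack([x0, x0 + 1.5 * np.eye(d)])
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 0.05, "fatol": 0.05,
                            "maxfev": 200 * d, "initial_simplex": simplex})
    mode = res.x
    f0 = -res.fun

    # diagonal curvature by central differences -> per-dimension scale
    h = 0.3
    sd = np.empty(d)
    for j in range(d):
        ej = np.zeros(d)
        ej[j] = h
        fp = -neg(mode + ej)
        fm = -neg(mode - ej)
        curv = -(fp - 2 * f0 + fm) / h**2
        sd[j] = 1.0 / math.sqrt(curv) if curv > 1e-4 else 2.0
    sd = np.clip(sd, 0.05, 3.0)

    if d <= max_tensor_dim:
        # hyperparameter posteriors can be strongly skewed when the data
        # barely identify a variance; scan outward along each axis until
        # the log posterior has dropped by `cutoff` nats and span the grid
        # over the (asymmetric) region found
        cutoff = 6.0
        lo = np.empty(d)
        hi = np.empty(d)
        for j in range(d):
            for sign, store in ((1, hi), (-1, lo)):
                span = 1.5 * sd[j]
                for mult in (1.5, 3.0, 5.0, 8.0, 12.0):
                    th = mode.copy()
                    th[j] += sign * mult * sd[j]
                    if -neg(th) < f0 - cutoff:
                        break
                    span = mult * sd[j]
                store[j] = span
        axes = [np.linspace(mode[j] - lo[j], mode[j] + hi[j], n_per_dim)
                for j in range(d)]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
    else:
        pts = [mode]
        for j in range(d):
            for a in (1.2, -1.2, 2.4, -2.4):
                p = mode.copy()
                p[j] += a * sd[j]
                pts.append(p)
        pts = np.array(pts)

    lps = np.empty(len(pts))
    for g, th in enumerate(pts):
        try:
            lps[g], z, _, _ = model.log_posterior_theta(th, warm["z"])
            warm["z"] = z
        except RuntimeError:
            lps[g] = -np.inf
    if not np.isfinite(lps).any():
        raise RuntimeError("hyperparameter grid misplaced: all weights zero")
    w = np.exp(lps - lps[np.isfinite(lps)].max())
    w[~np.isfinite(lps)] = 0.0
    w = w / w.sum()
    return HyperGrid(names=list(model.hyper_names), theta=pts, log_post=lps,
                     weights=w, mode=mode, mode_sd=sd)


def _weighted_quantile(vals, weights, qs):
    order = np.argsort(vals)
    v, w = np.asarray(vals)[order], np.asarray(weights)[order]
    cw = np.cumsum(w) - 0.5 * w
    cw = cw / w.sum()
    return np.interp(qs, cw, v)


def fit(spec: ModelSpec, panel: PanelData, graph: AdjacencyGraph,
        seed: int = 0, *, n_per_dim: int = 5, step: float = 0.85) -> PosteriorSummary:
    """Full approximate posterior: latent marginals as Gaussian mixtures
    over the hyperparameter grid.  Deterministic given inputs; ``seed`` is
    recorded for downstream posterior draws (DIC/WAIC).
    """
    model = _Model(spec, panel, graph)
    grid = hyper_posterior_grid(spec, panel, graph, n_per_dim=n_per_dim,
                                step=step, model=model)

    G = len(grid.weights)
    z_modes, covs, n_iters = [], [], []
    x_means_g = np.zeros((G, model.n_latent))
    x_vars_g = np.zeros((G, model.n_latent))
    eta_g = np.zeros((G, panel.n_cells))
    eta_var_g = np.zeros((G, panel.n_cells))
    warm = None
    for g in range(G):
        if grid.weights[g] <= 0:
            z_modes.append(np.zeros(model.nz))
            covs.append(np.eye(model.nz))
            n_iters.append(0)
            continue
        z, H, nit = model.newton(grid.theta[g], warm)
        warm = z
        Sz = scipy.linalg.cho_solve(scipy.linalg.cho_factor(H, lower=True),
                                    np.eye(model.nz))
        z_modes.append(z)
        covs.append(Sz)
        n_iters.append(nit)
        x_means_g[g] = model.x_from_z(z)
        x_vars_g[g] = model.xvar_from_cov(Sz)
        eta_g[g] = model.Dz @ z
        eta_var_g[g] = np.einsum("ij,jk,ik->i", model.Dz, Sz, model.Dz)

    w = grid.weights
    x_mean = w @ x_means_g
    x_var = w @ (x_vars_g + x_means_g**2) - x_mean**2
    x_sd = np.sqrt(np.maximum(x_var, 0.0))
    eta_mean = w @ eta_g
    eta_var = w @ (eta_var_g + eta_g**2) - eta_mean**2
    eta_sd = np.sqrt(np.maximum(eta_var, 0.0))

    fsl = model.x_slices["fixed"]
    fixed = pd.DataFrame({
        "mean": x_mean[fsl], "sd": x_sd[fsl],
        "q2.5": x_mean[fsl] - 1.96 * x_sd[fsl],
        "q97.5": x_mean[fsl] + 1.96 * x_sd[fsl],
    }, index=model.fixed_names)

    hyper_rows = []
    for j, name in enumerate(grid.names):
        var_vals = np.exp(-grid.theta[:, j])
        mean = float(w @ var_vals)
        lo, hi = _weighted_quantile(var_vals, w, [0.025, 0.975])
        hyper_rows.append({"param": f"variance[{name}]", "mean": mean,
                           "q2.5": lo, "q97.5": hi})
    hyper = pd.DataFrame(hyper_rows).set_index("param") if hyper_rows \
        else pd.DataFrame(columns=["mean", "q2.5", "q97.5"])

    effect_means, effect_sds = {}, {}
    for b in model.blocks:
        if b.name == "fixed":
            continue
        sl = model.x_slices[b.name]
        effect_means[b.name] = x_mean[sl]
        effect_sds[b.name] = x_sd[sl]

    worst = model.max_constraint_residual(x_mean)
    summary = PosteriorSummary(
        fixed_effects=fixed, hyper=hyper,
        effect_means=effect_means, effect_sds=effect_sds,
        eta_mean=eta_mean, eta_sd=eta_sd, grid=grid,
        diagnostics={"newton_iterations": n_iters, "grid_size": G,
                     "constraint_residual": worst, "seed": seed},
        data_hash=_data_hash(panel), spec=spec,
        _state={"model": model, "z_modes": z_modes, "covs": covs,
                "weights": w, "seed": seed},
    )
    log.info("fit: %d grid points, constraint residual %.2e", G, worst)
    return summary


def draw_latent(summary: PosteriorSummary, n_draws: int, seed: int | None = None):
    """Posterior draws of eta from the fitted Gaussian mixture.

    Returns (eta_draws (n_draws, n_cells), x_draws (n_draws, n_latent)).
    """
    st = summary._state
    model, w = st["model"], st["weights"]
    rng = np.random.default_rng(st["seed"] if seed is None else seed)
    chols = {}
    etas = np.empty((n_draws, model.Dz.shape[0]))
    xs = np.empty((n_draws, model.n_latent))
    gs = rng.choice(len(w), size=n_draws, p=w)
    for i, g in enumerate(gs):
        if g not in chols:
            chols[g] = np.linalg.cholesky(st["covs"][g])
        z = st["z_modes"][g] + chols[g] @ rng.standard_normal(model.nz)
        etas[i] = model.Dz @ z
        xs[i] = model.x_from_z(z)
    return etas, xs


# ---------------------------------------------------------------------------
# MCMC oracle


def mcmc_oracle(spec: ModelSpec, panel: PanelData, graph: AdjacencyGraph,
                n_iter: int = 20000, seed: int = 0, *, burn: int | None = None,
                thin: int = 10, rw_scale: float = 0.6):
    """Metropolis-within-Gibbs sampler over the constrained parameterization.

    Latent blocks are updated jointly with an independence proposal from
    the Gaussian approximation at the current hyperparameters; log
    precisions with adaptive random-walk steps.  Asymptotically exact;
    intended as a validation oracle on small instances.

    Returns a dict with thinned draws of the fixed effects, eta,
    hyper log-precisions, and acceptance rates.
    """
    model = _Model(spec, panel, graph)
    if model.n_latent > 2000:
        log.warning("mcmc_oracle on a large latent field (%d); this will be slow",
                    model.n_latent)
    rng = np.random.default_rng(seed)
    burn = n_iter // 4 if burn is None else burn
    d = model.n_hyper

    theta = np.zeros(d)
    cache = {}

    def approx(th):
        key = tuple(np.round(th, 12))
        if key not in cache:
            z_hat, H, _ = model.newton(th)
            cf = np.linalg.cholesky(H)
            sign, ld = np.linalg.slogdet(H)
            cache.clear()  # keep only current theta's approximation
            cache[key] = (z_hat, cf, ld)
        return cache[key]

    def log_target_z(z, Q):
        return model.loglik_quad(z) - 0.5 * z @ Q @ z

    Q = model.Q_z(theta)
    z_hat, cf, ldH = approx(theta)
    z = z_hat.copy()
    f_z = log_target_z(z, Q)

    def q_logpdf(zv, z_hat, cf, ldH):
        r = cf.T @ (zv - z_hat)
        return 0.5 * ldH - 0.5 * r @ r

    scales = np.full(d, rw_scale)
    acc_z = acc_h = tot_z = tot_h = 0
    acc_h_j = np.zeros(d)
    tot_h_j = np.zeros(d)

    keep = []
    fsl = model.x_slices["fixed"]
    for it in range(n_iter):
        # latent update: independence proposal from the Gaussian approximation
        z_hat, cf, ldH = approx(theta)
        zp = z_hat + scipy.linalg.solve_triangular(
            cf.T, rng.standard_normal(model.nz), lower=False)
        f_p = log_target_z(zp, Q)
        lr = (f_p - f_z) - (q_logpdf(zp, z_hat, cf, ldH)
                            - q_logpdf(z, z_hat, cf, ldH))
        tot_z += 1
        if math.log(rng.random()) < lr:
            z, f_z = zp, f_p
            acc_z += 1

        # hyper updates (random walk on each log precision)
        for j in range(d):
            thp = theta.copy()
            thp[j] += scales[j] * rng.standard_normal()
            Qp = model.Q_z(thp)
            lr = (-0.5 * z @ Qp @ z + model.log_gdet_prior(thp)
                  + model.log_hyper_prior(thp)) \
                - (-0.5 * z @ Q @ z + model.log_gdet_prior(theta)
                   + model.log_hyper_prior(theta))
            tot_h += 1
            tot_h_j[j] += 1
            if math.log(rng.random()) < lr:
                theta, Q = thp, Qp
                f_z = log_target_z(z, Q)
                acc_h += 1
                acc_h_j[j] += 1
            if it < burn and tot_h_j[j] and tot_h_j[j] % 50 == 0:
                rate = acc_h_j[j] / tot_h_j[j]
                scales[j] *= math.exp(0.5 * (rate - 0.4))
                scales[j] = float(np.clip(scales[j], 0.05, 5.0))

        if it >= burn and (it - burn) % thin == 0:
            x = model.x_from_z(z)
            keep.append((x[fsl].copy(), theta.copy(), model.Dz @ z))

    if tot_z:
        rate_z = acc_z / tot_z
        if rate_z < 0.05 or rate_z > 0.95:
            log.warning("latent acceptance rate %.2f outside (0.05, 0.95)", rate_z)
    fixed = np.array([k[0] for k in keep])
    thetas = np.array([k[1] for k in keep])
    etas = np.array([k[2] for k in keep])
    return {
        "fixed": fixed, "fixed_names": model.fixed_names,
        "theta": thetas, "hyper_names": model.hyper_names,
        "eta": etas,
        "acceptance": {"latent": acc_z / max(tot_z, 1),
                       "hyper": acc_h / max(tot_h, 1)},
    }
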