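"""Areal panel data: counts, exposures, expected counts, SMRs, design maps.

Cells are laid out time-major: the flat index of area s at period t is
``t * S + s`` (T consecutive blocks of S areas).  The Poisson mean for a
cell is ``e_it * omega_it`` with ``omega = exp(eta)``, so ``log e`` enters
the model as an offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln

__all__ = [
    "PanelData",
    "LatentLayout",
    "compute_expected_counts",
    "compute_smr",
    "standardize_covariates",
    "assemble_design",
    "poisson_loglik",
    "read_panel_csv",
    "panel_to_frame",
    "smr_table",
]


@dataclass
class PanelData:
    """District-by-period panel of event counts with covariates.

    O, N, e are (S, T) arrays; ``X`` is the (T*S, k) standardized covariate
    matrix in time-major cell order and ``offset`` is log(e) flattened the
    same way (zero-exposure cells carry offset -inf and are masked out of
    every likelihood).
    """

    O: np.ndarray
    N: np.ndarray
    e: np.ndarray
    X: np.ndarray
    area_ids: tuple
    covariate_names: tuple = ()
    x_means: np.ndarray | None = None
    x_sds: np.ndarray | None = None

    def __post_init__(self):
        self.O = np.asarray(self.O)
        self.N = np.asarray(self.N)
        if self.O.shape != self.N.shape:
            raise ValueError("O and N shapes differ")
        if np.any(self.O < 0) or np.any(self.N < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.O > self.N):
            raise ValueError("observed deaths exceed at-risk totals")
        S, T = self.O.shape
        if self.X.ndim != 2 or self.X.shape[0] != S * T:
            raise ValueError("X must have T*S rows (time-major)")
        if len(self.area_ids) != S:
            raise ValueError("area_ids length mismatch")

    @property
    def S(self) -> int:
        return self.O.shape[0]

    @property
    def T(self) -> int:
        return self.O.shape[1]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def n_cells(self) -> int:
        return self.S * self.T

    def flat(self, M: np.ndarray) -> np.ndarray:
        """Flatten an (S, T) array to time-major cell order."""
        return np.asarray(M).T.reshape(-1)

    @property
    def mask(self) -> np.ndarray:
        """Boolean (T*S,) — True for cells with exposure (N > 0)."""
        return self.flat(self.N) > 0

    @property
    def offset(self) -> np.ndarray:
        e = self.flat(self.e)
        with np.errstate(divide="ignore"):
            return np.where(e > 0, np.log(np.where(e > 0, e, 1.0)), -np.inf)


@dataclass(frozen=True)
class LatentLayout:
    """Index slices of each block in the stacked latent vector.

    Block order: intercept(s), covariate coefficients, spatial structured v,
    spatial heterogeneity u, temporal trend gamma, temporal iid phi,
    interaction psi.  Inactive blocks have empty slices.
    """

    slices: dict
    n_latent: int

    @staticmethod
    def create(S: int, T: int, k: int, n_intercepts: int = 1,
               active=("v", "u", "gamma", "phi", "psi")) -> "LatentLayout":
        sizes = {
            "intercept": n_intercepts,
            "beta": k,
            "v": S if "v" in active else 0,
            "u": S if "u" in active else 0,
            "gamma": T if "gamma" in active else 0,
            "phi": T if "phi" in active else 0,
            "psi": S * T if "psi" in active else 0,
        }
        slices, pos = {}, 0
        for name, n in sizes.items():
            slices[name] = slice(pos, pos + n)
            pos += n
        return LatentLayout(slices=slices, n_latent=pos)

    def size(self, name: str) -> int:
        s = self.slices[name]
        return s.stop - s.start

    def extract(self, x: np.ndarray, name: str) -> np.ndarray:
        return x[..., self.slices[name]]


def compute_expected_counts(O: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Internally standardized expected counts e_it = N_it * (sum O / sum N).

    One global rate pooled over all areas and periods, allocated by each
    cell's exposure; conserves the total (sum e = sum O exactly).  Cells
    with N = 0 get e = 0 and are excluded from any likelihood.
    """
    O = np.asarray(O, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("at-risk counts must be nonnegative")
    total_N = N.sum()
    if total_N <= 0:
        raise ValueError("all at-risk counts are zero")
    return N * (O.sum() / total_N)


def compute_smr(O: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Standardized mortality ratios SMR_it = O_it / e_it.

    Cells with e = 0 and O > 0 are undefined and returned as NaN with a
    warning; e = 0 with O = 0 gives SMR 0 by convention (no exposure).
    """
    O = np.asarray(O, dtype=float)
    e = np.asarray(e, dtype=float)
    out = np.zeros_like(O)
    ok = e > 0
    out[ok] = O[ok] / e[ok]
    bad = (~ok) & (O > 0)
    if np.any(bad):
        import warnings

        warnings.warn(f"{int(bad.sum())} cell(s) have O > 0 with zero expected "
                      "count; SMR undefined (NaN)", stacklevel=2)
        out[bad] = np.nan
    return out


def standardize_covariates(X: np.ndarray, names=None):
    """Center and scale each column to mean 0, sd 1 (population sd, ddof=0).

    Returns ``(Xstd, means, sds)``; the moments are retained so fitted
    coefficients can be mapped back to the raw proportion scale.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    bad = np.where(sds <= 0)[0]
    if bad.size:
        label = (names[bad[0]] if names is not None else f"column {bad[0]}")
        raise ValueError(f"constant covariate cannot be standardized: {label}")
    return (X - means) / sds, means, sds


def assemble_design(S: int, T: int, layout: LatentLayout) -> dict:
    """Sparse maps sending each latent block to the T*S cell vector.

    intercept -> 1_TS; v, u -> 1_T (x) I_S; gamma, phi -> I_T (x) 1_S;
    psi -> I_TS.  (Covariate columns X are supplied by the panel itself.)
    Multiplying each block through its map and summing reproduces the
    cell-wise linear predictor.
    """
    ones_T = np.ones((T, 1))
    ones_S = np.ones((S, 1))
    maps = {}
    if layout.size("intercept"):
        maps["intercept"] = sp.csr_matrix(np.ones((S * T, layout.size("intercept"))))
    if layout.size("v"):
        maps["v"] = sp.csr_matrix(sp.kron(ones_T, sp.eye(S)))
    if layout.size("u"):
        maps["u"] = sp.csr_matrix(sp.kron(ones_T, sp.eye(S)))
    if layout.size("gamma"):
        maps["gamma"] = sp.csr_matrix(sp.kron(sp.eye(T), ones_S))
    if layout.size("phi"):
        maps["phi"] = sp.csr_matrix(sp.kron(sp.eye(T), ones_S))
    if layout.size("psi"):
        maps["psi"] = sp.identity(S * T, format="csr")
    return maps


def poisson_loglik(O: np.ndarray, e: np.ndarray, eta: np.ndarray) -> float:
    """Poisson log likelihood of flat cell vectors with mean e * exp(eta).

    sum over exposed cells of O*(log e + eta) - e*exp(eta) - log O!.
    Cells with e = 0 (no exposure) are excluded.
    """
    O = np.asarray(O, dtype=float).reshape(-1)
    e = np.asarray(e, dtype=float).reshape(-1)
    eta = np.asarray(eta, dtype=float).reshape(-1)
    if not np.allclose(O, np.round(O)):
        raise ValueError("observed counts must be integers")
    ok = e > 0
    O, e, eta = O[ok], e[ok], eta[ok]
    with np.errstate(over="ignore"):
        ll = O * (np.log(e) + eta) - e * np.exp(eta) - gammaln(O + 1.0)
    return float(ll.sum())


# ---------------------------------------------------------------------------
# I/O helpers

_REQUIRED_COLS = ("area_id", "time_index", "deaths", "at_risk")


def read_panel_csv(path, covariate_cols=None) -> PanelData:
    """Load a long-format panel CSV.

    Required columns: area_id, time_index (0-based or 1-based contiguous),
    deaths, at_risk; every other numeric column is treated as a covariate
    unless ``covariate_cols`` names them explicitly.  Covariates are
    standardized on load.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise ValueError(f"panel CSV missing required column {col!r}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in _REQUIRED_COLS]
    else:
        for c in covariate_cols:
            if c not in df.columns:
                raise ValueError(f"panel CSV missing covariate column {c!r}")

    area_ids = tuple(dict.fromkeys(df["area_id"].astype(str)))
    times = np.sort(df["time_index"].unique())
    S, T = len(area_ids), len(times)
    if len(df) != S * T:
        raise ValueError(f"panel is not a complete {S} x {T} grid "
                         f"({len(df)} rows)")
    aidx = {a: i for i, a in enumerate(area_ids)}
    tidx = {t: j for j, t in enumerate(times)}

    O = np.zeros((S, T))
    N = np.zeros((S, T))
    Xraw = np.zeros((T * S, len(covariate_cols)))
    for _, row in df.iterrows():
        i, j = aidx[str(row["area_id"])], tidx[row["time_index"]]
        O[i, j] = row["deaths"]
        N[i, j] = row["at_risk"]
        Xraw[j * S + i] = [row[c] for c in covariate_cols]

    e = compute_expected_counts(O, N)
    if covariate_cols:
        X, mns, sds = standardize_covariates(Xraw, names=list(covariate_cols))
    else:
        X, mns, sds = Xraw, np.zeros(0), np.ones(0)
    return PanelData(O=O.astype(int), N=N.astype(int), e=e, X=X,
                     area_ids=area_ids, covariate_names=tuple(covariate_cols),
                     x_means=mns, x_sds=sds)


def panel_to_frame(panel: PanelData) -> pd.DataFrame:
    """Long-format DataFrame (area_id, time_index, deaths, at_risk, covariates)."""
    rows = []
    for t in range(panel.T):
        for i in range(panel.S):
            row = {"area_id": panel.area_ids[i], "time_index": t,
                   "deaths": int(panel.O[i, t]), "at_risk": int(panel.N[i, t])}
            for j, name in enumerate(panel.covariate_names):
                row[name] = panel.X[t * panel.S + i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def smr_table(panel: PanelData) -> pd.DataFrame:
    """Per-cell table of O, N, e and SMR (the crude mapping product)."""
    smr = compute_smr(panel.O, panel.e)
    rows = []
    for i in range(panel.S):
        for t in range(panel.T):
            rows.append({"area_id": panel.area_ids[i], "time_index": t,
                         "O": int(panel.O[i, t]), "N": int(panel.N[i, t]),
                         "e": panel.e[i, t], "SMR": smr[i, t]})
    return pd.DataFrame(rows)
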