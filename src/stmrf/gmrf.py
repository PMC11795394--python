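"""Temporal and space-time interaction GMRF structures, constraints, sampling.

Intrinsic Gaussian Markov random fields are specified by a PSD structure
matrix W and a variance: density proportional to exp(-x' W x / (2 s2)),
improper along null(W).  Identifiability is restored by one sum-to-zero
constraint per null direction; this module builds those constraint sets and
samples the constrained fields by spectral decomposition on the range space.

The four space-time interaction types are the Kronecker combinations of the
unstructured/structured temporal and spatial factors (time-major ordering,
i.e. the TS vector is laid out as T consecutive blocks of S areas):

=====  ==================  =========================
type   structure           rank
=====  ==================  =========================
I      I_T (x) I_S         T*S
II     W_rw1 (x) I_S       (T-1)*S
III    I_T (x) W_icar      T*(S-C)
IV     W_rw1 (x) W_icar    (T-1)*(S-C)
=====  ==================  =========================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .graph import AdjacencyGraph, PrecisionStructure, icar_structure

__all__ = [
    "ConstraintSet",
    "HyperParams",
    "rw1_structure",
    "iid_structure",
    "interaction_structure",
    "constraint_set",
    "sample_constrained_gmrf",
    "scale_structure",
    "export_structure",
]

INTERACTION_TYPES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class ConstraintSet:
    """Linear constraints A x = rhs (rhs is always zero here).

    Rows are linearly independent; for an intrinsic structure there is
    exactly one row per null-space dimension.
    """

    matrix: np.ndarray  # (m, n)
    rhs: np.ndarray     # (m,)

    @property
    def n_constraints(self) -> int:
        return self.matrix.shape[0]

    def residual(self, x: np.ndarray) -> float:
        if self.n_constraints == 0:
            return 0.0
        return float(np.abs(self.matrix @ x - self.rhs).max())


@dataclass
class HyperParams:
    """Variance parameters of the random-effect families.

    All entries are variances (not precisions), strictly positive:

    - ``sigma2_u``: iid spatial heterogeneity
    - ``delta2_v``: ICAR conditional-variance scale; a scalar, or one value
      per connected component when the spatial variance is split by country
    - ``sigma2_gamma``: RW1 temporal trend
    - ``sigma2_phi``: iid temporal effect
    - ``sigma2_psi``: space-time interaction
    """

    sigma2_u: float = 1.0
    delta2_v: float | np.ndarray = 1.0
    sigma2_gamma: float = 1.0
    sigma2_phi: float = 1.0
    sigma2_psi: float = 1.0

    def __post_init__(self):
        for name in ("sigma2_u", "delta2_v", "sigma2_gamma",
                     "sigma2_phi", "sigma2_psi"):
            val = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(val <= 0):
                raise ValueError(f"{name} must be strictly positive")


def rw1_structure(T: int) -> PrecisionStructure:
    """First-order random-walk structure matrix on T time points.

    Tridiagonal with 1 on the two corners, 2 on the interior diagonal and
    -1 off-diagonal; penalises first differences.  Rank T-1, null space the
    constant vector.
    """
    if T < 2:
        raise ValueError("RW1 needs at least 2 time points")
    W = np.zeros((T, T))
    idx = np.arange(T - 1)
    W[idx, idx] += 1.0
    W[idx + 1, idx + 1] += 1.0
    W[idx, idx + 1] -= 1.0
    W[idx + 1, idx] -= 1.0
    null = np.full((T, 1), 1.0 / np.sqrt(T))
    return PrecisionStructure(matrix=W, rank=T - 1, null_basis=null, label="rw1")


def iid_structure(n: int) -> PrecisionStructure:
    """Identity structure (exchangeable effects); full rank, no constraints."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return PrecisionStructure(
        matrix=np.eye(n), rank=n, null_basis=np.zeros((n, 0)), label="iid"
    )


def _kron_null_basis(Wt: PrecisionStructure, Ws: PrecisionStructure) -> np.ndarray:
    """Orthonormal basis of null(Wt (x) Ws) for PSD factors.

    null(A (x) B) = null(A) (x) R^S  +  R^T (x) null(B); the two spans
    overlap in null(A) (x) null(B), so the combined dimension is
    a*S + T*b - a*b.  The union of spanning sets is orthonormalised by SVD.
    """
    T, S = Wt.n, Ws.n
    cols = []
    if Wt.null_dim:
        cols.append(np.kron(Wt.null_basis, np.eye(S)))
    if Ws.null_dim:
        cols.append(np.kron(np.eye(T), Ws.null_basis))
    if not cols:
        return np.zeros((T * S, 0))
    M = np.hstack(cols)
    return scipy.linalg.orth(M, rcond=1e-10)


def interaction_structure(itype: str, T: int, graph: AdjacencyGraph) -> PrecisionStructure:
    """Space-time interaction structure matrix (time-major Kronecker order).

    Parameters
    ----------
    itype : {"I", "II", "III", "IV"}
        Which of the four interaction types to build.
    T : int
        Number of time periods (>= 2).
    graph : AdjacencyGraph
        Areal graph with S areas and C connected components.
    """
    if itype not in INTERACTION_TYPES:
        raise ValueError(f"unknown interaction type {itype!r}; "
                         f"expected one of {INTERACTION_TYPES}")
    if T < 2:
        raise ValueError("interaction needs T >= 2")
    S, C = graph.n_areas, graph.n_components
    Wt = rw1_structure(T) if itype in ("II", "IV") else iid_structure(T)
    Ws = icar_structure(graph) if itype in ("III", "IV") else iid_structure(S)

    M = np.kron(Wt.matrix, Ws.matrix)
    null = _kron_null_basis(Wt, Ws)
    rank = T * S - null.shape[1]
    expected = {"I": T * S, "II": (T - 1) * S,
                "III": T * (S - C), "IV": (T - 1) * (S - C)}[itype]
    assert rank == expected, "Kronecker rank identity violated"
    return PrecisionStructure(
        matrix=M, rank=rank, null_basis=null, label=f"interaction-{itype}",
        meta={"T": T, "S": S, "C": C},
    )


def constraint_set(structure: PrecisionStructure) -> ConstraintSet:
    """One sum-to-zero constraint per null direction of an intrinsic structure.

    For ICAR these are per-component sums; for RW1 the overall sum; for the
    structured interactions the standard Knorr-Held constraints arise as the
    Kronecker null vectors.  Proper structures yield an empty set.
    """
    A = structure.null_basis.T.copy()
    return ConstraintSet(matrix=A, rhs=np.zeros(A.shape[0]))


def sample_constrained_gmrf(
    structure: PrecisionStructure,
    variance: float,
    constraints: ConstraintSet | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw one field with density prop. to exp(-x'Wx/(2 s2)) on the
    constraint subspace.

    Sampling is spectral: x = sum_k sqrt(s2/lambda_k) z_k v_k over the
    positive eigenpairs of W, which automatically satisfies the intrinsic
    sum-to-zero constraints; any extra constraints are then imposed by
    conditioning (projection of the range-space sample).
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, V = np.linalg.eigh(structure.matrix)
    scale = max(abs(w[-1]), 1.0)
    pos = w > 1e-8 * scale
    z = rng.standard_normal(int(pos.sum()))
    x = V[:, pos] @ (np.sqrt(variance / w[pos]) * z)

    if constraints is not None and constraints.n_constraints:
        # conditioning by kriging: x | Ax=0 has mean x - Sigma A'(A Sigma A')^-1 Ax
        # rows aligned with null(W) have zero variance under the spectral
        # sample and are satisfied by construction; keep only rows with a
        # nonzero range-space projection (else A Sigma A' is singular)
        A = constraints.matrix
        Vp = V[:, pos]
        proj = A @ Vp
        live = np.linalg.norm(proj, axis=1) > 1e-8
        if np.any(live):
            A = A[live]
            Sig_At = Vp @ ((variance / w[pos])[:, None] * (A @ Vp).T)
            AAt = A @ Sig_At
            corr = Sig_At @ np.linalg.solve(AAt, A @ x)
            x = x - corr
    return x


def scale_structure(structure: PrecisionStructure) -> PrecisionStructure:
    """Rescale so the geometric mean marginal variance on the constrained
    subspace is 1 (the 'scaled' GMRF convention); off by default everywhere.
    """
    w, V = np.linalg.eigh(structure.matrix)
    scale = max(abs(w[-1]), 1.0)
    pos = w > 1e-8 * scale
    # generalized inverse marginal variances
    Vp = V[:, pos]
    margvar = np.einsum("ij,j,ij->i", Vp, 1.0 / w[pos], Vp)
    ref = float(np.exp(np.mean(np.log(margvar))))
    return PrecisionStructure(
        matrix=structure.matrix * ref,
        rank=structure.rank,
        null_basis=structure.null_basis,
        label=structure.label + "-scaled",
        meta=dict(structure.meta, scaled=True),
    )


def export_structure(structure: PrecisionStructure, path) -> None:
    """Write a structure matrix as a Matrix Market sparse file."""
    import scipy.io
    import scipy.sparse

    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(structure.matrix),
                     comment=f"{structure.label} structure, rank {structure.rank}")
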