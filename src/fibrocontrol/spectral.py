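"""Legendre-Gauss-Lobatto (GLL) spectral primitives and Galerkin assembly.

This module provides the building blocks of a nodal spectral Galerkin
discretization on a single element per dimension:

* Legendre polynomial evaluation by the three-term recurrence,
* GLL nodes (endpoints plus the roots of ``L_N'``) found by Newton
  iteration with Chebyshev-Gauss-Lobatto initial guesses,
* GLL quadrature weights ``w_k = 2 / (N(N+1) L_N(xi_k)^2)``,
* the first-derivative (differentiation) matrix at the GLL nodes,
* Lagrange cardinal basis evaluation,
* affine reference-to-physical interval maps, and
* 1-D and 2-D (tensor-product) mass, stiffness and load operators.

All quantities live on the reference interval [-1, 1] until mapped to a
physical interval [x_a, x_b].  The quadrature is exact for polynomials of
degree <= 2N - 1, which makes the mass matrix diagonal (the nodal Lagrange
basis is discretely orthogonal) and the stiffness matrix exact, since the
integrand ``phi_i' phi_j'`` has degree 2N - 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "legendre_eval",
    "legendre_deriv",
    "lobatto_eval",
    "gll_nodes",
    "gll_weights",
    "diff_matrix",
    "lagrange_basis_eval",
    "GLLBasis",
    "ElementMap",
    "GalerkinOperators1D",
    "GalerkinOperators2D",
    "assemble_1d",
    "assemble_2d",
]

_NEWTON_TOL = 1e-14
_NEWTON_MAXIT = 100


def legendre_eval(k: int, xi):
    """Evaluate the Legendre polynomial ``L_k`` at ``xi``.

    Uses the three-term recurrence
    ``(k+1) L_{k+1} = (2k+1) xi L_k - k L_{k-1}`` with the normalization
    ``L_k(1) = 1``.  ``xi`` may be a scalar or an ndarray in [-1, 1].
    """
    if k < 0:
        raise ValueError("polynomial degree must be nonnegative")
    xi = np.asarray(xi, dtype=float)
    if np.any(np.abs(xi) > 1.0 + 1e-12):
        raise ValueError("reference coordinate outside [-1, 1]")
    prev = np.ones_like(xi)
    if k == 0:
        return prev if prev.ndim else float(prev)
    cur = xi.copy()
    for j in range(1, k):
        prev, cur = cur, ((2 * j + 1) * xi * cur - j * prev) / (j + 1)
    return cur if cur.ndim else float(cur)


def legendre_deriv(k: int, xi):
    """Evaluate ``L_k'`` at ``xi`` via the derivative recurrence.

    ``L'_{j+1} = L'_{j-1} + (2j+1) L_j`` with ``L'_0 = 0``, ``L'_1 = 1``.
    Valid on the closed interval including the endpoints.
    """
    if k < 0:
        raise ValueError("polynomial degree must be nonnegative")
    xi = np.asarray(xi, dtype=float)
    if k == 0:
        out = np.zeros_like(xi)
        return out if out.ndim else float(out)
    L_prev = np.ones_like(xi)     # L_0
    L_cur = xi.copy()             # L_1
    d_prev = np.zeros_like(xi)    # L_0'
    d_cur = np.ones_like(xi)      # L_1'
    for j in range(1, k):
        L_next = ((2 * j + 1) * xi * L_cur - j * L_prev) / (j + 1)
        d_next = d_prev + (2 * j + 1) * L_cur
        L_prev, L_cur = L_cur, L_next
        d_prev, d_cur = d_cur, d_next
    return d_cur if d_cur.ndim else float(d_cur)


def lobatto_eval(k: int, xi):
    """Evaluate the k-th Lobatto polynomial ``Lo_k = L'_{k+1}``."""
    return legendre_deriv(k + 1, xi)


def gll_nodes(N: int) -> np.ndarray:
    """Gauss-Legendre-Lobatto nodes for order ``N``: the endpoints plus
    the N - 1 roots of ``L_N'``, sorted ascending.

    Interior roots are polished by Newton iteration on ``L_N'`` starting
    from Chebyshev-Gauss-Lobatto points; the second derivative needed by
    Newton comes from the Legendre ODE
    ``(1 - xi^2) L_N'' = 2 xi L_N' - N(N+1) L_N``.
    """
    if N < 2:
        raise ValueError("spectral order must be at least 2")
    # Chebyshev-Gauss-Lobatto initial guesses for the interior nodes.
    x = -np.cos(np.pi * np.arange(1, N) / N)
    for _ in range(_NEWTON_MAXIT):
        d1 = legendre_deriv(N, x)
        LN = legendre_eval(N, x)
        d2 = (2.0 * x * d1 - N * (N + 1) * LN) / (1.0 - x * x)
        dx = d1 / d2
        x -= dx
        if np.max(np.abs(dx)) < _NEWTON_TOL:
            break
    nodes = np.empty(N + 1)
    nodes[0], nodes[-1] = -1.0, 1.0
    nodes[1:-1] = np.sort(x)
    # Symmetrize: GLL nodes are antisymmetric about the origin.
    nodes = 0.5 * (nodes - nodes[::-1])
    return nodes


def gll_weights(N: int, nodes: np.ndarray) -> np.ndarray:
    """GLL quadrature weights ``w_k = 2 / (N(N+1) [L_N(xi_k)]^2)``.

    Exact for all polynomials of degree <= 2N - 1; the weights are
    positive and sum to 2.
    """
    LN = legendre_eval(N, nodes)
    return 2.0 / (N * (N + 1) * LN**2)


def diff_matrix(N: int, nodes: np.ndarray) -> np.ndarray:
    """First-derivative matrix ``d`` at the GLL nodes.

    ``(d f)_i = f'(xi_i)`` exactly for any polynomial ``f`` of degree
    <= N sampled at the nodes.  Off-diagonal entries follow the standard
    cardinal-basis formula ``d_ij = L_N(xi_i) / (L_N(xi_j) (xi_i - xi_j))``;
    diagonal entries are set to the negated off-diagonal row sums so each
    row annihilates constants to machine precision (this exactness is what
    keeps spatially uniform states uniform under time integration).
    """
    LN = legendre_eval(N, nodes)
    d = np.zeros((N + 1, N + 1))
    for i in range(N + 1):
        for j in range(N + 1):
            if i != j:
                d[i, j] = LN[i] / (LN[j] * (nodes[i] - nodes[j]))
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(d, -d.sum(axis=1))
    return d


@dataclass(frozen=True)
class GLLBasis:
    """Order-N GLL scheme: nodes, quadrature weights, derivative matrix."""

    order: int
    nodes: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    diff: np.ndarray = field(repr=False)

    @classmethod
    def of_order(cls, N: int) -> "GLLBasis":
        nodes = gll_nodes(N)
        return cls(order=N, nodes=nodes, weights=gll_weights(N, nodes),
                   diff=diff_matrix(N, nodes))


def lagrange_basis_eval(basis: GLLBasis, j: int, xi: float) -> float:
    """Evaluate the j-th Lagrange cardinal polynomial of the GLL basis.

    ``phi_j(xi) = (xi^2 - 1) L_N'(xi) / (N(N+1) L_N(xi_j) (xi - xi_j))``
    with the removable singularity at ``xi = xi_j`` evaluating to 1.
    Satisfies ``phi_j(xi_i) = delta_ij``.
    """
    N = basis.order
    if not 0 <= j <= N:
        raise IndexError("basis index out of range")
    if abs(xi) > 1.0 + 1e-12:
        raise ValueError("reference coordinate outside [-1, 1]")
    xj = basis.nodes[j]
    if abs(xi - xj) < 1e-13:
        return 1.0
    num = (xi * xi - 1.0) * legendre_deriv(N, xi)
    den = N * (N + 1) * legendre_eval(N, xj) * (xi - xj)
    return num / den


@dataclass(frozen=True)
class ElementMap:
    """Affine bijection between the reference interval [-1, 1] and a
    physical interval [x_a, x_b]."""

    x_a: float
    x_b: float

    def __post_init__(self):
        if not self.x_b > self.x_a:
            raise ValueError("element must have positive length")

    @property
    def h(self) -> float:
        return self.x_b - self.x_a

    def forward(self, xi):
        xi = np.asarray(xi, dtype=float)
        if np.any(np.abs(xi) > 1.0 + 1e-12):
            raise ValueError("reference coordinate outside [-1, 1]")
        x = 0.5 * self.h * xi + 0.5 * (self.x_a + self.x_b)
        return x if x.ndim else float(x)

    def inverse(self, x):
        x = np.asarray(x, dtype=float)
        if np.any((x < self.x_a - 1e-12) | (x > self.x_b + 1e-12)):
            raise ValueError("physical coordinate outside the element")
        xi = (2.0 * x - (self.x_a + self.x_b)) / self.h
        return xi if xi.ndim else float(xi)


@dataclass(frozen=True)
class GalerkinOperators1D:
    """Mass (diagonal), stiffness and load operators on one element.

    ``mass[i,i] = (h/2) w_i``; ``stiffness = (2/h) d^T W d`` (the Galerkin
    matrix of ``-d^2/dx^2`` before sign conventions, symmetric PSD with the
    constant vector in its null space); ``load_i = (h/2) w_i`` is the load
    of the constant-1 function, so ``load = mass @ 1`` exactly.
    """

    basis: GLLBasis
    element: ElementMap
    mass: np.ndarray = field(repr=False)
    stiffness: np.ndarray = field(repr=False)
    load: np.ndarray = field(repr=False)


def assemble_1d(basis: GLLBasis, em: ElementMap) -> GalerkinOperators1D:
    """Assemble the 1-D GLL Galerkin operators on one element.

    The quadrature representation of the stiffness matrix is
    ``S_ij = (2/h) sum_k w_k phi_i'(xi_k) phi_j'(xi_k)
           = (2/h) (d^T W d)_ij``,
    exact because the integrand has degree 2N - 2 <= 2N - 1.
    """
    w = basis.weights
    h = em.h
    W = np.diag(w)
    S = (2.0 / h) * basis.diff.T @ W @ basis.diff
    S = 0.5 * (S + S.T)  # enforce exact symmetry against rounding
    K = (h / 2.0) * np.diag(w)
    C = (h / 2.0) * w.copy()
    return GalerkinOperators1D(basis=basis, element=em, mass=K,
                               stiffness=S, load=C)


@dataclass(frozen=True)
class GalerkinOperators2D:
    """Tensor-product operators on a rectangular element.

    ``stiffness_convention`` selects how the 2-D stiffness is formed:

    * ``"laplacian_consistent"`` (default):
      ``S = S_x (x) K_y + K_x (x) S_y`` - the Galerkin matrix of the 2-D
      Laplacian;
    * ``"tensor_literal"``: ``S = S_x (x) S_y`` - a pure tensor product.

    Both annihilate spatially constant vectors (``S_x @ 1 = 0``), so they
    coincide on uniform fields; they differ on non-uniform ones, where only
    the consistent form discretizes the Laplacian.
    """

    ops_x: GalerkinOperators1D
    ops_y: GalerkinOperators1D
    stiffness_convention: str
    mass: np.ndarray = field(repr=False)
    stiffness: np.ndarray = field(repr=False)
    load: np.ndarray = field(repr=False)
    dims: int = 2

    @property
    def n(self) -> int:
        return self.mass.shape[0]


def assemble_2d(ops_x: GalerkinOperators1D, ops_y: GalerkinOperators1D,
                convention: str = "laplacian_consistent") -> GalerkinOperators2D:
    """Tensor-product assembly: ``K = K_x (x) K_y``, ``C = C_x (x) C_y``,
    and the 2-D stiffness under the chosen convention."""
    if ops_x.basis.order != ops_y.basis.order:
        raise ValueError("tensor assembly requires equal orders per dimension")
    Kx, Ky = ops_x.mass, ops_y.mass
    Sx, Sy = ops_x.stiffness, ops_y.stiffness
    K = np.kron(Kx, Ky)
    C = np.kron(ops_x.load, ops_y.load)
    if convention == "laplacian_consistent":
        S = np.kron(Sx, Ky) + np.kron(Kx, Sy)
    elif convention == "tensor_literal":
        S = np.kron(Sx, Sy)
    else:
        raise ValueError(f"unknown stiffness convention: {convention!r}")
    return GalerkinOperators2D(ops_x=ops_x, ops_y=ops_y,
                               stiffness_convention=convention,
                               mass=K, stiffness=S, load=C)
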