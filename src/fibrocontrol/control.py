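"""Optimal regulator solve via Pontryagin's minimum principle.

The problem is the affine linear-quadratic regulator

    min  J = 1/2 int_0^tf [ q_m <m^2> + r_T eta_T^2 + r_G eta_G^2 ] dt
    s.t. d/dt m_hat = A m_hat + B_T eta_T + B_G eta_G + C_b,

free endpoint, no terminal cost.  ``<m^2>`` denotes the mean-square nodal
density, so the state penalty measures the physical density level
independently of the spectral order (a per-node Euclidean penalty is
selectable for strict replication; it multiplies the effective state
weight by the state dimension).

Stationarity of the Hamiltonian

    H = 1/2 (q_m <m^2> + r_T eta_T^2 + r_G eta_G^2)
        + lambda^T (A m + B_T eta_T + B_G eta_G + C_b)

gives ``eta_T* = -B_T^T lambda / r_T`` (and likewise for eta_G), and the
costate obeys ``d lambda/dt = -Q m - A^T lambda``.  The linear-feedback
ansatz ``lambda = P m + s`` (scalar mode: ``lambda = p m + c g``) yields
backward Riccati equations, integrated here by explicit Euler from the
terminal conditions ``P(tf) = 0``, ``s(tf) = 0`` implied by the free
endpoint.

Two solve modes are provided:

* ``"scalar"`` (default): the exact reduction of the problem to the
  spatially uniform manifold - a pair of scalar backward ODEs

      dp/dt = -(2 a p - (b_T^2/r_T + b_G^2/r_G) p^2 + q_m)
      ds/dt = -((a - (b_T^2/r_T + b_G^2/r_G) p) s + p c),  s = c g,

  with ``a = -d_m``.  Valid because the dynamics, the controls and the
  initial data are spatially uniform, so the full solution never leaves
  the uniform manifold.
* ``"matrix"``: the full n-dimensional Riccati sweep, used as the
  verification oracle.  With the mean-square state weighting the
  aggregates ``1^T P 1`` and ``1^T s`` obey exactly the scalar flows, so
  both modes agree to rounding on uniform problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import SemiDiscreteSystem
from .simulate import IntegrationError, TimeGrid

__all__ = [
    "CostWeights",
    "RiccatiPath",
    "ControlSolution",
    "riccati_backward",
    "synthesize_controls",
    "closed_loop_solve",
    "duration_above_threshold",
    "NEVER",
]

#: Sentinel returned by :func:`duration_above_threshold` when the series
#: never settles below the threshold within the horizon.
NEVER = math.inf

DEFAULT_CONTROL_THRESHOLD = 1e-3   # dimensionless efficacy
STATE_THRESHOLD_FRACTION = 0.01    # of the initial density


@dataclass(frozen=True)
class CostWeights:
    """Quadratic cost weights (state, anti-TGF-beta, anti-PDGF)."""

    q_m: float = 1.0
    r_T: float = 1.0
    r_G: float = 1.0

    def __post_init__(self):
        if self.q_m < 0:
            raise ValueError("state weight must be nonnegative")
        if self.r_T <= 0 or self.r_G <= 0:
            raise ValueError("control weights must be positive "
                             "(stationarity solve requires penalized controls)")


@dataclass
class RiccatiPath:
    """Backward-swept Riccati solution.

    Scalar mode stores ``p(t)`` and ``g(t)`` (costate offset ``s = c g``);
    matrix mode stores ``P(t)`` (n x n, symmetric PSD) and ``s(t)``
    (n-vector).  Terminal values are zero by the free-endpoint condition.
    """

    mode: str
    times: np.ndarray
    weights: CostWeights
    p: Optional[np.ndarray] = field(default=None, repr=False)
    g: Optional[np.ndarray] = field(default=None, repr=False)
    P: Optional[np.ndarray] = field(default=None, repr=False)
    s: Optional[np.ndarray] = field(default=None, repr=False)
    state_weighting: str = "mean"


@dataclass
class ControlSolution:
    """Closed-loop optimal solution and reporting summaries."""

    times: np.ndarray
    state_center: np.ndarray
    state_mean: np.ndarray
    min_series: np.ndarray
    max_series: np.ndarray
    eta_T: np.ndarray
    eta_G: np.ndarray
    costate: np.ndarray          # scalar aggregate lambda along the path
    gain_T: np.ndarray           # K_T(t) = -B_T^T p(t) (scalar aggregate)
    gain_G: np.ndarray
    offset_T: np.ndarray         # rho_T(t) = -c B_T^T g(t)
    offset_G: np.ndarray
    objective: float
    duration_eta_T: float
    duration_eta_G: float
    duration_state: float
    state_threshold: float
    control_threshold: float
    clamped: bool
    path: RiccatiPath = field(repr=False, default=None)

    @property
    def uniformity_defect(self) -> float:
        return float(np.max(self.max_series - self.min_series))


def _beta(sys: SemiDiscreteSystem, w: CostWeights) -> float:
    """Scalar control-authority coefficient b_T^2/r_T + b_G^2/r_G."""
    return sys.b_T**2 / w.r_T + sys.b_G**2 / w.r_G


def riccati_backward(sys: SemiDiscreteSystem, grid: TimeGrid,
                     w: CostWeights = CostWeights(), mode: str = "scalar",
                     state_weighting: str = "mean") -> RiccatiPath:
    """Backward explicit-Euler sweep of the (extended) Riccati equations.

    Scalar mode integrates the exact uniform reduction; matrix mode the
    full symmetric flow

        dP/dt = -(P A + A^T P - P (B_T B_T^T/r_T + B_G B_G^T/r_G) P + Q)
        ds/dt = -((A - (B_T B_T^T/r_T + B_G B_G^T/r_G) P)^T s + P C_b)

    with ``Q = (q_m/n) I`` under the default mean-square state weighting
    (``q_m I`` under ``state_weighting="per_node"``).  Terminal conditions
    are zero.  Non-finite growth is reported with the step index.
    """
    nst = grid.n_steps
    dt = grid.dt
    times = grid.times
    if mode == "scalar":
        a = sys.a_s
        beta = _beta(sys, w)
        c = sys.c
        p = np.zeros(nst + 1)
        g = np.zeros(nst + 1)
        for k in range(nst, 0, -1):
            pk, gk = p[k], g[k]
            pdot = -(2.0 * a * pk - beta * pk * pk + w.q_m)
            gdot = -((a - beta * pk) * gk + pk)
            p[k - 1] = pk - dt * pdot
            g[k - 1] = gk - dt * gdot
            if not (math.isfinite(p[k - 1]) and math.isfinite(g[k - 1])):
                raise IntegrationError(k - 1, "Riccati sweep diverged "
                                              f"at backward step {k - 1}")
        return RiccatiPath(mode="scalar", times=times, weights=w, p=p, g=g,
                           state_weighting=state_weighting)

    if mode != "matrix":
        raise ValueError(f"unknown Riccati mode: {mode!r}")
    n = sys.n
    A = sys.A
    Bmat = (np.outer(sys.B_T, sys.B_T) / w.r_T
            + np.outer(sys.B_G, sys.B_G) / w.r_G)
    if state_weighting == "mean":
        Q = (w.q_m / n) * np.eye(n)
    elif state_weighting == "per_node":
        Q = w.q_m * np.eye(n)
    else:
        raise ValueError(f"unknown state weighting: {state_weighting!r}")
    P = np.zeros((nst + 1, n, n))
    s = np.zeros((nst + 1, n))
    for k in range(nst, 0, -1):
        Pk, sk = P[k], s[k]
        PA = Pk @ A
        Pdot = -(PA + PA.T - Pk @ Bmat @ Pk + Q)
        sdot = -((A - Bmat @ Pk).T @ sk + Pk @ sys.C_b)
        P[k - 1] = Pk - dt * Pdot
        P[k - 1] = 0.5 * (P[k - 1] + P[k - 1].T)
        s[k - 1] = sk - dt * sdot
        if not np.isfinite(P[k - 1]).all() or not np.isfinite(s[k - 1]).all():
            raise IntegrationError(k - 1, "Riccati sweep diverged "
                                          f"at backward step {k - 1}")
    return RiccatiPath(mode="matrix", times=times, weights=w, P=P, s=s,
                       state_weighting=state_weighting)


def synthesize_controls(path: RiccatiPath, state: np.ndarray,
                        sys: SemiDiscreteSystem, w: CostWeights,
                        k: int):
    """Controls, costate and feedback form at stored time index ``k``.

    Returns ``(eta_T, eta_G, lam)`` where ``lam`` is the scalar costate
    aggregate: in scalar mode ``lam = p m_bar + c g`` acting on the uniform
    state ``m_bar``; in matrix mode ``lam`` is the full costate vector
    ``P m + s`` and the controls are ``-B^T lam / r``.
    """
    if path.mode == "scalar":
        m_bar = float(np.mean(state))
        lam = path.p[k] * m_bar + sys.c * path.g[k]
        eta_T = -sys.b_T * lam / w.r_T
        eta_G = -sys.b_G * lam / w.r_G
        return eta_T, eta_G, lam
    lam = path.P[k] @ state + path.s[k]
    eta_T = -(sys.B_T @ lam) / w.r_T
    eta_G = -(sys.B_G @ lam) / w.r_G
    return eta_T, eta_G, lam


def closed_loop_solve(sys: SemiDiscreteSystem, path: RiccatiPath,
                      ic: np.ndarray, grid: TimeGrid,
                      eval_weights: Optional[np.ndarray] = None,
                      clamp: bool = False,
                      state_threshold: Optional[float] = None,
                      control_threshold: float = DEFAULT_CONTROL_THRESHOLD
                      ) -> ControlSolution:
    """Forward Euler of the closed-loop affine system with stored feedback.

    The controls are synthesized from the Riccati path at every step;
    the objective is evaluated by trapezoidal quadrature of the running
    cost along the realized trajectory.  ``clamp=True`` projects the
    *recorded* controls onto [0, 1] and integrates with the projected
    values (off by default; no bounds appear in the optimality system).
    """
    w = path.weights
    m = np.array(ic, dtype=float)
    n = sys.n
    if eval_weights is None:
        eval_weights = np.zeros(n)
        eval_weights[n // 2] = 1.0
    nst = grid.n_steps
    dt = grid.dt
    center = np.empty(nst + 1)
    mean = np.empty(nst + 1)
    lo = np.empty(nst + 1)
    hi = np.empty(nst + 1)
    eT = np.empty(nst + 1)
    eG = np.empty(nst + 1)
    lam_agg = np.empty(nst + 1)
    run_cost = np.empty(nst + 1)

    def running_cost(state, eta_T, eta_G):
        if path.state_weighting == "per_node" and path.mode == "matrix":
            sq = float(state @ state)
        else:
            sq = float(np.mean(state * state))
        return 0.5 * (w.q_m * sq + w.r_T * eta_T**2 + w.r_G * eta_G**2)

    for k in range(nst + 1):
        eta_T, eta_G, lam = synthesize_controls(path, m, sys, w, k)
        if clamp:
            eta_T = min(max(eta_T, 0.0), 1.0)
            eta_G = min(max(eta_G, 0.0), 1.0)
        center[k] = eval_weights @ m
        mean[k] = m.mean()
        lo[k] = m.min()
        hi[k] = m.max()
        eT[k] = eta_T
        eG[k] = eta_G
        lam_agg[k] = (float(np.mean(lam)) if path.mode == "matrix"
                      else float(lam))
        run_cost[k] = running_cost(m, eta_T, eta_G)
        if k < nst:
            m = m + dt * (sys.A @ m + sys.B_T * eta_T + sys.B_G * eta_G
                          + sys.C_b)
            if not math.isfinite(np.abs(m).max()):
                raise IntegrationError(k + 1)

    J = float(np.trapezoid(run_cost, dx=dt))
    if path.mode == "scalar":
        gain_T = -sys.b_T * path.p / w.r_T
        gain_G = -sys.b_G * path.p / w.r_G
        off_T = -sys.c * sys.b_T * path.g / w.r_T
        off_G = -sys.c * sys.b_G * path.g / w.r_G
    else:
        ones = np.ones(n)
        pg = np.array([ones @ P @ ones for P in path.P])
        sg = path.s @ ones
        gain_T = -sys.b_T * pg / w.r_T
        gain_G = -sys.b_G * pg / w.r_G
        off_T = -sys.b_T * sg / w.r_T
        off_G = -sys.b_G * sg / w.r_G

    if state_threshold is None:
        state_threshold = STATE_THRESHOLD_FRACTION * sys.params.m0
    times = grid.times
    return ControlSolution(
        times=times, state_center=center, state_mean=mean,
        min_series=lo, max_series=hi, eta_T=eT, eta_G=eG,
        costate=lam_agg, gain_T=gain_T, gain_G=gain_G,
        offset_T=off_T, offset_G=off_G, objective=J,
        duration_eta_T=duration_above_threshold(eT, times, control_threshold),
        duration_eta_G=duration_above_threshold(eG, times, control_threshold),
        duration_state=duration_above_threshold(center, times,
                                                state_threshold),
        state_threshold=state_threshold,
        control_threshold=control_threshold,
        clamped=clamp, path=path)


def duration_above_threshold(series, times, threshold: float) -> float:
    """First grid time at which ``series`` falls below ``threshold`` and
    stays below for the rest of the horizon.

    Returns the first grid time of the terminal below-threshold run:
    ``times[0]`` if the whole series is below, :data:`NEVER` (+inf) if the
    series is at or above the threshold at the final time.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = series >= threshold
    if above[-1]:
        return NEVER
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return float(times[0])
    return float(times[idx[-1] + 1])
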