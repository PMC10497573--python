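"""Biological parameter set and semi-discrete state-space assembly.

The physical model is a homogenized reaction-diffusion equation for the
myofibroblast density ``m(x, y, t)`` on the injured region
``D = [0.3, 0.6]^2`` cm of lung tissue:

    dm/dt - r lap(m) = -d_m m + activation,

where ``r = a D_m / gamma`` is the effective (homogenized) diffusivity and
the activation term is Michaelis-Menten saturated recruitment of
fibroblasts by TGF-beta and PDGF:

    activation = (lam_T T/(K_T + T) (1 - eta_T)
               +  lam_G G/(K_G + G) (1 - eta_G)) f,

with ``eta_T, eta_G`` in [0, 1] the (dimensionless) efficacies of
anti-TGF-beta and anti-PDGF drugs.  The cytokine concentrations ``T`` and
``G`` are held at their initial values (no dynamics are modelled for them),
so activation is constant in space and time for fixed doses.

Galerkin projection onto the GLL Lagrange basis turns the PDE into the
affine linear ODE system

    d/dt m_hat = A m_hat + B_T eta_T + B_G eta_G + C_b,

with ``A = -d_m I + sigma r K^-1 S`` (``sigma`` the diffusion sign
convention), constant vectors ``B_T = b_T 1``, ``B_G = b_G 1`` and
``C_b = c 1``.  Because the stiffness annihilates constants, a spatially
uniform state evolves exactly by the scalar reduction

    dm/dt = -d_m m + b_T eta_T + b_G eta_G + c,

which this module records alongside the matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import yaml

from .spectral import (ElementMap, GLLBasis, GalerkinOperators2D, assemble_1d,
                       assemble_2d)

__all__ = [
    "ModelParams",
    "SemiDiscreteSystem",
    "saturation",
    "activation_constant",
    "homogenized_diffusivity",
    "assemble_system",
    "build_operators",
    "load_params",
]


@dataclass(frozen=True)
class ModelParams:
    """All model constants (units: cm, day, g/cm^3).

    Defaults are the published parameter set for idiopathic pulmonary
    fibrosis: myofibroblast diffusivity and death rate, TGF-beta/PDGF
    activation rates and saturation constants, the fibroblast density in
    the damaged region, initial concentrations, the two homogenization
    coefficients, the damaged-region extent per dimension and the control
    and simulation horizons.
    """

    D_m: float = 1.47e-5          # myofibroblast diffusion, cm^2/day
    d_m: float = 1.66e-2          # death (apoptosis) rate, 1/day
    lambda_mfT: float = 1.2e-1    # activation rate via TGF-beta, 1/day
    lambda_mfG: float = 1.2e-1    # activation rate via PDGF, 1/day
    K_TGF: float = 1e-10          # TGF-beta saturation constant, g/cm^3
    K_G: float = 1.5e-8           # PDGF saturation constant, g/cm^3
    f: float = 4.75e-3            # fibroblast density in D, g/cm^3
    m0: float = 8.5e-3            # initial myofibroblast density, g/cm^3
    T_GF0: float = 2.51e-12       # initial TGF-beta concentration, g/cm^3
    G0: float = 0.58e-3           # initial PDGF concentration, g/cm^3
    a: float = 0.11               # homogenized coefficient (dimensionless)
    gamma: float = 127.0 / 343.0  # homogenized coefficient (dimensionless)
    domain: tuple = (0.3, 0.6)    # damaged interval per dimension, cm
    t_f: float = 350.0            # control horizon, days
    t_end_sim: float = 400.0      # forward-simulation horizon, days

    def __post_init__(self):
        nonneg = ("D_m", "d_m", "lambda_mfT", "lambda_mfG", "K_TGF", "K_G",
                  "f", "m0", "T_GF0", "G0", "a")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        if self.t_f <= 0:
            raise ValueError("control horizon must be positive")
        if not self.domain[0] < self.domain[1]:
            raise ValueError("domain lower bound must be below upper bound")


def saturation(conc: float, K: float) -> float:
    """Michaelis-Menten saturation fraction ``conc / (K + conc)``."""
    if conc < 0:
        raise ValueError("concentration must be nonnegative")
    if K <= 0:
        raise ValueError("saturation constant must be positive")
    return conc / (K + conc)


def activation_constant(p: ModelParams) -> float:
    """Total activation source ``c`` (g cm^-3 day^-1) at the initial,
    time-invariant cytokine concentrations:

    ``c = (lam_T T0/(K_T + T0) + lam_G G0/(K_G + G0)) f``.
    """
    return (p.lambda_mfT * saturation(p.T_GF0, p.K_TGF)
            + p.lambda_mfG * saturation(p.G0, p.K_G)) * p.f


def homogenized_diffusivity(p: ModelParams) -> float:
    """Effective diffusivity ``r = a D_m / gamma`` (cm^2/day)."""
    if p.gamma <= 0:
        raise ValueError("gamma must be positive")
    return p.a * p.D_m / p.gamma


@dataclass(frozen=True)
class SemiDiscreteSystem:
    """State-space form of the Galerkin semi-discretization.

    ``A`` is n x n; ``B_T``, ``B_G`` and ``C_b`` are constant n-vectors
    (``b_T 1``, ``b_G 1``, ``c 1``).  The scalar reduction
    ``(a_s, b_T, b_G, c)`` is the exact dynamics of spatially uniform
    states and is independent of the spectral order.
    """

    params: ModelParams
    n: int
    A: np.ndarray = field(repr=False)
    B_T: np.ndarray = field(repr=False)
    B_G: np.ndarray = field(repr=False)
    C_b: np.ndarray = field(repr=False)
    a_s: float       # uniform-state decay coefficient (= -d_m)
    b_T: float       # anti-TGF-beta control coefficient, g cm^-3 day^-1
    b_G: float       # anti-PDGF control coefficient, g cm^-3 day^-1
    c: float         # activation constant, g cm^-3 day^-1
    r: float         # homogenized diffusivity, cm^2/day
    dims: int = 2
    diffusion_sign: str = "stable_minus_rS"


def build_operators(p: ModelParams, N: int, dims: int = 2,
                    convention: str = "laplacian_consistent"):
    """Assemble the Galerkin operators for the damaged region at order N.

    For ``dims == 1`` the 1-D operators are wrapped in the 2-D container
    with an identity second factor so downstream code is dimension-agnostic.
    """
    basis = GLLBasis.of_order(N)
    em = ElementMap(*p.domain)
    ops = assemble_1d(basis, em)
    if dims == 2:
        return assemble_2d(ops, ops, convention=convention)
    if dims == 1:
        return GalerkinOperators2D(ops_x=ops, ops_y=ops,
                                   stiffness_convention=convention,
                                   mass=ops.mass, stiffness=ops.stiffness,
                                   load=ops.load, dims=1)
    raise ValueError("dims must be 1 or 2")


def assemble_system(p: ModelParams, ops: GalerkinOperators2D,
                    diffusion_sign: str = "stable_minus_rS") -> SemiDiscreteSystem:
    """Build ``A``, ``B_T``, ``B_G``, ``C_b`` and the scalar reduction.

    ``diffusion_sign`` selects the sign carried by the stiffness term in
    ``A``: ``"stable_minus_rS"`` (the dissipative sign produced by
    integration by parts of the weak form; default) or ``"literal_plus_rS"``
    (anti-dissipative, kept for strict replication).  Both coincide on
    spatially uniform states since ``S @ 1 = 0``.

    The control vectors come out constant because the mass-weighted load of
    a constant is ``K @ 1``, so ``K^-1 (load of const) = const * 1``
    entrywise (exact in floating point: the load vector equals the mass
    diagonal).
    """
    K = ops.mass
    if not np.allclose(K, np.diag(np.diagonal(K))):
        raise AssertionError("mass matrix must be diagonal")
    if diffusion_sign == "stable_minus_rS":
        sigma = -1.0
    elif diffusion_sign == "literal_plus_rS":
        sigma = +1.0
    else:
        raise ValueError(f"unknown diffusion sign: {diffusion_sign!r}")

    r = homogenized_diffusivity(p)
    kdiag = np.diagonal(K)
    n = K.shape[0]
    A = sigma * r * (ops.stiffness / kdiag[:, None])
    A[np.diag_indices(n)] -= p.d_m

    b_T = -p.lambda_mfT * p.f * saturation(p.T_GF0, p.K_TGF)
    b_G = -p.lambda_mfG * p.f * saturation(p.G0, p.K_G)
    c = activation_constant(p)
    ones = np.ones(n)
    return SemiDiscreteSystem(params=p, n=n, A=A,
                              B_T=b_T * ones, B_G=b_G * ones, C_b=c * ones,
                              a_s=-p.d_m, b_T=b_T, b_G=b_G, c=c, r=r,
                              dims=ops.dims, diffusion_sign=diffusion_sign)


# --- configuration -----------------------------------------------------------

_PARAM_KEYS = {f.name for f in fields(ModelParams)}
_EXTRA_KEYS = {"N", "n_steps", "mode", "clamp", "q_m", "r_T", "r_G",
               "state_threshold", "control_threshold", "stiffness_convention",
               "diffusion_sign", "dims"}


def load_params(path: Optional[str] = None,
                overrides: Optional[dict] = None) -> tuple:
    """Read a flat key-value YAML config; return (ModelParams, extras dict).

    Unknown keys are rejected by name.  ``domain`` may be given as a
    two-element list.  Keys outside the biological parameter set (spectral
    order, step counts, solver flags) are passed back verbatim in the
    extras dict for the caller to interpret.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded:
            raw.update(loaded)
    if overrides:
        raw.update(overrides)
    unknown = set(raw) - _PARAM_KEYS - _EXTRA_KEYS
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    pkw = {k: v for k, v in raw.items() if k in _PARAM_KEYS}
    if "domain" in pkw:
        pkw["domain"] = tuple(float(v) for v in pkw["domain"])
    extras = {k: v for k, v in raw.items() if k in _EXTRA_KEYS}
    return ModelParams(**pkw), extras
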