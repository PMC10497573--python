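"""Study orchestration: reproducible runs, convergence tables, reports.

Four study kinds are provided, mirroring the published figures/tables:

* ``uncontrolled`` - forward solve of the drug-free model over the
  simulation horizon, one trajectory per spectral order;
* ``dose`` - forward solves at the printed constant dose pairs
  (0,0), (0.1,0.1), (0.3,0.3), (0.5,0.5);
* ``optimal`` - the regulator solve (backward Riccati sweep + closed loop)
  per order, including the center-density extraction at
  t = 50, 100, 150, 250 days;
* ``convergence`` - order-vs-order error tables of the uncontrolled and
  optimally controlled center series over step counts 4000/7000/10000.

Every artifact is CSV or JSON, embeds the fully resolved configuration,
and is byte-reproducible for identical configurations.  Cells whose
explicit-Euler integration is unstable (too-coarse steps for the stiffest
resolved mode) are recorded with an ``unstable`` flag rather than a value.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .control import (ControlSolution, CostWeights, closed_loop_solve,
                      riccati_backward, DEFAULT_CONTROL_THRESHOLD)
from .model import ModelParams, assemble_system, build_operators
from .simulate import (IntegrationError, TimeGrid, Trajectory, center_weights,
                       integrate_euler, write_trajectory_csv)
from .spectral import ElementMap

log = logging.getLogger("fibrocontrol")

__all__ = ["StudyConfig", "ConvergenceReport", "run_study", "center_density_table",
           "run_optimal", "run_uncontrolled"]

DOSE_PAIRS = [(0.0, 0.0), (0.1, 0.1), (0.3, 0.3), (0.5, 0.5)]
TABLE_TIMES = (50.0, 100.0, 150.0, 250.0)


@dataclass
class StudyConfig:
    """Configuration of a study run (all defaults = published conditions)."""

    kind: str = "optimal"                       # uncontrolled|dose|optimal|convergence
    orders: Sequence[int] = (16, 24, 32)
    step_counts: Sequence[int] = (4000, 7000, 10000)
    n_steps: int = 10000
    dims: int = 2
    mode: str = "scalar"                        # scalar|matrix Riccati
    stiffness_convention: str = "laplacian_consistent"
    diffusion_sign: str = "stable_minus_rS"
    clamp: bool = False
    weights: CostWeights = field(default_factory=CostWeights)
    state_threshold: Optional[float] = None
    control_threshold: float = DEFAULT_CONTROL_THRESHOLD
    error_norm: str = "max"                     # max | final
    outdir: Optional[str] = None
    seed: int = 0                               # reserved; the math is deterministic
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self):
        if self.kind not in ("uncontrolled", "dose", "optimal", "convergence"):
            raise ValueError(f"unknown study kind: {self.kind!r}")
        if any(N < 2 for N in self.orders):
            raise ValueError("spectral orders must be >= 2")
        if any(k < 1 for k in self.step_counts) or self.n_steps < 1:
            raise ValueError("step counts must be positive")

    def resolved(self) -> dict:
        d = asdict(self)
        d["orders"] = list(self.orders)
        d["step_counts"] = list(self.step_counts)
        d["params"]["domain"] = list(self.params.domain)
        return d


@dataclass
class ConvergenceReport:
    """Order-pair error table plus the per-(N, t) center-density slice."""

    entries: list              # dicts: system, steps, N, N_ref, error, norm, unstable
    center_table: dict               # {N: {t: center value}}
    config: dict


def _system(cfg: StudyConfig, N: int):
    ops = build_operators(cfg.params, N, dims=cfg.dims,
                          convention=cfg.stiffness_convention)
    sys = assemble_system(cfg.params, ops, diffusion_sign=cfg.diffusion_sign)
    em = ElementMap(*cfg.params.domain)
    xi = em.inverse(0.5 * (cfg.params.domain[0] + cfg.params.domain[1]))
    wts = center_weights(ops.ops_x.basis, xi, cfg.dims)
    return sys, wts


def run_uncontrolled(cfg: StudyConfig, N: int, n_steps: Optional[int] = None,
                     eta: tuple = (0.0, 0.0)) -> Trajectory:
    sys, wts = _system(cfg, N)
    grid = TimeGrid(0.0, cfg.params.t_end_sim, n_steps or cfg.n_steps)
    ic = cfg.params.m0 * np.ones(sys.n)
    return integrate_euler(sys, ic, grid, eta_T=eta[0], eta_G=eta[1],
                           eval_weights=wts)


def run_optimal(cfg: StudyConfig, N: int,
                n_steps: Optional[int] = None) -> ControlSolution:
    """Backward Riccati sweep + closed-loop forward solve at order N."""
    sys, wts = _system(cfg, N)
    grid = TimeGrid(0.0, cfg.params.t_f, n_steps or cfg.n_steps)
    path = riccati_backward(sys, grid, cfg.weights, mode=cfg.mode)
    ic = cfg.params.m0 * np.ones(sys.n)
    return closed_loop_solve(sys, path, ic, grid, eval_weights=wts,
                             clamp=cfg.clamp,
                             state_threshold=cfg.state_threshold,
                             control_threshold=cfg.control_threshold)


def _interp(times: np.ndarray, series: np.ndarray, t: float) -> float:
    """Linear interpolation in time (exact at grid points)."""
    return float(np.interp(t, times, series))


def center_density_table(solutions: dict, times: Sequence[float] = TABLE_TIMES) -> dict:
    """Center-density values at the published report times per order.

    ``solutions`` maps order -> ControlSolution.  Times outside the solved
    grid are rejected.  Values are linearly interpolated when a report time
    is not a grid point (the default raw step counts do not divide 350 into
    multiples of the report days).
    """
    out = {}
    for N, sol in solutions.items():
        if times and (min(times) < sol.times[0] - 1e-9
                      or max(times) > sol.times[-1] + 1e-9):
            raise ValueError("requested report time outside the solved grid")
        out[N] = {t: _interp(sol.times, sol.state_center, t) for t in times}
    return out


def _error(times, ref, other, norm: str) -> float:
    diff = np.abs(np.asarray(ref) - np.asarray(other))
    return float(diff.max() if norm == "max" else diff[-1])


def _convergence(cfg: StudyConfig) -> ConvergenceReport:
    orders = sorted(cfg.orders)
    N_ref = orders[-1]
    entries = []
    center_table = {}
    for steps in cfg.step_counts:
        series = {"uncontrolled": {}, "optimal": {}}
        for N in orders:
            try:
                tr = run_uncontrolled(cfg, N, n_steps=steps)
                series["uncontrolled"][N] = tr.center_series
            except IntegrationError as exc:
                series["uncontrolled"][N] = exc
            try:
                sol = run_optimal(cfg, N, n_steps=steps)
                series["optimal"][N] = sol.state_center
                if steps == cfg.n_steps:
                    center_table[N] = sol
            except IntegrationError as exc:
                series["optimal"][N] = exc
        for system in ("uncontrolled", "optimal"):
            ref = series[system][N_ref]
            for N in orders[:-1]:
                oth = series[system][N]
                unstable = isinstance(ref, IntegrationError) or isinstance(
                    oth, IntegrationError)
                err = (None if unstable
                       else _error(None, ref, oth, cfg.error_norm))
                entries.append({"system": system, "steps": steps, "N": N,
                                "N_ref": N_ref, "error": err,
                                "norm": cfg.error_norm, "unstable": unstable})
                if unstable:
                    log.warning("unstable Euler cell: %s N=%s steps=%s",
                                system, N if isinstance(oth, IntegrationError)
                                else N_ref, steps)
    t3 = center_density_table(center_table) if center_table else {}
    return ConvergenceReport(entries=entries, center_table=t3,
                             config=cfg.resolved())


def _write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _maybe_plot(outdir, name, plot_fn):
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    fig, ax = plt.subplots()
    plot_fn(ax)
    fig.savefig(os.path.join(outdir, name), dpi=110)
    plt.close(fig)


def run_study(cfg: StudyConfig) -> dict:
    """Execute a study and (optionally) write its report files.

    Returns a manifest dict; when ``cfg.outdir`` is set, CSV/JSON (and PNG)
    artifacts are written there deterministically.
    """
    outdir = cfg.outdir
    if outdir:
        os.makedirs(outdir, exist_ok=True)
    manifest = {"config": cfg.resolved(), "artifacts": []}

    def emit(name, writer):
        if outdir:
            path = os.path.join(outdir, name)
            writer(path)
            manifest["artifacts"].append(name)

    if cfg.kind == "uncontrolled":
        for N in cfg.orders:
            tr = run_uncontrolled(cfg, N)
            manifest[f"final_center_N{N}"] = float(tr.center_series[-1])
            emit(f"uncontrolled_N{N}.csv",
                 lambda p, tr=tr: write_trajectory_csv(p, tr))
        sys0, _ = _system(cfg, min(cfg.orders))
        manifest["plateau"] = float(sys0.c / cfg.params.d_m)

    elif cfg.kind == "dose":
        N = max(cfg.orders)
        sys, wts = _system(cfg, N)
        grid = TimeGrid(0.0, cfg.params.t_end_sim, cfg.n_steps)
        ic = cfg.params.m0 * np.ones(sys.n)
        for eta_T, eta_G in DOSE_PAIRS:
            tr = integrate_euler(sys, ic, grid, eta_T=eta_T, eta_G=eta_G,
                                 eval_weights=wts)
            manifest[f"final_center_dose_{eta_T}_{eta_G}"] = float(
                tr.center_series[-1])
            emit(f"dose_{eta_T}_{eta_G}_N{N}.csv",
                 lambda p, tr=tr: write_trajectory_csv(p, tr))

    elif cfg.kind == "optimal":
        sols = {N: run_optimal(cfg, N) for N in cfg.orders}
        manifest["center_table"] = {str(N): {str(t): v for t, v in row.items()}
                              for N, row in center_density_table(sols).items()}
        N = max(cfg.orders)
        sol = sols[N]
        manifest["objective"] = sol.objective
        manifest["duration_eta_T"] = sol.duration_eta_T
        manifest["duration_eta_G"] = sol.duration_eta_G
        manifest["duration_state"] = sol.duration_state
        manifest["thresholds"] = {"state": sol.state_threshold,
                                  "control": sol.control_threshold}
        def write_sol(path, sol=sol):
            with open(path, "w", newline="") as fh:
                wr = csv.writer(fh)
                wr.writerow(["t", "m_center", "eta_T", "eta_G",
                             "lambda_center", "p", "g"])
                pth = sol.path
                for k, t in enumerate(sol.times):
                    wr.writerow([repr(float(t)),
                                 repr(float(sol.state_center[k])),
                                 repr(float(sol.eta_T[k])),
                                 repr(float(sol.eta_G[k])),
                                 repr(float(sol.costate[k])),
                                 repr(float(pth.p[k])) if pth.p is not None else "",
                                 repr(float(pth.g[k])) if pth.g is not None else ""])
        emit(f"optimal_N{N}.csv", write_sol)
        emit("optimal_summary.json",
             lambda p: _write_json(p, {k: v for k, v in manifest.items()
                                       if k != "artifacts"}))
        if outdir:
            _maybe_plot(outdir, f"optimal_N{N}.png", lambda ax: (
                ax.plot(sol.times, sol.state_center),
                ax.set_xlabel("time (days)"),
                ax.set_ylabel("myofibroblast density (g/cm^3)")))
            _maybe_plot(outdir, f"controls_N{N}.png", lambda ax: (
                ax.plot(sol.times, sol.eta_T, label="eta_T"),
                ax.plot(sol.times, sol.eta_G, label="eta_G"),
                ax.legend(), ax.set_xlabel("time (days)")))

    elif cfg.kind == "convergence":
        rep = _convergence(cfg)
        manifest["entries"] = rep.entries
        manifest["center_table"] = {str(N): {str(t): v for t, v in row.items()}
                              for N, row in rep.center_table.items()}
        def write_table(path, rep=rep):
            with open(path, "w", newline="") as fh:
                wr = csv.writer(fh)
                wr.writerow(["system", "steps", "N", "N_ref", "error",
                             "norm", "unstable"])
                for e in rep.entries:
                    wr.writerow([e["system"], e["steps"], e["N"], e["N_ref"],
                                 "" if e["error"] is None else repr(e["error"]),
                                 e["norm"], e["unstable"]])
        emit("convergence.csv", write_table)
        emit("convergence.json", lambda p: _write_json(
            p, {"entries": rep.entries, "config": rep.config}))

    emit("manifest.json", lambda p: _write_json(p, manifest))
    return manifest
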