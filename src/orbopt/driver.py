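"""Iteration control: startup, convergence tests, method dispatch, tracing.

The driver runs any of the four optimizers (``gdiis``, ``r-gdiis``,
``rs-rfo``, ``s-gek-rvo``) against an energy/gradient oracle -- a molecular
fixture (through the bundled HF engine), a prebuilt :class:`ScfOracle`, or a
synthetic :class:`ModelSurface`.  Convergence follows the standard SCF
criteria: consecutive energy change below ``1e-9`` E_h, maximum
occupied-virtual Fock element below ``1.5e-4``, and a kappa-step norm below
``1e-3`` -- all three simultaneously -- with a hard cap of 400 total
iterations (startup included) after which the trace reports
``converged=False`` rather than raising.

For fixtures the startup is deliberately minimal and fully deterministic: a
core-Hamiltonian (or caller-provided) orbital guess followed by
``n_startup_iterations`` plain Roothaan steps.  Reported iteration counts
distinguish startup from post-startup work.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np


from .fixtures import MoleculeFixture
from .gek import CoincidentPointsError, build_model, characteristic_lengths
from .hf import ScfOracle, core_guess, roothaan_steps
from .implicit_hessian import ImplicitHessian
from .orbital_space import KappaVector, OrbitalPoint, SpinBlock
from .rgdiis import (
    DegenerateDIISError,
    DIISHistory,
    ResetAction,
    apply_reset_rules,
    error_vector,
    gdiis_solve_vanilla,
    gdiis_step,
    solve_c2diis,
)
from .rsrfo import DEFAULT_STEP_LIMIT, RESET_STEP_LIMIT, restrict_step
from .subspace_rvo import RVOPolicy, build_subspace, expand, project, project_hessian, rvo_step
from .surfaces import ModelSurface

__all__ = ["RunConfig", "IterationTrace", "optimize", "startup", "METHODS"]

METHODS = ("gdiis", "r-gdiis", "rs-rfo", "s-gek-rvo")


@dataclass(frozen=True)
class RunConfig:
    method: str = "r-gdiis"
    energy_tol: float = 1e-9
    fock_ov_max: float = 1.5e-4
    dkappa_norm: float = 1e-3
    max_total_iterations: int = 400
    guess: str = "core"  # "core" | "provided"
    n_startup_iterations: int = 2
    hessian_floor: float = 0.025
    bfgs_max_depth: int = 20
    diis_m_max: int = 5
    step_limit: float = DEFAULT_STEP_LIMIT
    sgek_m: int = 5
    rvo_init_factor: float = 0.3
    rvo_floor: float = 1e-6
    rvo_cap_factor: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        for name in ("energy_tol", "fock_ov_max", "dkappa_norm", "hessian_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IterationTrace:
    method: str
    rows: list[dict] = field(default_factory=list)
    startup_iterations: int = 0
    startup_energies: list[float] = field(default_factory=list)
    converged: bool = False
    final_energy: float = np.nan

    @property
    def post_startup_count(self) -> int:
        return len(self.rows)

    @property
    def total_iterations(self) -> int:
        return self.startup_iterations + self.post_startup_count

    def to_json(self, path: str) -> None:
        payload = {
            "method": self.method,
            "converged": self.converged,
            "final_energy": self.final_energy,
            "startup_iterations": self.startup_iterations,
            "startup_energies": self.startup_energies,
            "post_startup_count": self.post_startup_count,
            "rows": self.rows,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)

    def to_tsv(self, path: str) -> None:
        cols = ["iteration", "energy", "gradient_norm", "fock_ov_max", "step_norm", "events"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.rows:
                fh.write(
                    "\t".join(
                        [
                            str(row["iteration"]),
                            f"{row['energy']:.12f}",
                            f"{row['gradient_norm']:.6e}",
                            f"{row['fock_ov_max']:.6e}",
                            f"{row['step_norm']:.6e}",
                            ",".join(row["events"]) or "-",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# oracle adapters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Eval:
    energy: float
    gradient: np.ndarray
    fock_ov_max: float


class _ScfAdapter:
    def __init__(self, oracle: ScfOracle, config: RunConfig):
        self.oracle = oracle
        self.blocks = oracle.blocks
        self.dimension = oracle.dimension
        self.start = np.zeros(self.dimension)
        self._floor = config.hessian_floor
        self._seed = None

    def evaluate(self, x: np.ndarray) -> _Eval:
        ev = self.oracle(x)
        if self._seed is None:
            self._seed = self.oracle.hessian_diag_guess(ev, floor=self._floor)
        return _Eval(ev.energy, ev.gradient, ev.fock_ov_max)

    def hess_seed(self) -> np.ndarray:
        return self._seed

    def make_point(self, x: np.ndarray, ev: _Eval) -> OrbitalPoint:
        return OrbitalPoint(KappaVector(x, self.blocks), ev.energy, ev.gradient)


class _SurfaceAdapter:
    def __init__(self, surface: ModelSurface, config: RunConfig):
        self.surface = surface
        self.dimension = surface.dimension
        self.blocks = (SpinBlock(1, surface.dimension),)
        self.start = surface.start.copy()
        self._floor = config.hessian_floor

    def evaluate(self, x: np.ndarray) -> _Eval:
        e, g = self.surface(x)
        # surfaces report the per-spin-channel equivalent of max |F_ov|
        return _Eval(e, g, float(np.max(np.abs(g))) / 2.0 if g.size else 0.0)

    def hess_seed(self) -> np.ndarray:
        return np.maximum(self.surface.hessian_diag, self._floor)

    def make_point(self, x: np.ndarray, ev: _Eval) -> OrbitalPoint:
        return OrbitalPoint(KappaVector(x, self.blocks), ev.energy, ev.gradient)


# ---------------------------------------------------------------------------
# startup
# ---------------------------------------------------------------------------


def startup(fixture: MoleculeFixture, config: RunConfig, orbitals=None):
    """Initial-guess orbitals plus preliminary Roothaan iterations.

    Returns ``(oracle, startup_energies)``: an :class:`ScfOracle` whose
    reference orbitals are the startup result (so the benchmarked method
    starts at ``kappa = 0``) and the energies of the preliminary iterations.
    """
    if config.guess == "provided":
        if orbitals is None:
            raise ValueError("guess='provided' requires orbitals")
        C = orbitals
    elif config.guess == "core":
        C = core_guess(fixture)
    else:
        raise ValueError(f"unknown guess {config.guess!r}")
    C, energies = roothaan_steps(fixture, C, config.n_startup_iterations)
    return ScfOracle(fixture, C), energies


# ---------------------------------------------------------------------------
# method steppers
# ---------------------------------------------------------------------------


class _GDIISStepper:
    def __init__(self, adapter, hessian: ImplicitHessian, config: RunConfig, resetting: bool):
        self.adapter = adapter
        self.h = hessian
        self.config = config
        self.resetting = resetting
        self.history = DIISHistory(m_max=config.diis_m_max)
        self.solver = solve_c2diis if resetting else gdiis_solve_vanilla

    def propose(self, x, ev):
        events, diag = [], {}
        point = self.adapter.make_point(x, ev)
        self.history.push(point, error_vector(ev.gradient, self.h))
        if self.resetting:
            for action in apply_reset_rules(self.history, ev.energy):
                if action is not ResetAction.NONE:
                    events.append(action.value)
        try:
            x_new, sol = gdiis_step(self.history, self.h, solver=self.solver)
        except DegenerateDIISError:
            events.append("degenerate_diis_reset")
            self.history.set_depth(1, drop=True)
            x_new, sol = gdiis_step(self.history, self.h, solver=self.solver)
        if self.resetting:
            while np.linalg.norm(x_new - x) > RESET_STEP_LIMIT and self.h.depth > 0:
                events.append(ResetAction.REDUCE_BFGS_DEPTH.value)
                self.h.reduce_depth(self.h.depth - 1)
                self.history.errors[-1] = error_vector(ev.gradient, self.h)
                x_new, sol = gdiis_step(self.history, self.h, solver=self.solver)
            step = x_new - x
            norm = np.linalg.norm(step)
            if norm > RESET_STEP_LIMIT:  # seed-only Hessian still too bold
                x_new = x + step * (RESET_STEP_LIMIT / norm)
                events.append("step_clipped_pi")
        diag["diis_m"] = self.history.m
        diag["diis_coefficients"] = [float(c) for c in sol.coefficients]
        diag["predicted_error_sq"] = sol.predicted_error_sq
        return x_new, events, diag

    def notify(self, ev_new, dE):
        pass


class _RSRFOStepper:
    def __init__(self, adapter, hessian: ImplicitHessian, config: RunConfig):
        self.adapter = adapter
        self.h = hessian
        self.config = config

    def _predict(self, g):
        events = []
        step = restrict_step(g, self.h, self.config.step_limit)
        limit = self.config.step_limit
        if step.norm > RESET_STEP_LIMIT:
            self.h.reduce_depth(1)
            events.append("bfgs_depth_reset")
            limit = RESET_STEP_LIMIT
            step = restrict_step(g, self.h, limit)
        return step, limit, events

    def propose(self, x, ev):
        step, _, events = self._predict(ev.gradient)
        diag = {
            "alpha": step.alpha_final,
            "eigenvalue": step.eigenvalue,
            "restricted": step.restricted,
            "micro_iterations": step.micro_iterations,
        }
        return x + step.dkappa, events, diag

    def notify(self, ev_new, dE):
        pass


class _SGEKStepper:
    def __init__(self, adapter, hessian: ImplicitHessian, config: RunConfig):
        self.adapter = adapter
        self.h = hessian
        self.config = config
        self.rfo = _RSRFOStepper(adapter, hessian, config)
        self.policy = RVOPolicy(
            init_factor=config.rvo_init_factor,
            floor=config.rvo_floor,
            cap_factor=config.rvo_cap_factor,
        )
        self.points: list[OrbitalPoint] = []
        self.last_dE: float | None = None

    def propose(self, x, ev):
        cfg = self.config
        m = cfg.sgek_m
        self.points.append(self.adapter.make_point(x, ev))
        self.points = self.points[-max(m, 2) :]

        rfo_step_obj, limit, events = self.rfo._predict(ev.gradient)
        basis = build_subspace(self.points[-m:], ev.gradient, rfo_step_obj.dkappa)
        if basis.dim_reduced == 0:
            return x, events + ["empty_subspace"], {}

        Hr = project_hessian(basis, self.h)
        h_eig, W = np.linalg.eigh(Hr)
        lengths = characteristic_lengths(h_eig, floor=cfg.hessian_floor)

        # project the retained history into the current reduced eigenframe;
        # drop (older) points that collide after projection
        pts, energies, grads = [], [], []
        for p in reversed(self.points[-m:]):
            z = W.T @ project(basis, p.kappa.values - x)
            if any(np.linalg.norm((z - q) / lengths) <= 1e-8 for q in pts):
                continue
            pts.append(z)
            energies.append(p.energy)
            grads.append(W.T @ project(basis, p.gradient))
        pts, energies, grads = pts[::-1], energies[::-1], grads[::-1]

        g_r = W.T @ project(basis, ev.gradient)
        model = None
        try:
            model = build_model(np.array(pts), np.array(energies), np.array(grads), lengths)
        except (CoincidentPointsError, np.linalg.LinAlgError):
            events.append("gek_degenerate_fallback")

        if self.last_dE is None:
            # Newton-decrement scale of the expected first energy change
            est = float(np.dot(ev.gradient, ev.gradient)) / float(np.median(self.h.seed))
            self.last_dE = max(est, cfg.rvo_floor)
        vlimit = self.policy.limit(self.last_dE)
        z0 = np.zeros(basis.dim_reduced)
        res = rvo_step(model, z0, vlimit, limit, fallback=(g_r, np.diag(h_eig)))
        if res.used_fallback and "gek_degenerate_fallback" not in events:
            events.append("gek_degenerate_fallback")
        dkappa = expand(basis, W @ res.dz)
        diag = {
            "subspace_dim": basis.dim_reduced,
            "gek_points": len(pts),
            "gek_system_dim": (model.system_dimension if model is not None else 0),
            "variance_limit": vlimit,
            "predicted_std": res.predicted_std,
            "rvo_alpha": res.alpha,
            "rvo_micro_iterations": res.micro_iterations,
        }
        return x + dkappa, events, diag

    def notify(self, ev_new, dE):
        self.policy.update(dE < 0)
        self.last_dE = dE if dE != 0 else self.last_dE


def _make_stepper(method, adapter, hessian, config):
    if method == "gdiis":
        return _GDIISStepper(adapter, hessian, config, resetting=False)
    if method == "r-gdiis":
        return _GDIISStepper(adapter, hessian, config, resetting=True)
    if method == "rs-rfo":
        return _RSRFOStepper(adapter, hessian, config)
    if method == "s-gek-rvo":
        return _SGEKStepper(adapter, hessian, config)
    raise ValueError(method)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def optimize(target, config: RunConfig | None = None, orbitals=None) -> IterationTrace:
    """Run the configured optimizer to the SCF convergence criteria.

    ``target`` may be a :class:`MoleculeFixture` (startup is performed), a
    prebuilt :class:`ScfOracle` (no startup) or a :class:`ModelSurface`.
    Never raises on non-convergence: the trace carries ``converged=False``.
    """
    config = config or RunConfig()
    trace = IterationTrace(method=config.method)

    if isinstance(target, MoleculeFixture):
        oracle, startup_energies = startup(target, config, orbitals=orbitals)
        trace.startup_iterations = len(startup_energies)
        trace.startup_energies = [float(e) for e in startup_energies]
        adapter = _ScfAdapter(oracle, config)
    elif isinstance(target, ScfOracle):
        adapter = _ScfAdapter(target, config)
    elif isinstance(target, ModelSurface):
        adapter = _SurfaceAdapter(target, config)
    else:
        raise TypeError(f"cannot optimize a {type(target).__name__}")

    x = adapter.start.copy()
    ev = adapter.evaluate(x)
    trace.final_energy = ev.energy

    if ev.fock_ov_max < config.fock_ov_max:
        trace.converged = True  # already-converged input: zero iterations
        return trace

    hessian = ImplicitHessian(adapter.hess_seed(), max_depth=config.bfgs_max_depth)
    stepper = _make_stepper(config.method, adapter, hessian, config)

    while trace.startup_iterations + len(trace.rows) < config.max_total_iterations:
        x_new, events, diag = stepper.propose(x, ev)
        ev_new = adapter.evaluate(x_new)
        dx = x_new - x
        dE = ev_new.energy - ev.energy
        if np.linalg.norm(dx) > 0:
            hessian.push_pair(dx, ev_new.gradient - ev.gradient)
        stepper.notify(ev_new, dE)
        trace.rows.append(
            {
                "iteration": len(trace.rows) + 1,
                "energy": float(ev_new.energy),
                "energy_change": float(dE),
                "gradient_norm": float(np.linalg.norm(ev_new.gradient)),
                "fock_ov_max": float(ev_new.fock_ov_max),
                "step_norm": float(np.linalg.norm(dx)),
                "events": list(events),
                "method_internals": diag,
            }
        )
        converged = (
            abs(dE) < config.energy_tol
            and ev_new.fock_ov_max < config.fock_ov_max
            and float(np.linalg.norm(dx)) < config.dkappa_norm
        )
        x, ev = x_new, ev_new
        trace.final_energy = float(ev.energy)
        if converged:
            trace.converged = True
            break
    return trace


def gdiis_iterate(oracle, config: RunConfig | None = None, resetting: bool = True):
    """Convenience wrapper fixing the method to (r-)GDIIS."""
    config = config or RunConfig()
    method = "r-gdiis" if resetting else "gdiis"
    return optimize(oracle, replace(config, method=method))
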