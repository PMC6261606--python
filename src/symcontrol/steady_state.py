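"""Steady-state computation and continuation-style parameter scans.

Strategy: integrate the ODEs to quasi-stationarity with LSODA, then refine
the root of dS/dt with a Newton-type solver in log-concentration space
(which enforces positivity).  Scans seed each point from the previous
converged state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_core import KineticModel, ModelError

__all__ = [
    "SteadyState",
    "ScanResult",
    "CompiledModel",
    "compile_model",
    "find_steady_state",
    "parameter_scan",
    "log_grid",
]

INTEGRATION_TOL = 1e-6  # relative rate residual reached by integration
NEWTON_TOL = 1e-12  # residual target of the refinement step
FLUX_BALANCE_TOL = 1e-9


@dataclass
class SteadyState:
    concentrations: dict[str, float]
    fluxes: dict[str, float]
    residual: float
    converged: bool

    def flux_vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])

    def concentration_vector(self, species_ids: list[str]) -> np.ndarray:
        return np.array([self.concentrations[s] for s in species_ids])


class CompiledModel:
    """Lambdified rate laws plus the variable-species stoichiometric matrix.

    Parameters (including fixed-species values and per-reaction activity
    multipliers) are passed per call, so parameter scans and perturbations
    do not trigger recompilation.
    """

    def __init__(self, model: KineticModel):
        self.model = model
        self.species = model.variable_ids
        self.reactions = model.reaction_ids
        self.param_names = list(model.parameters) + [s.id for s in model.fixed_species]
        self.activity_names = [f"activity_{r}" for r in self.reactions]

        n_s, n_r = len(self.species), len(self.reactions)
        self.N = np.zeros((n_s, n_r))
        for j, r in enumerate(model.reactions):
            for sid, coef in r.stoichiometry.items():
                if sid in self.species:
                    self.N[self.species.index(sid), j] = coef

        args = (
            [sp.Symbol(s) for s in self.species]
            + [sp.Symbol(p) for p in self.param_names]
            + [sp.Symbol(a) for a in self.activity_names]
        )
        exprs = [
            sp.Symbol(a) * r.rate_law
            for a, r in zip(self.activity_names, model.reactions)
        ]
        self._rates = sp.lambdify(args, exprs, modules="numpy")
        self.base_params = np.array(
            [model.parameters[p] for p in model.parameters]
            + [s.initial_value for s in model.fixed_species]
        )

    def parameter_vector(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        p = self.base_params.copy()
        if overrides:
            for k, v in overrides.items():
                if k not in self.param_names:
                    raise ModelError(f"unknown parameter {k!r}")
                p[self.param_names.index(k)] = v
        return p

    def rates(
        self,
        conc: np.ndarray,
        params: np.ndarray | None = None,
        activities: np.ndarray | None = None,
    ) -> np.ndarray:
        p = self.base_params if params is None else params
        a = np.ones(len(self.reactions)) if activities is None else activities
        return np.asarray(self._rates(*conc, *p, *a), dtype=float)

    def dsdt(self, conc, params=None, activities=None) -> np.ndarray:
        return self.N @ self.rates(conc, params, activities)


def compile_model(model: KineticModel) -> CompiledModel:
    return CompiledModel(model)


def _residual(compiled: CompiledModel, conc, params, activities) -> float:
    v = compiled.rates(conc, params, activities)
    dsdt = compiled.N @ v
    scale = np.mean(np.abs(v)) or 1.0
    return float(np.max(np.abs(dsdt)) / scale) if len(dsdt) else 0.0


def find_steady_state(
    model: KineticModel | CompiledModel,
    initial: dict[str, float] | np.ndarray | None = None,
    tol: float = INTEGRATION_TOL,
    parameter_overrides: dict[str, float] | None = None,
    activities: dict[str, float] | None = None,
    max_time: float = 1e9,
) -> SteadyState:
    compiled = model if isinstance(model, CompiledModel) else CompiledModel(model)
    params = compiled.parameter_vector(parameter_overrides)
    act = np.ones(len(compiled.reactions))
    if activities:
        for rid, a in activities.items():
            act[compiled.reactions.index(rid)] = a

    if initial is None:
        y0 = np.array([compiled.model.species_by_id(s).initial_value for s in compiled.species])
    elif isinstance(initial, dict):
        y0 = np.array([initial[s] for s in compiled.species])
    else:
        y0 = np.asarray(initial, dtype=float)
    if np.any(y0 <= 0):
        raise ModelError("initial concentrations must be strictly positive")
    if not np.all(np.isfinite(compiled.rates(y0, params, act))):
        raise ModelError("non-finite rate evaluation at the initial point")

    y = y0.copy()
    if len(compiled.species) == 0:
        v = compiled.rates(y, params, act)
        return SteadyState({}, dict(zip(compiled.reactions, v)), 0.0, True)

    def g(u):
        return compiled.N @ compiled.rates(np.exp(u), params, act)

    def newton(start: np.ndarray) -> np.ndarray | None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = root(g, np.log(np.maximum(start, 1e-300)), method="hybr", tol=NEWTON_TOL)
        if res.success:
            cand = np.exp(res.x)
            if _residual(compiled, cand, params, act) <= tol:
                return cand
        return None

    # fast path: Newton directly from the start point when it is already
    # near-stationary (seeded from a neighbouring converged state); cold
    # starts integrate in bursts first so Newton cannot jump to a
    # non-attracting root
    best = newton(y) if _residual(compiled, y, params, act) < 1e-2 else None
    if best is None:
        t_end, elapsed = 10.0, 0.0
        for _ in range(10):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = solve_ivp(
                    lambda _t, yy: compiled.dsdt(np.maximum(yy, 1e-300), params, act),
                    (0.0, t_end),
                    y,
                    method="LSODA",
                    t_eval=[t_end],  # final point only: trajectories can be huge
                    rtol=1e-8,
                    atol=1e-12,
                )
            if sol.success and sol.y.size:
                y = np.maximum(sol.y[:, -1], 1e-300)
            elapsed += t_end
            if _residual(compiled, y, params, act) < tol or elapsed >= max_time:
                break
            best = newton(y)  # each burst may land in the Newton basin
            if best is not None:
                break
            t_end *= 10.0
        if best is None:
            refined = newton(y)
            best = refined if refined is not None else y

    resid = _residual(compiled, best, params, act)
    converged = bool(resid <= tol and np.all(best > 0) and np.all(np.isfinite(best)))
    v = compiled.rates(best, params, act)
    return SteadyState(
        concentrations=dict(zip(compiled.species, best)),
        fluxes=dict(zip(compiled.reactions, v)),
        residual=resid,
        converged=converged,
    )


@dataclass
class ScanResult:
    parameter: str
    values: np.ndarray
    states: list[SteadyState]
    model: KineticModel
    extra: dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        d = np.diff(self.values)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ModelError("scan values must be strictly monotone")

    @property
    def converged(self) -> np.ndarray:
        return np.array([s.converged for s in self.states])

    def fluxes(self) -> pd.DataFrame:
        return pd.DataFrame(
            [s.fluxes for s in self.states], index=pd.Index(self.values, name=self.parameter)
        ).rename(columns=lambda c: f"flux.{c}")

    def concentrations(self) -> pd.DataFrame:
        return pd.DataFrame(
            [s.concentrations for s in self.states],
            index=pd.Index(self.values, name=self.parameter),
        ).rename(columns=lambda c: f"conc.{c}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.concat([self.concentrations(), self.fluxes()], axis=1)
        df.insert(0, "converged", self.converged)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def log_grid(lo: float, hi: float, points: int = 200) -> np.ndarray:
    """Default scan grid: logarithmically spaced."""
    return np.geomspace(lo, hi, points)


def parameter_scan(
    model: KineticModel,
    parameter: str,
    values,
    initial: dict[str, float] | None = None,
    tol: float = INTEGRATION_TOL,
    max_failed_fraction: float = 0.10,
) -> ScanResult:
    """Continuation scan: each point is seeded from the previous converged
    state.  Aborts when more than ``max_failed_fraction`` of rows fail."""
    compiled = CompiledModel(model)
    if parameter not in compiled.param_names:
        raise ModelError(f"unknown parameter {parameter!r}")
    values = np.asarray(list(values), dtype=float)
    states: list[SteadyState] = []
    seed = initial
    failed: list[float] = []
    for val in values:
        st = find_steady_state(
            compiled, initial=seed, tol=tol, parameter_overrides={parameter: val}
        )
        states.append(st)
        if st.converged:
            seed = st.concentrations
        else:
            failed.append(val)
    if len(failed) > max_failed_fraction * len(values):
        raise ModelError(
            f"parameter scan of {parameter!r} failed to converge at "
            f"{len(failed)}/{len(values)} values: {failed[:10]}"
        )
    return ScanResult(parameter=parameter, values=values, states=states, model=model)
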