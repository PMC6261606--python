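"""Full-analysis orchestration: ratio transforms, scans, symbolic
control-coefficient expressions, pattern selection/factorization tables,
elasticity partitions, the equilibrium-constant perturbation experiment and
the fixed- versus free-ratio comparison."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .elasticities import partition_elasticity, symbolic_elasticities
from .model_core import KineticModel, ModelError, apply_ratio_transform, parse_model
from .patterns import (
    allocate_subpattern_coefficients,
    factorization_census,
    factorizations_to_json,
    factorize_pattern,
    group_by_dominance,
    quantify_patterns,
    select_dominant,
)
from .steady_state import ScanResult, find_steady_state, log_grid, parameter_scan
from .symca import (
    control_coefficient_expression,
    symbol_values,
    verify_theorems,
)
from .synthetic_models import load_fixture

log = logging.getLogger("symcontrol")

__all__ = [
    "AnalysisConfig",
    "run_full_analysis",
    "perturbation_experiment",
    "compare_fixed_free",
    "prepare_model",
    "free_ratio_scan",
]


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    model: str = "fixture:pyruvate_branch"
    transforms: dict[str, str] = field(
        default_factory=lambda: {"phiA": "free", "phiC": "free", "phiN": "fixed"}
    )
    scan_parameter: str = "phiN"
    scan_from: float = 2e-4
    scan_to: float = 1.77
    scan_points: int = 200
    scan_log: bool = True
    flux: str = "v6"
    reaction: str = "v3"
    selection_grid: tuple[int, int, int] = (1, 15, 1)
    coverage_floor: float = 70.0
    top_branch_reaction: str | None = "v8"
    perturbations: dict[str, float] = field(default_factory=dict)
    output_dir: str = "runs/analysis"

    def validate(self) -> None:
        if self.scan_points < 2:
            raise ModelError("scan needs at least two points")
        if not (self.scan_from > 0 and self.scan_to > 0) and self.scan_log:
            raise ModelError("log scan bounds must be positive")
        for mode in self.transforms.values():
            if mode not in ("free", "fixed"):
                raise ModelError(f"bad transform mode {mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.selection_grid, list):
            cfg.selection_grid = tuple(cfg.selection_grid)
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["selection_grid"] = list(self.selection_grid)
        return yaml.safe_dump(d, sort_keys=False)


def prepare_model(config: AnalysisConfig) -> KineticModel:
    """Load the model and apply the configured ratio transforms."""
    if config.model.startswith("fixture:"):
        model = load_fixture(config.model.split(":", 1)[1])
    else:
        model = parse_model(Path(config.model).read_text())
    for name, mode in config.transforms.items():
        rts = {r.ratio_symbol: r for r in model.ratios}
        if name not in rts:
            raise ModelError(f"model declares no ratio {name!r}")
        model = apply_ratio_transform(
            model, dataclasses.replace(rts[name], mode=mode)
        )
    if config.perturbations:
        model = model.with_parameters(**config.perturbations)
    return model


def _scan_grid(config: AnalysisConfig) -> np.ndarray:
    if config.scan_log:
        return log_grid(config.scan_from, config.scan_to, config.scan_points)
    return np.linspace(config.scan_from, config.scan_to, config.scan_points)


def run_full_analysis(config: AnalysisConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and write tables/reports to the run directory.

    Returns a summary dict (pattern counts, selection, census, groups) whose
    entries all trace to files in the run directory.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    summary: dict = {}
    t0 = time.time()

    def stage(name):
        log.info("stage %-22s t=%6.1fs", name, time.time() - t0)

    try:
        stage("prepare_model")
        model = prepare_model(config)

        stage("steady_state")
        state = find_steady_state(model)
        if not state.converged:
            raise ModelError("reference steady state did not converge")
        summary["reference_fluxes"] = dict(state.fluxes)

        stage("theorems")
        theorems = verify_theorems(model, state)
        (out / "theorem_report.json").write_text(
            json.dumps(
                {
                    "max_summation_residual": theorems.max_summation_residual,
                    "max_connectivity_residual": theorems.max_connectivity_residual,
                    "flagged": theorems.flagged(),
                },
                indent=2,
            )
        )
        summary["theorems_ok"] = theorems.ok

        stage("symbolic_inversion")
        expr = control_coefficient_expression(
            model, flux=config.flux, reaction=config.reaction, state=state
        )
        (out / "control_coefficient.json").write_text(expr.to_json())
        summary["n_patterns"] = expr.n_patterns

        stage("scan")
        scan = parameter_scan(model, config.scan_parameter, _scan_grid(config))
        scan.to_csv(out / "scan.csv")

        stage("quantify_patterns")
        elas = symbolic_elasticities(model)
        contribs = quantify_patterns(expr, scan, elas)
        contribs.to_csv(out / "patterns.csv")

        stage("select_dominant")
        lo, hi, step = config.selection_grid
        selection = select_dominant(
            contribs, grid_lo=lo, grid_hi=hi, grid_step=step,
            coverage_floor=config.coverage_floor,
        )
        selection.grid.to_csv(out / "selection_grid.csv", index=False)
        summary["selection"] = {
            "cutoff_contribution": selection.cutoff_contribution,
            "cutoff_span": selection.cutoff_span,
            "n_selected": selection.n_selected,
            "coverage": selection.coverage,
            "floor_met": selection.floor_met,
            "selected": selection.selected,
        }

        stage("factorize")
        facts = allocate_subpattern_coefficients(
            {
                p.id: factorize_pattern(model, p, config.flux, config.reaction)
                for p in expr.patterns
            }
        )
        (out / "factorizations.json").write_text(
            factorizations_to_json(list(facts.values()))
        )
        summary["census"] = factorization_census(list(facts.values()))

        stage("group_by_dominance")
        top = None
        if config.top_branch_reaction:
            top = {config.top_branch_reaction}
        groups = group_by_dominance(selection, contribs, facts, top)
        summary["groups"] = [
            {
                "patterns": g.patterns,
                "parameter_range": list(g.parameter_range),
            }
            for g in groups
        ]

        stage("elasticity_partitions")
        rows = []
        for val, stt in zip(scan.values, scan.states):
            if not stt.converged:
                continue
            overrides = {config.scan_parameter: float(val)}
            for r in model.reactions:
                for sid in model.variable_ids:
                    if elas.is_structural_zero(r.id, sid):
                        continue
                    if r.reversible and r.keq_ref is None:
                        continue
                    part = partition_elasticity(
                        model, r.id, sid, stt, elas, parameter_overrides=overrides
                    )
                    rows.append(
                        {
                            config.scan_parameter: val,
                            "reaction": r.id,
                            "species": sid,
                            "total": part.total,
                            "binding": part.binding,
                            "mass_action": part.mass_action,
                            "rho": part.rho,
                            "regime": part.regime,
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "elasticity_partitions.csv", index=False)

        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        stage("done")
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def perturbation_experiment(
    config: AnalysisConfig, parameter: str, factor: float
) -> dict:
    """Re-run the scan with one parameter multiplied by ``factor`` and
    report per-quantity maximum deviations from the reference run."""
    config.validate()
    ref_model = prepare_model(config)
    value = ref_model.parameters.get(parameter)
    if value is None:
        raise ModelError(f"unknown parameter {parameter!r}")
    pert_model = ref_model.with_parameters(**{parameter: value * factor})

    grid = _scan_grid(config)
    out: dict = {"parameter": parameter, "factor": factor}
    results = {}
    for label, model in (("reference", ref_model), ("perturbed", pert_model)):
        state = find_steady_state(model)
        expr = control_coefficient_expression(
            model, flux=config.flux, reaction=config.reaction, state=state
        )
        scan = parameter_scan(model, config.scan_parameter, grid)
        contribs = quantify_patterns(expr, scan)
        facts = allocate_subpattern_coefficients(
            {
                p.id: factorize_pattern(model, p, config.flux, config.reaction)
                for p in expr.patterns
            }
        )
        results[label] = (expr, contribs, facts)

    (_, ref_c, ref_f), (_, per_c, per_f) = results["reference"], results["perturbed"]
    # patterns match by factor content (ids are stable for identical structure)
    ref_cc, per_cc = ref_c.coefficient, per_c.coefficient
    denom = np.maximum(np.abs(ref_cc), 1e-12)
    out["coefficient_max_rel_dev"] = float(np.nanmax(np.abs(per_cc - ref_cc) / denom))

    pattern_devs = {}
    for pid in ref_c.values.columns:
        a = ref_c.values[pid].to_numpy()
        b = per_c.values[pid].to_numpy()
        pattern_devs[pid] = float(
            np.nanmax(np.abs(b - a) / np.maximum(np.abs(a), 1e-12))
        )
    out["pattern_max_rel_dev"] = pattern_devs
    out["max_pattern_shift"] = max(pattern_devs.values())
    return out


def free_ratio_scan(
    model_free: KineticModel,
    driver: str,
    ratio_symbol: str,
    target_range: tuple[float, float],
    points: int = 200,
    expand_limit: float = 1e8,
) -> tuple[ScanResult, np.ndarray]:
    """Scan a driver parameter (e.g. the NADH-oxidase Vmax) over a range wide
    enough that the realized ratio sweeps ``target_range``; returns the scan
    and the realized ratio per row (monotone axis for downstream analysis).

    The driver range is found adaptively: starting from the declared value
    the bounds are extended geometrically until the realized ratio covers
    the requested interval (or the expansion limit is hit).
    """
    v0 = model_free.parameters[driver]
    lo_t, hi_t = min(target_range), max(target_range)

    def realized(v, seed=None):
        st = find_steady_state(
            model_free, initial=seed, parameter_overrides={driver: v}
        )
        return st.concentrations[ratio_symbol], st

    lo_v = hi_v = v0
    phi0, st0 = realized(v0)
    # probe the response direction (a demand driver lowers the ratio, a
    # supply driver raises it)
    phi_probe, _ = realized(v0 * 2.0, st0.concentrations)
    lowers = phi_probe < phi0

    phi_lo = phi_hi = phi0
    seed_lo = seed_hi = st0.concentrations
    while phi_lo > lo_t and hi_v < v0 * expand_limit and lo_v > v0 / expand_limit:
        if lowers:
            hi_v *= 4.0
            phi_lo, st = realized(hi_v, seed_lo)
        else:
            lo_v /= 4.0
            phi_lo, st = realized(lo_v, seed_lo)
        seed_lo = st.concentrations
    while phi_hi < hi_t and lo_v > v0 / expand_limit and hi_v < v0 * expand_limit:
        if lowers:
            lo_v /= 4.0
            phi_hi, st = realized(lo_v, seed_hi)
        else:
            hi_v *= 4.0
            phi_hi, st = realized(hi_v, seed_hi)
        seed_hi = st.concentrations
    if phi_lo > lo_t or phi_hi < hi_t:
        raise ModelError(
            f"driver {driver!r} cannot sweep {ratio_symbol} over "
            f"[{lo_t}, {hi_t}] (reached [{phi_lo:.3g}, {phi_hi:.3g}])"
        )
    # order the driver grid so the realized ratio ascends
    grid = np.geomspace(hi_v, lo_v, points) if lowers else np.geomspace(lo_v, hi_v, points)
    scan = parameter_scan(model_free, driver, grid)
    phi = np.array([s.concentrations[ratio_symbol] for s in scan.states])
    return scan, phi


def compare_fixed_free(
    config: AnalysisConfig,
    driver: str = "V13",
    isolated_reaction: str = "v13",
    points: int = 60,
) -> dict:
    """Fixed-ratio versus free-ratio comparison.

    The free variant keeps the scanned ratio as a system variable and drives
    it by modulating ``driver``; rows are aligned by the realized ratio and
    fluxes compared (all reactions except the isolated demand reaction
    should agree).
    """
    config.validate()
    ratio = config.scan_parameter
    fixed_cfg = dataclasses.replace(
        config, transforms={**config.transforms, ratio: "fixed"}
    )
    free_cfg = dataclasses.replace(
        config, transforms={**config.transforms, ratio: "free"}
    )
    fixed_model = prepare_model(fixed_cfg)
    free_model = prepare_model(free_cfg)

    scan_free, phi = free_ratio_scan(
        free_model, driver, ratio, (config.scan_from, config.scan_to), points
    )
    keep = (phi >= config.scan_from) & (phi <= config.scan_to)
    # enforce a strictly increasing realized-ratio axis
    last = -np.inf
    for i in range(len(phi)):
        if keep[i]:
            if phi[i] <= last:
                keep[i] = False
            else:
                last = phi[i]
    phi_axis = phi[keep]
    free_states = [s for s, k in zip(scan_free.states, keep) if k]
    driver_values = scan_free.values[keep]

    # fixed model evaluated at the realized ratio values
    scan_fixed = parameter_scan(fixed_model, ratio, phi_axis)

    flux_dev: dict[str, float] = {}
    for rid in fixed_model.reaction_ids:
        a = np.array([s.fluxes[rid] for s in scan_fixed.states])
        b = np.array([s.fluxes[rid] for s in free_states])
        flux_dev[rid] = float(np.max(np.abs(a - b) / np.maximum(np.abs(a), 1e-9)))

    st_free = find_steady_state(free_model)
    expr_free = control_coefficient_expression(
        free_model, flux=config.flux, reaction=config.reaction, state=st_free
    )
    contribs = quantify_patterns(
        expr_free,
        ScanResult(
            parameter=driver,
            values=driver_values,
            states=free_states,
            model=free_model,
        ),
    )
    # selection operates on the realized-ratio axis (ascending)
    contribs.parameter_values = phi_axis
    lo, hi, step = config.selection_grid
    selection = select_dominant(
        contribs, grid_lo=lo, grid_hi=hi, grid_step=step,
        coverage_floor=config.coverage_floor,
    )
    return {
        "n_patterns_free": expr_free.n_patterns,
        "flux_max_rel_dev": flux_dev,
        "agree_except_isolated": all(
            dev < 1e-4 for rid, dev in flux_dev.items() if rid != isolated_reaction
        ),
        "isolated_reaction_dev": flux_dev.get(isolated_reaction),
        "free_selection": {
            "cutoff_contribution": selection.cutoff_contribution,
            "cutoff_span": selection.cutoff_span,
            "n_selected": selection.n_selected,
            "coverage": selection.coverage,
            "floor_met": selection.floor_met,
        },
        "realized_ratio_range": [float(phi_axis.min()), float(phi_axis.max())],
    }
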