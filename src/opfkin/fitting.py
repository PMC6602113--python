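"""Calibration and global parameter estimation for the reaction network.

Three layers, mirroring how the electrode experiments constrain the model:

1. ``calibrate_diffusion`` — the open measuring cell exchanges O2 with the
   environment; depleting O2 (dithionite) and watching it recover gives the
   exchange rate ``kdiff`` and the saturation level ``o2_sat`` from a
   single-exponential fit.
2. ``calibrate_ero1_dtt`` — assays containing only Ero1p and DTT isolate the
   oxidase branch; a joint least-squares fit over a DTT titration series pins
   ``k1`` (O2 reaction) and ``kdtt`` (DTT reduction of Ero1p disulfides).
3. ``fit_parameters`` — with the experimentally determined constants held
   fixed, the remaining constants are fitted to coupled-assay titration
   series by a derivative-free global search in log-parameter space,
   repeated from independent seeded starts; repeats are ranked by average
   RMSD and the per-constant spread across repeats serves as the
   identifiability diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, differential_evolution, least_squares

from .model import CONSTANT_NAMES, AssayConditions, RateConstants, SimulationError, simulate
from .traces import Trace

#: log10 bounds applied to every free second-order constant during fitting
LOG10_BOUNDS = (-8.0, 3.0)


@dataclass
class ExperimentSet:
    """Titration series: matched (conditions, measured trace) pairs."""

    experiments: Sequence[tuple[AssayConditions, Trace]]
    series_id: str = ""

    def __post_init__(self):
        if len(self.experiments) < 1:
            raise ValueError("an experiment set needs at least one experiment")
        self.experiments = tuple(self.experiments)

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)


@dataclass
class FitResult:
    constants: RateConstants
    per_experiment_rmsd: tuple[float, ...]
    repeat_index: int
    seed: int
    converged: bool
    objective: float
    n_evaluations: int

    @property
    def avg_rmsd(self) -> float:
        return float(np.mean(self.per_experiment_rmsd))


@dataclass
class FitEnsemble:
    """Repeat fits ranked ascending by average RMSD (ties by repeat index)."""

    results: tuple[FitResult, ...]
    spread: dict = field(default_factory=dict)

    def __post_init__(self):
        self.results = tuple(
            sorted(self.results, key=lambda r: (r.avg_rmsd, r.repeat_index))
        )

    @property
    def best(self) -> FitResult:
        return self.results[0]

    def constant_values(self, name: str) -> np.ndarray:
        return np.array([getattr(r.constants, name) for r in self.results])


def rmsd(model_trace: Trace, data_trace: Trace) -> float:
    """Root-mean-squared deviation between two traces on a shared grid (μM)."""
    if model_trace.t.shape != data_trace.t.shape or not np.allclose(
        model_trace.t, data_trace.t, rtol=0, atol=1e-9
    ):
        raise ValueError("traces are not on the same time grid")
    return float(np.sqrt(np.mean((model_trace.o2 - data_trace.o2) ** 2)))


def calibrate_diffusion(recovery_trace: Trace) -> tuple[float, float, dict]:
    """Fit O2(t) = o2_sat·(1 − exp(−kdiff·t)) to a depletion-recovery trace.

    Returns ``(kdiff, o2_sat, diagnostics)``; raises if the trace carries no
    recovery signal (flat or falling).
    """
    t = recovery_trace.t - recovery_trace.t[0]
    o2 = recovery_trace.o2
    rise = float(np.max(o2) - o2[0])
    if rise <= 0 or o2[-1] <= o2[0]:
        raise ValueError("no recovery signal: trace is flat or falling")

    def f(tt, kd, sat):
        return sat * (1.0 - np.exp(-kd * tt))

    sat0 = float(np.max(o2))
    kd0 = 1.0 / max(t[-1] / 3.0, 1e-6)
    popt, pcov = curve_fit(
        f, t, o2, p0=(kd0, sat0), bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=10000
    )
    kdiff, o2_sat = float(popt[0]), float(popt[1])
    resid = o2 - f(t, *popt)
    diagnostics = {
        "rmsd": float(np.sqrt(np.mean(resid**2))),
        "stderr": tuple(float(s) for s in np.sqrt(np.diag(pcov))),
        "n_points": int(t.size),
    }
    return kdiff, o2_sat, diagnostics


def _check_dtt_only(conditions: AssayConditions) -> None:
    if conditions.total_added(("PDI_ox", "PDI_mix", "PDI_red")) > 0:
        raise ValueError("DTT calibration experiments must not contain Pdi1p")
    if conditions.total_added(("GSH",)) > 0:
        raise ValueError("DTT calibration experiments must not contain GSH")
    if conditions.total_added(("ERO_rr", "ERO_r1", "ERO_act_ox", "ERO_act_red")) <= 0:
        raise ValueError("DTT calibration experiments must contain Ero1p")


def calibrate_ero1_dtt(
    dtt_experiments: ExperimentSet,
    k_template: RateConstants | None = None,
    x0: tuple[float, float] = (1e-2, 1e-4),
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> tuple[float, float, dict]:
    """Jointly fit ``k1`` and ``kdtt`` to an Ero1p/DTT titration series.

    The experiments must contain Ero1p and DTT only (no Pdi1p, no GSH); the
    fit is an unweighted least squares over every trace simultaneously, in
    log10-parameter space.  Returns ``(k1, kdtt, diagnostics)``.
    """
    k_template = k_template or RateConstants()
    for conditions, _trace in dtt_experiments:
        _check_dtt_only(conditions)
    if all(c.total_added(("DTT_red",)) <= 0 for c, _ in dtt_experiments):
        raise ValueError("no signal: DTT absent from every experiment")

    def residuals(logx):
        k1, kdtt = 10.0 ** logx
        k = k_template.with_values(k1=k1, kdtt=kdtt)
        res = []
        for conditions, trace in dtt_experiments:
            try:
                traj = simulate(conditions, k, rtol=rtol, atol=atol, eval_times=trace.t)
            except SimulationError:
                return np.full(sum(len(tr) for _, tr in dtt_experiments), 1e6)
            res.append(traj.species("O2") - trace.o2)
        return np.concatenate(res)

    sol = least_squares(
        residuals,
        x0=np.log10(np.asarray(x0)),
        bounds=(LOG10_BOUNDS[0], LOG10_BOUNDS[1]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    k1, kdtt = (float(v) for v in 10.0**sol.x)
    r = residuals(sol.x)
    diagnostics = {
        "rmsd": float(np.sqrt(np.mean(r**2))),
        "success": bool(sol.success),
        "n_experiments": len(dtt_experiments),
    }
    return k1, kdtt, diagnostics


def _objective_factory(
    experiments: ExperimentSet,
    template: RateConstants,
    free: tuple[str, ...],
    baseline_s: float,
    rtol: float,
    atol: float,
):
    masks = [trace.t >= trace.t[0] + baseline_s for _, trace in experiments]

    def objective(logx: np.ndarray) -> float:
        values = {n: float(10.0**v) for n, v in zip(free, logx)}
        k = template.with_values(**values)
        total = 0.0
        for (conditions, trace), mask in zip(experiments, masks):
            try:
                traj = simulate(conditions, k, rtol=rtol, atol=atol, eval_times=trace.t)
            except SimulationError:
                return 1e12
            d = traj.species("O2")[mask] - trace.o2[mask]
            total += float(d @ d)
        return total

    return objective


def fit_parameters(
    experiments: ExperimentSet,
    fixed: RateConstants | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    baseline_s: float = 100.0,
    maxiter: int = 200,
    popsize: int = 15,
    tol: float = 1e-8,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> FitEnsemble:
    """Repeated global fits of the free constants to a titration series.

    ``fixed`` supplies both the values of the held constants and, through its
    ``fixed`` mask, which constants are free (default mask fixes ``k1``,
    ``kdtt``, ``kdiff`` and ``o2_sat``).  Repeat ``r`` seeds its search with
    ``seed + r``; each repeat runs a differential-evolution search over
    log10-parameter bounds ``[-8, 3]`` followed by a local polish.  Results
    are ranked ascending by average per-experiment RMSD; a repeat that fails
    to converge is flagged but kept.
    """
    template = fixed or RateConstants()
    free = template.free
    if not free:
        raise ValueError("no free constants to fit")
    if n_repeats < 1:
        raise ValueError("need at least one repeat")

    objective = _objective_factory(experiments, template, free, baseline_s, rtol, atol)
    bounds = [LOG10_BOUNDS] * len(free)
    masks = [trace.t >= trace.t[0] + baseline_s for _, trace in experiments]
    polish_rtol, polish_atol = min(rtol, 1e-8), min(atol, 1e-10)

    def residuals(logx: np.ndarray) -> np.ndarray:
        values = {n: float(10.0**v) for n, v in zip(free, logx)}
        k = template.with_values(**values)
        res = []
        for (conditions, trace), mask in zip(experiments, masks):
            try:
                traj = simulate(conditions, k, rtol=polish_rtol, atol=polish_atol,
                                eval_times=trace.t)
            except SimulationError:
                return np.full(sum(int(m.sum()) for m in masks), 1e6)
            res.append(traj.species("O2")[mask] - trace.o2[mask])
        return np.concatenate(res)

    results = []
    for r in range(n_repeats):
        repeat_seed = seed + r
        de = differential_evolution(
            objective,
            bounds=bounds,
            seed=repeat_seed,
            maxiter=maxiter,
            popsize=popsize,
            tol=tol,
            init="latinhypercube",
            polish=False,
        )
        # residual-based local polish at tight solver tolerance: the global
        # search locates the basin, the least-squares step pins the minimum
        ls = least_squares(
            residuals, de.x, bounds=(LOG10_BOUNDS[0], LOG10_BOUNDS[1]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300,
        )
        x_best, f_best = (ls.x, 2.0 * ls.cost) if 2.0 * ls.cost < de.fun else (de.x, de.fun)
        values = {n: float(10.0**v) for n, v in zip(free, x_best)}
        k_fit = template.with_values(**values)
        per_rmsd = []
        for (conditions, trace), mask in zip(experiments, masks):
            traj = simulate(conditions, k_fit, rtol=rtol, atol=atol, eval_times=trace.t)
            d = traj.species("O2")[mask] - trace.o2[mask]
            per_rmsd.append(float(np.sqrt(np.mean(d**2))))
        results.append(
            FitResult(
                constants=k_fit,
                per_experiment_rmsd=tuple(per_rmsd),
                repeat_index=r,
                seed=repeat_seed,
                converged=bool(de.success or ls.success),
                objective=float(f_best),
                n_evaluations=int(de.nfev + ls.nfev),
            )
        )

    if not any(res.converged for res in results):
        # keep the ensemble anyway: ranking is still informative
        pass
    ensemble = FitEnsemble(results=tuple(results))
    ensemble.spread = _spread_statistics(ensemble, free)
    return ensemble


def _spread_statistics(ensemble: FitEnsemble, free: tuple[str, ...]) -> dict:
    stats = {}
    for name in free:
        vals = ensemble.constant_values(name)
        mean = float(np.mean(vals))
        stats[name] = {
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "median": float(np.median(vals)),
            "cv": float(np.std(vals) / mean) if mean > 0 else math.inf,
        }
    return stats


def fit_report_table(ensemble: FitEnsemble) -> "pandas.DataFrame":  # noqa: F821
    """Constants × repeats report with RMSD columns, in rank order."""
    import pandas as pd

    rows = []
    for rank, res in enumerate(ensemble.results, start=1):
        row = {"rank": rank, "repeat": res.repeat_index, "seed": res.seed,
               "converged": res.converged, "avg_rmsd_uM": res.avg_rmsd}
        row.update({n: getattr(res.constants, n) for n in CONSTANT_NAMES})
        for i, v in enumerate(res.per_experiment_rmsd):
            row[f"rmsd_exp{i}_uM"] = v
        rows.append(row)
    return pd.DataFrame(rows)
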