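"""Mass-action reaction network for Pdi1p/Ero1p-catalyzed oxygen consumption.

The network tracks electron flow from a small-molecule reductant (glutathione
in the coupled assay, DTT in the Ero1p-only calibration assay) through the
redox states of Pdi1p and Ero1p to molecular oxygen:

* Pdi1p cycles through three states of its single modeled active site:
  oxidized disulfide (``PDI_ox``), glutathionylated mixed intermediate
  (``PDI_mix``), and reduced dithiol (``PDI_red``).  GSH reduces PDI_ox in two
  sequential steps that share one rate constant ``kg``.
* Ero1p is produced in a fully oxidized, inactive form (``ERO_rr``: both
  regulatory disulfides intact) and is activated by two sequential reductions
  of its regulatory disulfides (``ka1``, ``ka2``), catalyzed by reduced Pdi1p.
  The activated enzyme cycles between ``ERO_act_ox`` and ``ERO_act_red`` via
  re-oxidation of Pdi1p (``kox``) and a single-step reaction with O2 (``k1``)
  that yields H2O2.
* DTT can reduce any Ero1p disulfide (``kdtt``); this branch drives the
  Pdi1p-free calibration assay.
* The measuring cell is open: O2 exchanges with the environment at rate
  ``kdiff`` toward the air-saturation level ``o2_sat``.

All concentrations are in μM and all times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .traces import Trace

#: Canonical species ordering used by every array-valued interface.
SPECIES: tuple[str, ...] = (
    "O2",
    "H2O2",
    "GSH",
    "GSSG",
    "DTT_red",
    "DTT_ox",
    "PDI_ox",
    "PDI_mix",
    "PDI_red",
    "ERO_rr",
    "ERO_r1",
    "ERO_act_ox",
    "ERO_act_red",
)

_IDX = {name: i for i, name in enumerate(SPECIES)}

PDI_SPECIES = ("PDI_ox", "PDI_mix", "PDI_red")
ERO_SPECIES = ("ERO_rr", "ERO_r1", "ERO_act_ox", "ERO_act_red")

#: Rate-constant names in canonical order.
CONSTANT_NAMES: tuple[str, ...] = ("k1", "kox", "ka1", "ka2", "kg", "kdtt", "kdiff", "o2_sat")


class SimulationError(RuntimeError):
    """Integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_good_time: float):
        super().__init__(f"{message} (last good time: {last_good_time:.6g} s)")
        self.last_good_time = last_good_time


@dataclass
class StateVector:
    """Concentrations (μM) of every redox species at one instant."""

    O2: float = 0.0
    H2O2: float = 0.0
    GSH: float = 0.0
    GSSG: float = 0.0
    DTT_red: float = 0.0
    DTT_ox: float = 0.0
    PDI_ox: float = 0.0
    PDI_mix: float = 0.0
    PDI_red: float = 0.0
    ERO_rr: float = 0.0
    ERO_r1: float = 0.0
    ERO_act_ox: float = 0.0
    ERO_act_red: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(SPECIES),):
            raise ValueError(f"expected {len(SPECIES)} species, got shape {y.shape}")
        return cls(**{s: float(v) for s, v in zip(SPECIES, y)})

    def validate(self) -> None:
        for s in SPECIES:
            v = getattr(self, s)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"concentration of {s} must be finite and >= 0, got {v}")

    @property
    def pdi_total(self) -> float:
        return self.PDI_ox + self.PDI_mix + self.PDI_red

    @property
    def ero_total(self) -> float:
        return self.ERO_rr + self.ERO_r1 + self.ERO_act_ox + self.ERO_act_red

    @property
    def glutathione_moieties(self) -> float:
        """Total GSH equivalents: free GSH + one per mixed disulfide + two per GSSG."""
        return self.GSH + self.PDI_mix + 2.0 * self.GSSG


# Default constants. k1 and the DTT branch are calibrated so that the
# Ero1p-only assay reproduces the measured maximal rate of 0.8 μM O2 per μM
# Ero1p per second at 10 mM DTT; kdiff and o2_sat describe the open electrode
# cell; the GSH-branch constants reproduce the coupled-assay phenomenology
# (lag phase, ~1.5 μM/s saturating maximum, Pdi1p saturation above ~15 μM at
# 1 μM Ero1p).  See docs/methods.md for the calibration procedure.
_DEFAULTS = {
    "k1": 0.02,                    # μM⁻¹ s⁻¹  ERO_act_red + O2 (experimentally fixed)
    "kox": 0.25,                   # μM⁻¹ s⁻¹  PDI_red + ERO_act_ox
    "ka1": 1.5e-3,                 # μM⁻¹ s⁻¹  first regulatory-disulfide reduction
    "ka2": 1.5e-3,                 # μM⁻¹ s⁻¹  second regulatory-disulfide reduction
    "kg": 0.05,                    # μM⁻¹ s⁻¹  both GSH steps (shared value)
    "kdtt": 9.753351536546294e-05,  # μM⁻¹ s⁻¹  DTT reduction of any Ero1p disulfide
    "kdiff": 0.002,                # s⁻¹       electrode-cell O2 exchange
    "o2_sat": 258.0,               # μM        air saturation near 25 °C
}

#: Constants held fixed during global fitting by default: k1 and kdiff are
#: determined experimentally (DTT assays, dithionite recovery), kdtt comes from
#: the same DTT calibration, and o2_sat is a property of the apparatus.
FIXED_DEFAULT = frozenset({"k1", "kdtt", "kdiff", "o2_sat"})


@dataclass
class RateConstants:
    """Kinetic parameters of the network (second-order constants in μM⁻¹s⁻¹).

    ``fixed`` marks which constants are held at their input values during
    fitting; the remainder are free.
    """

    k1: float = _DEFAULTS["k1"]
    kox: float = _DEFAULTS["kox"]
    ka1: float = _DEFAULTS["ka1"]
    ka2: float = _DEFAULTS["ka2"]
    kg: float = _DEFAULTS["kg"]
    kdtt: float = _DEFAULTS["kdtt"]
    kdiff: float = _DEFAULTS["kdiff"]
    o2_sat: float = _DEFAULTS["o2_sat"]
    fixed: frozenset = FIXED_DEFAULT

    def __post_init__(self):
        for name in CONSTANT_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")
        unknown = set(self.fixed) - set(CONSTANT_NAMES)
        if unknown:
            raise ValueError(f"unknown constants in fixed mask: {sorted(unknown)}")
        self.fixed = frozenset(self.fixed)

    @property
    def free(self) -> tuple[str, ...]:
        return tuple(n for n in CONSTANT_NAMES if n not in self.fixed)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in CONSTANT_NAMES}

    def with_values(self, **values: float) -> "RateConstants":
        return replace(self, **values)


@dataclass(frozen=True)
class Injection:
    """Instantaneous addition of species to the cell at a given time."""

    time: float
    increments: Mapping[str, float]

    def __post_init__(self):
        bad = set(self.increments) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species in injection: {sorted(bad)}")
        if any(v < 0 for v in self.increments.values()):
            raise ValueError("injection increments must be >= 0")


@dataclass
class AssayConditions:
    """Initial state, injection schedule, and sampling of one electrode run."""

    initial: StateVector
    injections: Sequence[Injection] = ()
    duration: float = 900.0
    sample_interval: float = 1.0
    diffusion_on: bool = True
    #: optional switch: regulatory disulfides also reduced directly by GSH
    gsh_activation: bool = False
    gsh_activation_rate: float = 0.0  # μM⁻¹ s⁻¹

    def __post_init__(self):
        self.initial.validate()
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.sample_interval <= 0:
            raise ValueError("sampling interval must be > 0")
        for inj in self.injections:
            if not 0 <= inj.time <= self.duration:
                raise ValueError(
                    f"injection at {inj.time} s outside [0, {self.duration}] s"
                )
        self.injections = tuple(sorted(self.injections, key=lambda i: i.time))

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.sample_interval))
        return np.linspace(0.0, n * self.sample_interval, n + 1)

    def total_added(self, species_group: Iterable[str]) -> float:
        """Total of a species group over initial state plus all injections."""
        total = sum(getattr(self.initial, s) for s in species_group)
        for inj in self.injections:
            total += sum(inj.increments.get(s, 0.0) for s in species_group)
        return total


@dataclass
class Trajectory:
    """Full-state time course on a strictly increasing grid, with provenance."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), len(SPECIES))
    conditions: AssayConditions
    constants: RateConstants
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.t.size, len(SPECIES)):
            raise ValueError("trajectory shape mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")

    def species(self, name: str) -> np.ndarray:
        return self.y[:, _IDX[name]]

    def state_at(self, i: int) -> StateVector:
        return StateVector.from_array(self.y[i])

    def o2_trace(self, **metadata) -> Trace:
        return Trace(t=self.t.copy(), o2=self.species("O2").copy(), metadata=dict(metadata))


def derivatives(
    state: StateVector | np.ndarray,
    k: RateConstants,
    diffusion_on: bool = True,
    gsh_activation_rate: float = 0.0,
) -> np.ndarray:
    """Mass-action time derivatives (μM/s), in ``SPECIES`` order.

    ``gsh_activation_rate`` > 0 enables the optional direct reduction of the
    Ero1p regulatory disulfides by GSH (two GSH consumed, one GSSG formed per
    disulfide), used only when the assay is configured for it.
    """
    if isinstance(state, StateVector):
        state.validate()
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
        if np.any(y < 0):
            raise ValueError("negative concentration in state")
    return _rhs(y, k, diffusion_on, gsh_activation_rate)


def _rhs(y: np.ndarray, k: RateConstants, diffusion_on: bool, kga: float) -> np.ndarray:
    (o2, _h2o2, gsh, _gssg, dtt_red, _dtt_ox,
     pdi_ox, pdi_mix, pdi_red, ero_rr, ero_r1, ero_ao, ero_ar) = y

    v_a1 = k.ka1 * ero_rr * pdi_red
    v_a2 = k.ka2 * ero_r1 * pdi_red
    v_r2 = k.kox * ero_ao * pdi_red
    v_r1 = k.k1 * ero_ar * o2
    v_g1 = k.kg * pdi_ox * gsh
    v_g2 = k.kg * pdi_mix * gsh
    v_d1 = k.kdtt * ero_rr * dtt_red
    v_d2 = k.kdtt * ero_r1 * dtt_red
    v_d3 = k.kdtt * ero_ao * dtt_red
    # optional GSH-driven activation of the regulatory disulfides
    v_ga1 = kga * ero_rr * gsh
    v_ga2 = kga * ero_r1 * gsh

    d = np.empty_like(y)
    d[_IDX["O2"]] = -v_r1 + (k.kdiff * (k.o2_sat - o2) if diffusion_on else 0.0)
    d[_IDX["H2O2"]] = v_r1
    d[_IDX["GSH"]] = -v_g1 - v_g2 - 2.0 * (v_ga1 + v_ga2)
    d[_IDX["GSSG"]] = v_g2 + v_ga1 + v_ga2
    d[_IDX["DTT_red"]] = -(v_d1 + v_d2 + v_d3)
    d[_IDX["DTT_ox"]] = v_d1 + v_d2 + v_d3
    d[_IDX["PDI_ox"]] = v_a1 + v_a2 + v_r2 - v_g1
    d[_IDX["PDI_mix"]] = v_g1 - v_g2
    d[_IDX["PDI_red"]] = v_g2 - v_a1 - v_a2 - v_r2
    d[_IDX["ERO_rr"]] = -v_a1 - v_d1 - v_ga1
    d[_IDX["ERO_r1"]] = v_a1 + v_d1 + v_ga1 - v_a2 - v_d2 - v_ga2
    d[_IDX["ERO_act_ox"]] = v_a2 + v_d2 + v_ga2 + v_r1 - v_r2 - v_d3
    d[_IDX["ERO_act_red"]] = v_r2 + v_d3 - v_r1
    return d


def simulate(
    conditions: AssayConditions,
    k: RateConstants,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    eval_times: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the network under the given assay conditions.

    The integration is stopped and restarted at every injection event with the
    injected species incremented; no event interpolation is used.  Output is
    reported on the conditions' sampling grid unless ``eval_times`` overrides
    it (used when evaluating a model against measured data on its own grid).
    """
    if eval_times is None:
        eval_times = conditions.time_grid()
    else:
        eval_times = np.asarray(eval_times, dtype=float)
        if eval_times.ndim != 1 or eval_times.size < 1 or np.any(np.diff(eval_times) <= 0):
            raise ValueError("eval_times must be a strictly increasing 1-D array")

    kga = conditions.gsh_activation_rate if conditions.gsh_activation else 0.0

    def rhs(_t, y):
        return _rhs(y, k, conditions.diffusion_on, kga)

    t_end = float(max(conditions.duration, eval_times[-1]))
    breaks = sorted({float(inj.time) for inj in conditions.injections})
    segment_edges = [0.0] + [b for b in breaks if 0.0 < b < t_end] + [t_end]
    inj_at = {}
    for inj in conditions.injections:
        inj_at.setdefault(float(inj.time), []).append(inj)

    y = conditions.initial.as_array()
    # injections scheduled at t=0 are applied before integration starts
    for inj in inj_at.get(0.0, []):
        for s, dv in inj.increments.items():
            y[_IDX[s]] += dv

    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    if eval_times[0] == 0.0:
        out_t.append(np.array([0.0]))
        out_y.append(y[None, :].copy())

    for t0, t1 in zip(segment_edges[:-1], segment_edges[1:]):
        mask = (eval_times > t0) & (eval_times <= t1)
        t_eval = eval_times[mask]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=t_eval if t_eval.size else None,
            dense_output=False,
        )
        if not sol.success:
            last = sol.t[-1] if len(sol.t) else t0
            raise SimulationError(f"ODE solver failed: {sol.message}", float(last))
        if t_eval.size:
            out_t.append(sol.t)
            out_y.append(sol.y.T)
        y = sol.y[:, -1].copy()
        for inj in inj_at.get(t1, []):
            for s, dv in inj.increments.items():
                y[_IDX[s]] += dv

    t = np.concatenate(out_t)
    ys = np.vstack(out_y)
    prov = {
        "solver": "LSODA",
        "rtol": rtol,
        "atol": atol,
        "constants": k.to_dict(),
        "diffusion_on": conditions.diffusion_on,
    }
    return Trajectory(t=t, y=ys, conditions=conditions, constants=k, provenance=prov)


def electron_balance(traj: Trajectory) -> float:
    """Maximum drift of the thiol-equivalent ledger along a trajectory (μM).

    Every electron pair drawn from a reduced thiol pool ends up either still in
    a thiol (GSH, mixed disulfide, reduced active sites, reduced regulatory
    disulfides, DTT) or in one H2O2.  The ledger

        T(t) = GSH + PDI_mix + 2·(PDI_red + DTT_red)
             + 2·(ERO_r1 + 2·ERO_act_ox + 3·ERO_act_red)

    (ERO_r1 carries one reduced regulatory pair; the activated forms carry two;
    ERO_act_red additionally carries its reduced active site) must satisfy
    T(t) + 2·H2O2(t) = const.  The glutathione-moiety ledger
    GSH + PDI_mix + 2·GSSG and the DTT ledger DTT_red + DTT_ox are checked
    alongside, since a corruption that swaps oxidized for reduced forms can
    leave the electron ledger itself untouched.  Returns the largest drift of
    any ledger relative to its value at t = 0, adjusted for injected amounts.
    """
    g = traj.species("GSH")
    mix = traj.species("PDI_mix")
    t_led = (
        g
        + mix
        + 2.0 * (traj.species("PDI_red") + traj.species("DTT_red"))
        + 2.0
        * (
            traj.species("ERO_r1")
            + 2.0 * traj.species("ERO_act_ox")
            + 3.0 * traj.species("ERO_act_red")
        )
    )
    injected_thiol = np.zeros_like(traj.t)
    injected_gsh = np.zeros_like(traj.t)
    injected_dtt = np.zeros_like(traj.t)
    for inj in traj.conditions.injections:
        after = traj.t > inj.time
        injected_thiol[after] += (
            inj.increments.get("GSH", 0.0)
            + inj.increments.get("PDI_mix", 0.0)
            + 2.0 * (inj.increments.get("PDI_red", 0.0) + inj.increments.get("DTT_red", 0.0))
            + 2.0
            * (
                inj.increments.get("ERO_r1", 0.0)
                + 2.0 * inj.increments.get("ERO_act_ox", 0.0)
                + 3.0 * inj.increments.get("ERO_act_red", 0.0)
            )
        )
        injected_gsh[after] += (
            inj.increments.get("GSH", 0.0)
            + inj.increments.get("PDI_mix", 0.0)
            + 2.0 * inj.increments.get("GSSG", 0.0)
        )
        injected_dtt[after] += inj.increments.get("DTT_red", 0.0) + inj.increments.get(
            "DTT_ox", 0.0
        )

    electron = t_led + 2.0 * traj.species("H2O2") - injected_thiol
    moiety = g + mix + 2.0 * traj.species("GSSG") - injected_gsh
    dtt = traj.species("DTT_red") + traj.species("DTT_ox") - injected_dtt
    return float(
        max(
            np.max(np.abs(ledger - ledger[0]))
            for ledger in (electron, moiety, dtt)
        )
    )
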