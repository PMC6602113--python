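"""In vivo capacity/demand calculus for oxidative protein folding in yeast.

Connects the in vitro kinetics to the cell: convert per-cell copy numbers of
Pdi1p and Ero1p to ER concentrations, estimate the proteome-wide demand for
disulfide-bond formation from abundance, cysteine count and turnover of every
protein transiting the secretory pathway, compare it with the supply capacity
of the Pdi1p population, and predict how overexpressing either enzyme changes
the pathway's maximal throughput.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import AssayConditions, Injection, RateConstants, SimulationError, simulate
from .traces import max_consumption_rate

AVOGADRO = 6.02214076e23

#: Pdi1p / Ero1p copy numbers per cell from proteome datasets; ER volume is
#: the midpoint of the 0.2–0.4 μm³ literature range; the per-molecule rate is
#: the saturating in vitro throughput of one Pdi1p molecule.
@dataclass
class CellParameters:
    pdi_copies: float = 28000.0       # molecules/cell
    ero_copies: float = 5200.0        # molecules/cell
    er_volume_um3: float = 0.3        # μm³
    doubling_time_min: float = 120.0  # min
    per_pdi_rate: float = 15.0        # disulfide bonds · min⁻¹ · molecule⁻¹

    def __post_init__(self):
        for name in ("er_volume_um3", "doubling_time_min", "per_pdi_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("pdi_copies", "ero_copies"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ProteomeEntry:
    """One protein of the ER/secretory proteome."""

    protein_id: str
    abundance: float        # molecules/cell
    n_cys: int              # cysteines per molecule
    deg_rate_per_min: float  # first-order degradation rate, min⁻¹

    def __post_init__(self):
        if self.abundance < 0:
            raise ValueError(f"{self.protein_id}: abundance must be >= 0")
        if int(self.n_cys) != self.n_cys or self.n_cys < 0:
            raise ValueError(f"{self.protein_id}: cysteine count must be a non-negative integer")
        if self.deg_rate_per_min < 0:
            raise ValueError(f"{self.protein_id}: degradation rate must be >= 0")

    @classmethod
    def from_half_life(
        cls, protein_id: str, abundance: float, n_cys: int, half_life_min: float
    ) -> "ProteomeEntry":
        if half_life_min <= 0:
            raise ValueError(f"{protein_id}: half-life must be > 0")
        return cls(protein_id, abundance, n_cys, math.log(2.0) / half_life_min)


@dataclass
class CapacityReport:
    demand_per_min: float              # k_Cys, cystines · min⁻¹ · cell⁻¹
    supply_per_min: float              # Pdi1p capacity, bonds · min⁻¹ · cell⁻¹
    contributions: dict = field(default_factory=dict)  # protein_id -> min⁻¹

    @property
    def supply_demand_ratio(self) -> float:
        return self.supply_per_min / self.demand_per_min


@dataclass
class OverexpressionCurve:
    """Normalized pathway capacity vs fold-overexpression of one enzyme."""

    scan: str                      # "pdi" or "ero"
    folds: np.ndarray
    fold_change: np.ndarray        # capacity relative to fold 1 (== 1.0 there)
    base_capacity: float           # μM O2/s at fold 1

    def __post_init__(self):
        self.folds = np.asarray(self.folds, dtype=float)
        self.fold_change = np.asarray(self.fold_change, dtype=float)

    def at(self, fold: float) -> float:
        i = int(np.argmin(np.abs(self.folds - fold)))
        if not math.isclose(self.folds[i], fold, rel_tol=1e-9, abs_tol=1e-12):
            raise KeyError(f"fold {fold} not on the computed grid")
        return float(self.fold_change[i])


def molecules_to_concentration(n_molecules: float, volume_um3: float) -> float:
    """Copy number in a compartment of given volume (μm³) → concentration (μM).

    1 μm³ = 1e-15 L, so c = n / (N_A · V·1e-15) mol/L, reported in μM.
    """
    if volume_um3 <= 0:
        raise ValueError("volume must be > 0")
    if n_molecules < 0:
        raise ValueError("molecule count must be >= 0")
    molar = n_molecules / (AVOGADRO * volume_um3 * 1e-15)
    return molar * 1e6


def k_cys(
    proteome: Sequence[ProteomeEntry], t_d: float = 120.0
) -> tuple[float, dict[str, float]]:
    """Proteome-wide maximum disulfide-formation demand (cystines · min⁻¹).

    At steady state each protein is synthesized at the rate balancing its
    first-order degradation plus dilution by growth, so the demand is

        k_Cys = Σ_i A_i · ⌊Cys_i / 2⌋ · (k_i + ln 2 / t_d)

    with A_i the abundance, Cys_i the cysteine count (only even numbers of
    cysteines can pair into disulfides, hence the floor), k_i the degradation
    rate, and t_d the culture doubling time in minutes.  Returns the total and
    per-protein contributions.
    """
    if t_d <= 0:
        raise ValueError("doubling time must be > 0")
    dilution = math.log(2.0) / t_d
    contributions: dict[str, float] = {}
    for entry in proteome:
        contributions[entry.protein_id] = (
            entry.abundance * (entry.n_cys // 2) * (entry.deg_rate_per_min + dilution)
        )
    return float(sum(contributions.values())), contributions


def round_to_one_sig_fig(x: float) -> float:
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def pdi_capacity(cell: CellParameters) -> tuple[float, float]:
    """Disulfide-formation capacity of the cellular Pdi1p population.

    Returns ``(capacity, capacity rounded to one significant figure)`` in
    bonds · min⁻¹ · cell⁻¹, assuming every Pdi1p molecule works at its
    saturating in vitro rate.
    """
    cap = cell.pdi_copies * cell.per_pdi_rate
    return float(cap), round_to_one_sig_fig(cap)


def capacity_report(
    proteome: Sequence[ProteomeEntry], cell: CellParameters | None = None
) -> CapacityReport:
    cell = cell or CellParameters()
    demand, contributions = k_cys(proteome, cell.doubling_time_min)
    supply, _ = pdi_capacity(cell)
    return CapacityReport(demand_per_min=demand, supply_per_min=supply,
                          contributions=contributions)


def _scaled_conditions(base: AssayConditions, scan: str, fold: float) -> AssayConditions:
    if scan == "pdi":
        group = ("PDI_ox", "PDI_mix", "PDI_red")
    elif scan == "ero":
        group = ("ERO_rr", "ERO_r1", "ERO_act_ox", "ERO_act_red")
    else:
        raise ValueError("scan must be 'pdi' or 'ero'")
    initial = replace(
        base.initial, **{s: getattr(base.initial, s) * fold for s in group}
    )
    injections = []
    for inj in base.injections:
        inc = {
            s: (v * fold if s in group else v) for s, v in inj.increments.items()
        }
        injections.append(Injection(inj.time, inc))
    return replace(base, initial=initial, injections=tuple(injections))


def predict_overexpression(
    k: RateConstants,
    base_conditions: AssayConditions,
    folds: Sequence[float],
    scan: str,
    window_s: float = 10.0,
    baseline_s: float = 100.0,
) -> OverexpressionCurve:
    """Predicted capacity fold-change when scaling one enzyme's total level.

    For each fold the scanned enzyme's total (initial plus injected) is
    scaled, the assay is simulated, and capacity is taken as the maximum
    windowed O2-consumption rate of the resulting trace (one O2 consumed per
    disulfide formed).  The curve is normalized to fold 1, which is always
    evaluated even if absent from the requested grid.
    """
    folds = np.asarray(sorted(set(float(f) for f in folds)), dtype=float)
    if np.any(folds < 0):
        raise ValueError("folds must be >= 0")

    def capacity_at(fold: float) -> float:
        try:
            traj = simulate(_scaled_conditions(base_conditions, scan, fold), k)
        except SimulationError as err:
            raise SimulationError(
                f"overexpression scan failed at fold {fold:g}", err.last_good_time
            ) from err
        return max_consumption_rate(traj.o2_trace(), window_s, baseline_s)

    base = capacity_at(1.0)
    values = np.array(
        [base if math.isclose(f, 1.0) else capacity_at(f) for f in folds]
    )
    return OverexpressionCurve(
        scan=scan, folds=folds, fold_change=values / base, base_capacity=base
    )
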