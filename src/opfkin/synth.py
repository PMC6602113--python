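"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the three kinds of electrode experiment (coupled GSH assays with the
enzyme injected after a 100-s baseline, Ero1p-only DTT assays, and
dithionite-depletion/recovery runs) plus per-protein proteome tables of
abundance, cysteine count and turnover.  Electrode noise is modeled as iid
Gaussian readings with an optional slow linear drift; every generator is
seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .capacity import ProteomeEntry
from .fitting import ExperimentSet
from .model import AssayConditions, Injection, RateConstants, StateVector, simulate
from .traces import Trace

#: Default titration grids (μM except DTT, which is listed in mM in protocols).
PDI_SCAN_UM = (1.0, 2.5, 5.0, 10.0, 15.0, 20.0)
ERO_SCAN_UM = (0.25, 0.5, 1.0, 2.0)
DTT_SCAN_MM = (1.0, 5.0, 10.0, 20.0)


@dataclass
class NoiseSpec:
    """Additive electrode noise: iid Gaussian sd (μM) plus linear drift (μM/s)."""

    sd: float = 1.0
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class ProteomeGeneratorConfig:
    """Sampling distributions for a synthetic ER/secretory proteome table.

    Abundances and half-lives are log-normal (median/shape parameterization),
    cysteine counts Poisson.  The defaults are calibrated so that the expected
    proteome-wide disulfide demand of a generated table, at a 120-min doubling
    time, matches the ~269,000 cystines/min scale estimated for the yeast
    secretory proteome (closed-form expectation; see docs/methods.md).
    """

    n_proteins: int = 4000
    abundance_median: float = 1976.0   # molecules/cell
    abundance_sigma: float = 1.2       # log-space sd
    cys_lambda: float = 4.0            # mean cysteines per protein
    half_life_median_min: float = 240.0
    half_life_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")
        for name in ("abundance_median", "abundance_sigma", "cys_lambda",
                     "half_life_median_min", "half_life_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def gsh_assay_conditions(
    pdi_uM: float,
    ero_uM: float,
    gsh_uM: float = 40000.0,
    o2_uM: float = 258.0,
    duration: float = 900.0,
    sample_interval: float = 1.0,
    ero_injection_time: float = 100.0,
) -> AssayConditions:
    """Coupled assay: Pdi1p (oxidized) + GSH equilibrate, Ero1p injected later."""
    return AssayConditions(
        initial=StateVector(O2=o2_uM, GSH=gsh_uM, PDI_ox=pdi_uM),
        injections=(Injection(ero_injection_time, {"ERO_rr": ero_uM}),),
        duration=duration,
        sample_interval=sample_interval,
        diffusion_on=True,
    )


def dtt_assay_conditions(
    ero_uM: float = 1.0,
    dtt_uM: float = 10000.0,
    o2_uM: float = 258.0,
    duration: float = 600.0,
    sample_interval: float = 1.0,
    dtt_injection_time: float = 100.0,
) -> AssayConditions:
    """Ero1p-only calibration assay: enzyme equilibrates, DTT injected later."""
    return AssayConditions(
        initial=StateVector(O2=o2_uM, ERO_rr=ero_uM),
        injections=(Injection(dtt_injection_time, {"DTT_red": dtt_uM}),),
        duration=duration,
        sample_interval=sample_interval,
        diffusion_on=True,
    )


def recovery_conditions(
    start_o2_uM: float = 0.0,
    duration: float = 1800.0,
    sample_interval: float = 1.0,
) -> AssayConditions:
    """Dithionite-depleted open cell with no enzymes: O2 relaxes to saturation."""
    return AssayConditions(
        initial=StateVector(O2=start_o2_uM),
        injections=(),
        duration=duration,
        sample_interval=sample_interval,
        diffusion_on=True,
    )


def generate_trace(
    k_true: RateConstants,
    conditions: AssayConditions,
    noise: NoiseSpec | None = None,
    **metadata,
) -> Trace:
    """Simulate an assay and overlay seeded electrode noise and drift."""
    noise = noise or NoiseSpec()
    traj = simulate(conditions, k_true)
    rng = np.random.default_rng(noise.seed)
    o2 = traj.species("O2").copy()
    if noise.sd > 0:
        o2 = o2 + rng.normal(0.0, noise.sd, size=o2.size)
    if noise.drift != 0.0:
        o2 = o2 + noise.drift * traj.t
    md = {"noise_sd_uM": noise.sd, "drift_uM_per_s": noise.drift, "seed": noise.seed}
    md.update(metadata)
    return Trace(t=traj.t.copy(), o2=o2, metadata=md)


def generate_titration_series(
    k_true: RateConstants,
    design: str,
    noise: NoiseSpec | None = None,
    grid: tuple[float, ...] | None = None,
    **assay_kwargs,
) -> ExperimentSet:
    """One synthetic titration series: ``pdi_scan``, ``ero_scan`` or ``dtt_scan``.

    Defaults follow the standard assay designs: Pdi1p ∈ {1, 2.5, 5, 10, 15,
    20} μM at 1 μM Ero1p and 40 mM GSH; Ero1p ∈ {0.25, 0.5, 1, 2} μM at 5 μM
    Pdi1p; DTT ∈ {1, 5, 10, 20} mM at 1 μM Ero1p.  Each member's noise stream
    is derived from the series seed and the member index.
    """
    noise = noise or NoiseSpec()
    if design == "pdi_scan":
        values = PDI_SCAN_UM if grid is None else grid
        make = lambda v: gsh_assay_conditions(pdi_uM=v, ero_uM=1.0, **assay_kwargs)
        label = "pdi_uM"
    elif design == "ero_scan":
        values = ERO_SCAN_UM if grid is None else grid
        make = lambda v: gsh_assay_conditions(pdi_uM=5.0, ero_uM=v, **assay_kwargs)
        label = "ero_uM"
    elif design == "dtt_scan":
        values = DTT_SCAN_MM if grid is None else grid
        make = lambda v: dtt_assay_conditions(ero_uM=1.0, dtt_uM=v * 1000.0, **assay_kwargs)
        label = "dtt_mM"
    else:
        raise ValueError("design must be one of: pdi_scan, ero_scan, dtt_scan")
    if len(values) == 0:
        raise ValueError("titration grid is empty")

    experiments = []
    seeds = np.random.SeedSequence(noise.seed).spawn(len(values))
    for i, v in enumerate(values):
        conditions = make(v)
        member_noise = NoiseSpec(sd=noise.sd, drift=noise.drift, seed=0)
        traj_trace = _trace_with_seedseq(
            k_true, conditions, member_noise, seeds[i],
            metadata={"series": design, label: v, "member": i},
        )
        experiments.append((conditions, traj_trace))
    return ExperimentSet(experiments=experiments, series_id=design)


def _trace_with_seedseq(k_true, conditions, noise, seedseq, metadata):
    traj = simulate(conditions, k_true)
    rng = np.random.default_rng(seedseq)
    o2 = traj.species("O2").copy()
    if noise.sd > 0:
        o2 = o2 + rng.normal(0.0, noise.sd, size=o2.size)
    if noise.drift != 0.0:
        o2 = o2 + noise.drift * traj.t
    md = {"noise_sd_uM": noise.sd, "drift_uM_per_s": noise.drift}
    md.update(metadata)
    return Trace(t=traj.t.copy(), o2=o2, metadata=md)


def generate_proteome(cfg: ProteomeGeneratorConfig) -> list[ProteomeEntry]:
    """Sample a synthetic proteome table of abundance / cysteines / turnover.

    Abundance, cysteine and half-life draws come from independent child
    streams of the config seed, so rescaling one distribution's parameters
    leaves the other fields' draws unchanged.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_a = np.random.default_rng(ss[0])
    rng_c = np.random.default_rng(ss[1])
    rng_h = np.random.default_rng(ss[2])

    n = cfg.n_proteins
    abundance = cfg.abundance_median * np.exp(
        cfg.abundance_sigma * rng_a.standard_normal(n)
    )
    n_cys = rng_c.poisson(cfg.cys_lambda, size=n)
    half_life = cfg.half_life_median_min * np.exp(
        cfg.half_life_sigma * rng_h.standard_normal(n)
    )
    width = len(str(n))
    return [
        ProteomeEntry(
            protein_id=f"SYN{i:0{width}d}",
            abundance=float(abundance[i]),
            n_cys=int(n_cys[i]),
            deg_rate_per_min=math.log(2.0) / float(half_life[i]),
        )
        for i in range(n)
    ]
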