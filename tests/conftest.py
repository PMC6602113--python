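import numpy as np
import pytest

from opfkin import RateConstants

# Independent fixed-step oracle.  The right-hand side is written out from the
# reaction list by hand (not shared with the package) so that both the
# stoichiometry wiring and the adaptive integration path are cross-checked.

ORACLE_SPECIES = (
    "O2", "H2O2", "GSH", "GSSG", "DTT_red", "DTT_ox",
    "PDI_ox", "PDI_mix", "PDI_red", "ERO_rr", "ERO_r1", "ERO_act_ox", "ERO_act_red",
)


def oracle_rhs(y, k: RateConstants, diffusion_on: bool):
    s = dict(zip(ORACLE_SPECIES, y))
    flux = {name: 0.0 for name in ORACLE_SPECIES}

    def react(rate, consumed, produced):
        for sp in consumed:
            flux[sp] -= rate
        for sp in produced:
            flux[sp] += rate

    react(k.ka1 * s["ERO_rr"] * s["PDI_red"], ["ERO_rr", "PDI_red"], ["ERO_r1", "PDI_ox"])
    react(k.ka2 * s["ERO_r1"] * s["PDI_red"], ["ERO_r1", "PDI_red"], ["ERO_act_ox", "PDI_ox"])
    react(k.kox * s["ERO_act_ox"] * s["PDI_red"], ["ERO_act_ox", "PDI_red"],
          ["ERO_act_red", "PDI_ox"])
    react(k.k1 * s["ERO_act_red"] * s["O2"], ["ERO_act_red", "O2"], ["ERO_act_ox", "H2O2"])
    react(k.kg * s["PDI_ox"] * s["GSH"], ["PDI_ox", "GSH"], ["PDI_mix"])
    react(k.kg * s["PDI_mix"] * s["GSH"], ["PDI_mix", "GSH"], ["PDI_red", "GSSG"])
    for ero_from, ero_to in (("ERO_rr", "ERO_r1"), ("ERO_r1", "ERO_act_ox"),
                             ("ERO_act_ox", "ERO_act_red")):
        react(k.kdtt * s[ero_from] * s["DTT_red"], [ero_from, "DTT_red"], [ero_to, "DTT_ox"])
    if diffusion_on:
        flux["O2"] += k.kdiff * (k.o2_sat - s["O2"])
    return np.array([flux[name] for name in ORACLE_SPECIES])


def oracle_integrate(y0, k, t_end, h=0.005, diffusion_on=True, record_at=None):
    """Classic 4th-order Runge-Kutta at fixed step; records states at grid times."""
    y = np.asarray(y0, dtype=float).copy()
    n_steps = int(round(t_end / h))
    record_at = np.asarray(record_at if record_at is not None else [t_end], dtype=float)
    out = {}
    t = 0.0
    for i in range(n_steps):
        k1_ = oracle_rhs(y, k, diffusion_on)
        k2_ = oracle_rhs(y + 0.5 * h * k1_, k, diffusion_on)
        k3_ = oracle_rhs(y + 0.5 * h * k2_, k, diffusion_on)
        k4_ = oracle_rhs(y + h * k3_, k, diffusion_on)
        y = y + (h / 6.0) * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
        t = (i + 1) * h
        hits = record_at[np.isclose(record_at, t, rtol=0, atol=h / 4)]
        for tt in hits:
            out[float(tt)] = y.copy()
    return out


@pytest.fixture
def default_constants():
    return RateConstants()
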