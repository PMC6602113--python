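# opfkin

Kinetic modeling of oxidative protein folding (OPF) in the yeast endoplasmic
reticulum: the electron flow from glutathione through the disulfide-exchange
enzymes Pdi1p and Ero1p to molecular oxygen.

The package is aimed at quantitative biochemists working with Clarke-electrode
oxygen-consumption assays of the Pdi1p/Ero1p system, and at anyone asking the
follow-up systems question: does the measured in vitro throughput of these
enzymes cover the disulfide-bond demand of a growing yeast cell's secretory
proteome, and what would overexpressing either enzyme buy?

## The model

All species are tracked in μM and seconds.  Pdi1p's single modeled active
site cycles through oxidized (`PDI_ox`), glutathionylated (`PDI_mix`) and
reduced (`PDI_red`) states; Ero1p is produced inactive with both regulatory
disulfides intact (`ERO_rr`) and is activated by two sequential reductions of
those disulfides by reduced Pdi1p; the activated enzyme shuttles between
`ERO_act_ox` and `ERO_act_red` while passing electrons to O₂.  Mass-action
reactions (second-order constants, μM⁻¹s⁻¹):

    A1:  ERO_rr     + PDI_red → ERO_r1     + PDI_ox      (ka1)
    A2:  ERO_r1     + PDI_red → ERO_act_ox + PDI_ox      (ka2)
    R2:  ERO_act_ox + PDI_red → ERO_act_red + PDI_ox     (kox)
    R1:  ERO_act_red + O2     → ERO_act_ox + H2O2        (k1, fixed)
    G1:  PDI_ox  + GSH        → PDI_mix                  (kg)
    G2:  PDI_mix + GSH        → PDI_red + GSSG           (kg)
    D*:  DTT_red + ERO_*      → DTT_ox + reduced ERO_*   (kdtt)
    dO2/dt += kdiff · (O2_sat − O2)                      (open measuring cell)

On top of the simulator sit: trace statistics (100-s baseline strip, 10-s
sliding-window least-squares consumption rates, maximum rate), the
calibrations (`kdiff`/`O2_sat` from dithionite-recovery traces; `k1`/`kdtt`
from Ero1p-only DTT titrations), a COPASI-style repeated global fit of the
free constants (differential evolution in log-parameter space, ranked by
average per-experiment RMSD, with per-constant spread across repeats as the
identifiability diagnostic), and the in vivo calculus:

    k_Cys = Σᵢ Aᵢ · ⌊Cysᵢ/2⌋ · (kᵢ + ln 2 / t_d)

the proteome-wide disulfide-formation demand from each protein's abundance
Aᵢ, cysteine count Cysᵢ, degradation rate kᵢ and the culture doubling time
t_d, compared against the supply capacity of the cell's Pdi1p population.

## Worked example

```python
from opfkin import (RateConstants, NoiseSpec, generate_trace,
                    max_consumption_rate, CellParameters,
                    molecules_to_concentration, pdi_capacity)
from opfkin.synth import dtt_assay_conditions

# Ero1p-only assay: 1 uM enzyme, 10 mM DTT injected after a 100-s baseline
trace = generate_trace(RateConstants(), dtt_assay_conditions(), NoiseSpec(sd=0.0))
print(f"max rate: {max_consumption_rate(trace):.3f} uM O2 / uM Ero1p / s")

cell = CellParameters()
print(f"Pdi1p in the ER: {molecules_to_concentration(cell.pdi_copies, cell.er_volume_um3):.0f} uM")
print(f"Ero1p in the ER: {molecules_to_concentration(cell.ero_copies, cell.er_volume_um3):.0f} uM")
print(f"supply capacity: {pdi_capacity(cell)[1]:,.0f} bonds/min")
```

prints

```
max rate: 0.800 uM O2 / uM Ero1p / s
Pdi1p in the ER: 155 uM
Ero1p in the ER: 29 uM
supply capacity: 400,000 bonds/min
```

i.e. the calibrated oxidase branch consumes 0.8 μM O₂ per μM Ero1p per
second at 10 mM DTT; the cell's 28,000 Pdi1p and 5,200 Ero1p copies
correspond to 155 and 29 μM in a 0.3 μm³ ER; and at ~15 disulfide bonds per
minute per molecule the Pdi1p pool could form ~400,000 bonds per minute —
comfortably above the ~269,000 cystines/min demanded by turnover and growth
dilution of the secretory proteome.

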