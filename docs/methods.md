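# Methods

## Reaction network

The model describes the in vitro reconstituted oxidative-folding relay:
electrons flow from a small-molecule reductant to O₂ through the redox
states of Pdi1p (protein disulfide isomerase) and Ero1p (ER oxidase).
Design choices, with rationale:

* **One Pdi1p active site.**  Pdi1p's two CGHC motifs are functionally
  asymmetric (one oxidase site, one mostly isomerase); the model collapses
  the enzyme to a single site with three states — oxidized disulfide,
  glutathionylated mixed disulfide, reduced dithiol.
* **Two-step GSH reduction with one shared constant `kg`.**  The two
  sequential GSH attacks are chemically near-identical, so they share a
  rate constant.  Because GSH is present at 40 mM in the coupled assay,
  these steps are far from limiting; `kg` is therefore expected to be
  unidentifiable from O₂ traces, and the fitting module treats its
  repeat-to-repeat spread as the diagnostic for that.
* **Sequential activation of Ero1p.**  Purified Ero1p starts with both
  regulatory disulfides intact and is inactive; two sequential reductions
  (constants `ka1`, `ka2`), catalyzed by reduced Pdi1p, produce the active
  enzyme.  This is what creates the lag phase in coupled assays.  A
  configuration switch (`AssayConditions.gsh_activation`) lets GSH reduce
  the regulatory disulfides directly instead; it is off by default.
  Activation is irreversible in-model (no re-oxidation of regulatory
  disulfides).
* **Single-step O₂ chemistry.**  The multi-step FAD chemistry of
  `ERO_act_red + O2 → ERO_act_ox + H2O2` is fast and lumped into one
  second-order reaction (`k1`).  H₂O₂ is an inert accumulating product; an
  H₂O₂–Pdi1p inhibition reaction was considered and excluded because it
  does not change trace shapes in the regimes modeled.
* **DTT branch.**  DTT reduces any Ero1p disulfide with one constant
  `kdtt`; with no Pdi1p and no GSH present this isolates the oxidase cycle
  and is the calibration assay for `k1`/`kdtt`.
* **Open measuring cell.**  The electrode chamber exchanges O₂ with the
  environment: `dO2/dt += kdiff · (O2_sat − O2)`.  `kdiff` and `O2_sat` are
  calibrated from depletion/recovery traces by a single-exponential fit.

Units are μM and seconds throughout (40 mM GSH enters as 40000 μM).

## Default parameters

| constant | default | unit | origin |
|---|---|---|---|
| `k1` | 0.02 | μM⁻¹s⁻¹ | fixed; with `kdtt` reproduces the DTT-assay observable below |
| `kdtt` | 9.7534e-5 | μM⁻¹s⁻¹ | solved so the default DTT assay (1 μM Ero1p, 10 mM DTT) yields a maximal windowed rate of exactly 0.8 μM O₂·μM Ero1p⁻¹·s⁻¹ |
| `kox` | 0.25 | μM⁻¹s⁻¹ | coupled-assay phenomenology: saturating max rate ≈ 1.5 μM/s |
| `ka1`, `ka2` | 1.5e-3 | μM⁻¹s⁻¹ | lag phase: time of maximal rate ≈ 430 s at 5 μM Pdi1p / 1 μM Ero1p |
| `kg` | 0.05 | μM⁻¹s⁻¹ | fast, non-limiting at 40 mM GSH (any sufficiently large value is equivalent) |
| `kdiff` | 0.002 | s⁻¹ | plausible stirred-open-cell exchange; recalibrate per apparatus |
| `O2_sat` | 258 | μM | air-saturated water near 25 °C |

The GSH-branch defaults were chosen once against the qualitative titration
behavior of the reconstituted system (max rate roughly linear in Pdi1p
below ~15 μM at 1 μM Ero1p, flattening above; roughly linear in Ero1p up to
2 μM at 5 μM Pdi1p; ~1.5 μM/s at saturation) and then frozen.  They are a
self-consistent reference parameterization, not fitted values from any
specific laboratory's traces; the fitting module exists to replace them
with values calibrated to real data.

In vivo parameters: 28,000 Pdi1p and 5,200 Ero1p copies per cell, ER volume
0.3 μm³ (midpoint of the 0.2–0.4 μm³ literature range — the only value in
that range that reproduces both 155 and 29 μM to the nearest integer),
doubling time 120 min, and a saturating per-Pdi1p throughput of 15
disulfide bonds·min⁻¹·molecule⁻¹ (consistent with ~1.5 μM/s at 5 μM Pdi1p:
(1.5/5)·60 = 18 min⁻¹).

## Numerical choices

* Integration: LSODA (stiffness-switching) with rtol 1e-8, atol 1e-10 μM.
  Injections are handled by stopping the integrator, incrementing the
  injected species, and restarting — never by event interpolation.  An
  output sample that falls exactly on an injection time reports the
  pre-injection state.
* Model-vs-data evaluation uses the data's own time grid as solver output
  points (`eval_times`), not interpolation of a coarse trajectory.
* Windowed rates: per-sample sliding windows of fixed width (default 10 s)
  with an ordinary least-squares slope, sign-flipped so consumption is
  positive.  Sliding windows were chosen over disjoint ones: they are
  robust to Gaussian electrode noise and do not quantize the time of the
  maximum.  No additional smoothing — any smoother would silently bias
  maximum-rate values.
* Global fitting: differential evolution over log10-parameter space with
  bounds [1e-8, 1e3] per second-order constant, one seeded start per
  repeat (`seed + r`), followed by a bounded least-squares polish at tight
  solver tolerance (the global stage locates the basin; the residual-based
  polish pins the minimum far more reliably than a scalar-objective
  quasi-Newton step, whose finite-difference gradients drown in solver
  noise).  The objective is the unweighted sum of squared μM deviations
  across all experiments, after the 100-s baseline cut.  Repeats are ranked
  ascending by average per-experiment RMSD, ties broken by repeat index.
  A non-converged repeat is flagged but retained.
* Degenerate inputs raise early: negative concentrations, non-monotone
  time grids, traces shorter than baseline+window, flat recovery traces,
  DTT-calibration sets containing Pdi1p or GSH.

## Synthetic data

The generators produce every input the pipeline consumes, from known ground
truth: coupled GSH assays (enzyme injected at 100 s, 900-s duration, 1-s
sampling), Ero1p-only DTT assays (DTT injected at 100 s, 600 s),
dithionite-depletion/recovery traces, titration series over the standard
grids (Pdi1p {1, 2.5, 5, 10, 15, 20} μM at 1 μM Ero1p; Ero1p {0.25, 0.5, 1,
2} μM at 5 μM Pdi1p; DTT {1, 5, 10, 20} mM at 1 μM Ero1p), and proteome
tables.  Electrode noise is iid Gaussian (default sd 1 μM — a placeholder;
real electrode noise magnitude and autocorrelation are apparatus-specific
and not modeled) plus an optional linear drift.  Everything is seeded and
bit-reproducible; series members draw noise from independent child streams
of the series seed.

The proteome generator samples log-normal abundances (median 1976
molecules/cell, σ=1.2), Poisson cysteine counts (λ=4) and log-normal
half-lives (median 240 min, σ=0.7) for 4000 proteins.  With independent
draws the expected demand factorizes,

    E[k_Cys] = n · E[A] · E[⌊Cys/2⌋] · (E[k] + ln2/t_d),

and the defaults were solved in closed form so that E[k_Cys] ≈ 2.69e5
cystines/min at t_d = 120 min, the scale estimated for the yeast secretory
proteome; realized tables scatter by ~3% (n = 4000 heavy-tailed summands).
These defaults emulate that aggregate scale only — they do
not reproduce per-protein correlations (e.g. abundant proteins being
longer-lived), so tests passing on generated tables demonstrate the
arithmetic and the pipeline, not biological distributions.

What synthetic electrode traces do not emulate: autocorrelated electrode
drift, stirring artifacts, injection transients, and temperature or pH
dependence of the rate constants.  Parameter-recovery results on synthetic
data therefore demonstrate identifiability structure under the stated noise
model, not instrument-grade accuracy.

## Capacity metric and predictions

The overexpression predictor scales the total of one enzyme (initial plus
injected) by each fold, re-simulates the reference assay (5 μM Pdi1p, 1 μM
Ero1p, 40 mM GSH), and takes capacity as the maximum windowed O₂-consumption
rate, with one O₂ consumed per disulfide formed (two-electron reduction of
O₂ to H₂O₂).  Capacity-as-cumulative-O₂ over a fixed horizon was considered
as an alternative metric and not adopted; with a 258 μM O₂ stock it mostly
measures the oxygen budget of the chamber rather than enzyme throughput.
Under the maximum-rate metric, 10× Ero1p more than doubles capacity, and the
Pdi1p curve saturates (the marginal gain per fold shrinks at high fold).
Note that the absolute size of the Pdi1p ×10 gain is metric-dependent: a
throughput (max-rate) definition and an oxygen-budget (cumulative) definition
of capacity disagree by several-fold — see the known-limitations note.

## Known limitations

* No externally fitted reference parameter set is bundled; the SBML
  importer plus its identifier mapping table is the designated adaptation
  point for importing one.  The package defaults are a self-calibrated
  reference parameterization.
* Under the maximum-rate capacity metric the Pdi1p-overexpression gain at
  ×10 is ≈5-fold with the default constants, and no parameterization that
  also reproduces the titration phenomenology (max rate roughly
  proportional to Pdi1p below ~15 μM) can make that gain small: any such
  model gains ≈3-fold between 5 and 15 μM already.  Much smaller quoted
  gains therefore imply a different capacity definition, not different
  constants.
* No RNase A (protein substrate) species, no pH dependence, no peroxide
  feedback, no isomerase load on Pdi1p, single Pdi1p active site.
* `calibrate_ero1_dtt` estimates `k1` and `kdtt` jointly; on short traces
  the two trade off along a shallow valley, so calibration sets should
  include DTT concentrations spanning the saturation knee and traces long
  enough for substantial O₂ depletion.
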