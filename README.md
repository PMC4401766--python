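# gliokin

Chemical-kinetic modelling of intracellular insulin signalling coupled to
glioblastoma growth.

Glioblastoma progression is accelerated in patients with hyperinsulinemia,
and the insulin-like growth factor axis is a long-standing (and so far
clinically disappointing) drug target. `gliokin` implements a minimal
ODE model that links the microscale signalling state of a glioblastoma
cell — free and IGFBP2-bound IGFI, and the oxygen sensor HIF1α — to the
macroscale diameter of a spheroid or tumor, and provides everything
needed to interrogate that model: simulation, parameter estimation,
local and global sensitivity analysis, and in-silico reaction knockouts.
It is aimed at systems-biology researchers studying which arm of the
insulin pathway (the direct IGFI→HIF1α input or the hypothesized
IGFBP2→HIF1α feedback) drives tumor growth.

## Model

With B = [IGFBP2] (nM), I = [IGFI]_free (nM), C = [IGFI–IGFBP2] (nM),
H = [HIF1α] (μM), GD = tumor diameter (μm) and O₂ the oxygen level in
percent (2–21):

```
I_total = I + C                                      (ligand conservation)
dB/dt   = k₁BI(1 − k₂B) − k₃IB + k₄C − k_d B + k₅H
dC/dt   = k₃IB − k₄C − k_d C
dH/dt   = k₆I − k₇·O₂·H + k₈H/(k₁₂ + k₉H) + k₁₀B
dGD/dt  = v₁ + k₁₁H
Volume  = (4/3)·π·(GD/2)³
```

IGFBP2 production is logistic in B and ligand-driven; HIF1α is produced
basally through an oxygen-independent Hill term, driven by IGFI and
IGFBP2, and degraded in proportion to oxygen; the tumor grows at a basal
glucose-dependent rate plus a HIF1α-proportional rate. Two cell-line
parameterizations ship with the package: **U87** (weakly
insulin-dependent growth, spheroid scale) and **LN229** (strongly
insulin-dependent growth, xenograft scale); they differ only in initial
diameter and the growth constants v₁, k₁₁.

On top of the model the package provides:

* `simulate` / `steady_state` / `hypoxia_response` — stiff-capable
  integration (LSODA, rtol 1e-8) and steady-state summaries across
  oxygen levels;
* `fitting.fit` — seeded genetic-algorithm search in log₁₀-parameter
  space with Nelder–Mead refinement against any mix of growth, IGFBP2
  and HIF1α-vs-O₂ series;
* `sensitivity` — the normalized local index
  SI = |GD_n − GD_o|/(C·T·Δk), Latin-Hypercube designs,
  partial correlation (values- or rank-based, two independent
  computation routes) and PCA;
* `knockout` — zeroing single rate constants (excluding the
  untargetable basal HIF1α machinery) and ranking growth reductions;
* `synthetic` — seeded generators replicating the structure of the
  calibration experiments, for end-to-end pipeline tests.

## Worked example

```python
from gliokin import LN229, simulate
from gliokin.knockout import growth_reduction_table

traj = simulate(LN229)                     # 40 days, hourly grid, 21% O2
print(traj.to_frame().iloc[[0, 24, 960]])
```

```
 time_hr  igfi_free_nM  igfbp2_nM  complex_nM  hif1a_uM       gd_um   volume_um3
     0.0     92.500000   3.680000    2.600000  1.000000 3200.000000 1.715728e+10
    24.0     94.221465 183.205712    0.878535  0.018643 3341.285753 1.953167e+10
   960.0     94.216509 184.155977    0.883491  0.018733 7030.349599 1.819405e+11
```

Within a day IGFBP2 climbs from 3.68 nM to its logistic plateau
(~184 nM), HIF1α is degraded from 1 μM to its normoxic quasi-steady
value (~0.019 μM), and the tumor roughly doubles its diameter over the
40 days (3200 → 7030 μm). Ranking the in-silico knockouts:

```python
print(growth_reduction_table(LN229).head(4))
```

```
parameter  final_gd_um  pct_reduction_diameter  volume_ratio_vs_control
  control    7030.3496                  0.0000                   1.0000
      k11    3754.7840                 46.5918                   0.1523
      k10    4485.0217                 36.2049                   0.2596
       k1    4491.2700                 36.1160                   0.2607
```

Removing the IGFBP2→HIF1α feedback (k₁₀) cuts 40-day diameter growth to
about 40% of what removing the direct IGFI→HIF1α input (k₆) leaves —
i.e. the feedback arm, not the classical drug target, dominates
insulin-driven growth in the LN229 parameterization.

The same analyses are available from the shell:

```bash
gliokin simulate --profile LN229 --days 40 --out runs/sim
gliokin knockout --profile LN229 --out runs/ko
gliokin sensitivity-lhs --profile LN229 --n-samples 500 --seed 1 --out runs/lhs
```

Every run writes its tables plus a `manifest.json` (config snapshot,
seed, output digests) sufficient to replay it.

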