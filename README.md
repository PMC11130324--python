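# her2qsp

A mechanistic quantitative-systems-pharmacology (QSP) model of HER2-positive
breast cancer for preclinical efficacy evaluation and combination assessment.
The package is aimed at modelers and pharmacologists who want to simulate —
and calibrate against their own data — how ErbB-pathway signaling, five
second-line therapeutics and mouse pharmacokinetics jointly determine tumor
growth in HER2+ xenografts.

## The model

A single ODE system (≤ 60 species, ≤ 80 reactions including PK) couples three
layers:

1. **ErbB signaling** in a representative tumor cell: EGFR/HER2/HER3/HER4
   with cell-line copy numbers (SKBR3: 1.5 × 10⁶ HER2 per cell), EGF and NRG1
   ligand binding, five HER2-containing dimers (including the
   ligand-independent HER2–HER2 and HER2–HER3 pairs that keep baseline
   signaling on), transphosphorylation, receptor turnover with FOXO-mediated
   HER3 feedback, and lumped Raf/ERK and PI3K/AKT cascades.
2. **Drug mechanisms**: lapatinib (reversible EGFR/HER2 TKI), pyrotinib
   (irreversible pan-ErbB TKI), T-DM1 and T-DXd (HER2 ADCs with
   internalization, lysosomal processing vs recycling, DAR-scaled payload
   release, DM1 efflux without re-entry vs membrane-permeant DXd) and
   capecitabine (prodrug of 5-FU).
3. **Tumor growth**, with signal-driven proliferation and stimulus-driven
   death:

   dN/dt = N·[ μmax·H(S; km13, n13)·(1 − V/Vmax)
             − dmax·(1 + w14·H(PL) + w15·H(FU)) ]

   where S integrates pERK/pAKT, PL is intracellular ADC payload and FU the
   5-FU exposure; V is capped logistically at 2000 mm³ in vivo.

On top of the simulator sit Bliss-independence synergy surfaces, PRCC/Sobol
global sensitivity, pattern-search calibration with a strict in-vitro→in-vivo
translation policy, bootstrap uncertainty, resistance-phenotype presets and a
synthetic-data generator (see `docs/methods.md` for the full account).

## Worked example

```python
from her2qsp import TumorGrowthModel, bath
from her2qsp.protocols import Regimen, RegimenArm, XenograftProtocol, \
    compute_tgi, control_regimen

# in vitro: pathway shutdown and its NRG1 escape
cell = TumorGrowthModel.skbr3(drugs=["lapatinib"])
base = cell.simulate(1.0)
lap = cell.simulate(1.0, events=[bath("lapatinib", 100.0)])
print(f"pERK under 100 nM lapatinib: {100*lap.final('pERK')/base.final('pERK'):.1f}% of baseline")

# in vivo: low-dose TKI + ADC combination over three 21-day cycles
mouse = TumorGrowthModel.skbr3(
    drugs=["lapatinib", "pyrotinib", "capecitabine", "T-DM1", "T-DXd"],
    in_vivo=True)
prot = XenograftProtocol(start_volume=80.0, follow_up_days=62.0)
combo = Regimen((RegimenArm("pyrotinib", 6.0, "qd"),
                 RegimenArm("T-DM1", 6.0, "q3w", route="iv")))
ctrl = mouse.xenograft(control_regimen(), prot)
trt = mouse.xenograft(combo, prot)
print(f"TGI(day 62) pyrotinib 6 + T-DM1 6: {compute_tgi(trt, ctrl, 62.0):.1f}%")
```

prints

```
pERK under 100 nM lapatinib: 0.3% of baseline
TGI(day 62) pyrotinib 6 + T-DM1 6: 100.0%
```

That is: 100 nM lapatinib alone silences ERK signaling almost completely in
HER2-overexpressing cells, and the markedly dose-reduced pyrotinib + T-DM1
combination holds the xenograft at or below its 80 mm³ starting volume for
three full treatment cycles (baseline-corrected TGI is clipped at 100% once
the treated tumor regresses below baseline), while each agent alone at these
doses lets the tumor escape.

Fitting follows the statsmodels pattern — a model object, a `fit`, a results
object:

```python
res = mouse.fit(dataset, simulators, free={"umax": (0.1, 1.5)})
print(res.summary())
```

A thin CLI mirrors the main simulations:
`her2qsp simulate-cell`, `her2qsp simulate-viability --drug lapatinib`,
`her2qsp simulate-xenograft --regimen regimen.yaml --phenotype tdm1_resistant`.

## Layout

| module | contents |
| --- | --- |
| `her2qsp.params` | parameter containers, cell-line / drug / PK presets |
| `her2qsp.network` | species + reactions, packed numba RHS, naive oracle |
| `her2qsp.simulate` | events, stiff integration, steady state, trajectories |
| `her2qsp.pharmacokinetics` | compartment PK, capecitabine cascade, tumor coupling |
| `her2qsp.protocols` | regimens, viability assays, xenografts, TGI |
| `her2qsp.calibration` | weighted loss, pattern search, translation policy |
| `her2qsp.synergy` | Bliss surfaces and classification |
| `her2qsp.sensitivity` | LHS/PRCC, Sobol total-order, bootstrap uncertainty |
| `her2qsp.phenotypes` | resistance presets and the 13-regimen TGI grid |
| `her2qsp.synthetic` | fixture generator with known ground truth |
| `her2qsp.model` | `TumorGrowthModel` / `TumorGrowthResults` facade |
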