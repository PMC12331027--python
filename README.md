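# potatosim

Potential-yield simulation and yield-gap analysis for potato (*Solanum
tuberosum* L.), built around the LINTUL (Light INTerception and
UtiLization) scheme used by the CIP Solanum model, together with the
parameter-estimation procedures that feed it and a late-blight
(*Phytophthora infestans*) AUDPC/yield-loss analysis.  The package is
aimed at agronomists and crop modellers who want to quantify how far
farm yields sit below the radiation-limited ceiling of a season, and how
much of that gap a disease like late blight explains.

## The model

Growth runs on thermal time `t` (growing degree days, °C·d, daily
increment `max(0, (Tmax+Tmin)/2 − Tb)`, default base temperature
`Tb = 2 °C`, clock starting at crop emergence).

Canopy ground cover follows the beta growth function

```
W(t) = Wmax · [1 + (te − t)/(te − tm)] · (t/te)^(te/(te−tm)),   0 ≤ tm < te
```

with maximum cover `Wmax` reached at `t = te` and maximum growth rate at
`t = tm`.  Intercepted photosynthetically active radiation accumulates
as `IPAR = Σ 0.5 · SR · W`, total dry biomass as `RUE × IPAR` (radiation
use efficiency, g·MJ⁻¹), and the harvest index — the tuber fraction of
total dry mass — follows a Gompertz curve

```
HI(t) = A · exp(−exp(−(t − Tu)/b))
```

with asymptote `A` and maximum partition rate at `t = Tu`.  Fresh tuber
yield converts the final tuber dry mass through a tuber dry-matter
fraction (default 0.20): `yield [t/ha] = tuber_dm / DM × 0.01`.

Disease pressure is summarized by the area under the disease progress
curve, `AUDPC = Σ (yᵢ + yᵢ₊₁)/2 · (tᵢ₊₁ − tᵢ)` (%·days), and the yield
gap of a season is the mean simulated potential yield across genotypes
minus the surveyed farm yield.

The package ships the monthly climates of the three Yunnan growing
seasons (spring, autumn, early spring) and the nine fitted genotype ×
season parameter sets from the field study it models, plus a synthetic
field-trial generator so every estimator can be exercised against known
truth without any external data.

## Worked example

```python
from potatosim import datasets, potential_yield
from potatosim.yieldgap import gap_report

crop = datasets.load_crop_parameters("autumn", "Yunshu 505")
phen = datasets.load_phenology("autumn", "Yunshu 505")
clim = datasets.load_climate("autumn")
print(f"potential yield: {potential_yield(crop, clim, phen):.2f} t/ha")
print(gap_report(datasets.load_yield_records()).to_string(index=False))
```

prints

```
potential yield: 54.83 t/ha
      season  mean_potential  actual    gap  relative_gap_pct
      spring           125.6   19.60 106.00         84.394904
      autumn            45.3   15.27  30.03         66.291391
early_spring           56.4   20.72  35.68         63.262411
```

The first line is the radiation-limited fresh tuber yield of cultivar
Yunshu 505 in the autumn season, simulated from the monthly climate
disaggregated to days (30 d/month) over the observed emergence-to-
maturity window.  The table decomposes each season: spring combines the
highest potential (125.6 t/ha, abundant radiation over a long cycle)
with the widest gap (106 t/ha, 84% of potential unrealized — late
blight season), while autumn's low radiation caps potential at 45.3
t/ha and leaves the smallest gap.

The same pipeline is scriptable from the shell:

```
potatosim simulate --weather w.csv --params p.json --emergence 44 --maturity 164 --out r.json
potatosim yieldgap --out report.csv
potatosim synth --seed 1 --out trial/
```

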