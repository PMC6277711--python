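# mppsim

A deterministic system-dynamics simulator of a patented-drug market before
and after its stakeholders join the Medicines Patent Pool (MPP), built for
health-policy analysts who want to ask: *under what generic price, royalty
rate and government subsidy does everyone prefer to join the pool?*

The MPP licenses patented medicines from originator companies to generic
manufacturers to broaden access.  An originator joins only if its
cumulative profit does not fall; a government joins only if its cumulative
medical expenditure does not rise.  `mppsim` runs both worlds — in-pool and
out-of-pool — on identical parameters and locates the policy thresholds
where those decisions flip.

## The model

Three coupled subsystems are advanced over a 16-year horizon at a 2-month
step (the defaults describe an anti-multiple-myeloma drug in the Chinese
hospital market):

**Patent intensity.**  Patent value decays exponentially,
`dV/dt = -V/(τ + 1/d)` (τ: patent technology life cycle, d:
substitutability), from the initial R&D investment `V0`.  Relative patent
intensity `r = V_in/(V_in + V_out)` and the class's average price set the
drug attraction `A = clip(r^γr · (p_ref/p_avg)^γp, 0, 1)`.

**Patient flow.**  Diagnosed patients `UP` and patients in therapy `CP`
follow `dUP/dt = up - cp`, `dCP/dt = cp - ccp - dp`, fed by an incidence
funnel (population x morbidity x affordability x diagnosis x outpatient x
treatment rates).  Potential sales `pp = m·δ·(α·UP + β·CP)` are split by
attraction into adoptions and rejections; rejected patients may retreat
(rate `zz`); death and treatment suspension hazards are derived from the
median survival ω and the suspension probability `z`.

**Money.**  The generic sells at `price_ratio x p_orig` from its launch —
two years after joining the pool, or two years after the 12-year patent
expiry outside it.  Enterprises earn after-tax operating profit; the
licensed generic pays a royalty on sales to the originator; the government
pays the drug bill plus, in-pool, a one-time subsidy
`subsidy_coef x V0_in`.

With the shipped default calibration the paired-world sweeps place the
government/originator subsidy balance point at a generic price ratio of
**35.8%**, the royalty ceiling (above which the licensed generic earns less
than its out-of-pool baseline) at **34%**, and the subsidy-coefficient
interval acceptable to both parties at price ratio 30% / royalty 5% at
**[0.05, 0.08]**.

## Worked example

```python
from mppsim import ModelParameters, compare_worlds

metrics = compare_worlds(ModelParameters())   # default levers: price ratio
for k, v in metrics.metrics.to_dict().items():  # 0.40, royalty 0.0209,
    print(k, "=", v)                            # subsidy coefficient 0.065
```

prints

```
d_profit_orig = 531882.2164598573
d_profit_gen = 9104664.23242267
d_gov = -134231.92028419673
required_subsidy = 2718117.7835401436
affordable_subsidy = 3115768.0797158033
joins_orig = True
joins_gov = False
```

Read: at a 40% generic price ratio the originator needs $2.72M to be made
whole for joining (its 16-year profit shortfall before any subsidy), and
the government saves $3.12M of drug spending by joining — so a feasible
subsidy exists.  At the default coefficient 0.065 the subsidy is
0.065 x $50M = $3.25M: the originator gains $0.53M and joins, but the
subsidy overshoots the government's savings by $0.13M, so the government
declines — a coefficient in [0.055, 0.062] would satisfy both at this
price ratio.  The generic maker is $9.1M better off in-pool (twelve extra
years on the market).

The same analyses are available from the shell:

```sh
mppsim run --pooled --out out/            # one world, 97-row trajectory CSV
mppsim compare --out out/                 # paired worlds + decision metrics
mppsim sweep --lever price_ratio --grid 0.10:0.60:0.002 --out out/
mppsim reproduce --figure 4 --out out/    # canned published-experiment grids
```

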