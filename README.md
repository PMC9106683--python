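# socbalance

Soil organic carbon (SOC) stock accounting and loss partitioning for
degrading high-alpine pastures.

Alpine *Kobresia* pastures on the Tibetan Plateau hold a disproportionate
share of the world's soil carbon in a thick root-mat topsoil. Under
overgrazing and freeze–thaw stress the root mat cracks, dies back and
erodes, and the degradation sequence is conventionally described by six
ordered stages: S0 (intact root mat) through S1–S4 (widening polygonal
cracks) to S5 (bare soil). `socbalance` is a toolkit for the quantitative
carbon bookkeeping of such sequences, aimed at soil biogeochemists who
have horizon-resolved pedon data (contents, bulk densities, crack depths)
and want defensible stock, loss and attribution numbers.

## What it computes

**Stocks.** The elemental stock of a soil layer is

```
stock [kg ha⁻¹] = 100 · content [g kg⁻¹] · BD [g cm⁻³] · depth [cm]
```

accumulated horizon-wise to a fixed depth limit (default 30 cm, horizons
prorated at the limit) and reported in kg m⁻² per stage as mean ± SE over
field replicates. SOM contents are converted to SOC by division by 2.0.

**Loss partitioning.** For each degraded stage `s` with erosion (crack)
depth `e_s`, the decline of the 0–30 cm SOC stock relative to S0 is split
into

* *erosion*: `∫₀^{e_s} c_ref(z)·BD_ref(z) dz` — the carbon of the removed
  topsoil, evaluated on the reference profiles;
* *mineralization / reduced input*: for each surviving reference horizon,
  `stock_S0,h − c_{s,h}·BD_{s,h}·T̄_{S0,h}·10⁻²`, i.e. the deficit of the
  degraded stage's content×BD spread over the reference horizon's mean
  thickness.

A Welch t-test per stage checks *closure* — that erosion + mineralization
statistically accounts for the observed total loss. On noise-free data
the three components satisfy an exact algebraic identity in the
reference-frame window (total = erosion + mineralization to machine
precision), which the test suite verifies across randomized scenarios.

**Meta-analysis.** Literature records of degradation gradients are
filtered by explicit inclusion criteria (classification present, SOC/N/BD
data, within-study non-degraded reference, depths given, exact 10-cm
intervals), regrouped onto S0–S5 through an editable label→stage table,
and converted to effect sizes `ES [%] = 100·(D − R)/R` against each
study's own reference, aggregated as means ± SE.

**δ¹³C–lignin mixing.** Treating SOC as a two-pool mixture of lignin C
(δ¹³C depleted by 4.3‰ relative to bulk plant tissue; recovered at 38%
by the CuO VSC method) and a fixed non-lignin residue, a rise of the
lignin fraction shifts bulk δ¹³C by `Δf·(−4.3‰)`; the package computes
the lignin-attributable share of an observed isotopic shift.

**Synthetic data.** A generator produces degradation sequences (and
literature corpora) from an analytic scenario with known ground truth,
so every estimator can be validated end to end without field data.

## Worked example

Simulate a degradation sequence (4 replicates, 10% replicate noise),
compute stage stocks and partition the losses:

```
$ socbalance simulate --seed 5 --noise-cv 0.1 -o profiles.csv --truth truth.csv
$ socbalance stocks profiles.csv -o stocks.csv
$ socbalance partition profiles.csv -o partition.csv
```

`stocks.csv` (0–30 cm SOC stocks, kg C m⁻², mean ± SE, n = 4):

```
stage,element,depth_limit_cm,stock_kg_m2,se_kg_m2,n
S0,C,30,15.3196,0.397854,4
S1,C,30,14.9667,1.08641,4
...
S5,C,30,11.1038,0.532579,4
```

`partition.csv` (losses vs S0 in the reference-frame window, kg C m⁻²):

```
stage  total_loss_ref_frame  erosion_loss  mineralization_loss  closure_p  closure_ns
S1     1.47879               0.851669      0.627120             1.0        True
S3     4.01620               3.022270      0.993928             1.0        True
S5     7.13241               5.076400      2.056010             1.0        True
```

Reading the S5 row: of the ~7.1 kg C m⁻² lost from the upper 30 cm by the
bare-soil stage, ~5.1 kg C m⁻² (about two-thirds) left the plot with the
eroded topsoil and ~2.1 kg C m⁻² was lost in place to reduced root input
and accelerated mineralization; `closure_ns = True` means the two
components account for the total within replicate uncertainty.

The lignin mixing model is a one-liner:

```python
>>> from socbalance import LigninState, lignin_delta_shift
>>> lignin_delta_shift(LigninState(0.009), LigninState(0.047))
-0.43000000000000005
```

i.e. a rise of VSC lignin phenols from 0.9% to 4.7% of SOC depletes bulk
δ¹³C by 0.43‰ under the default depletion/recovery parameters.

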