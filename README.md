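# csfcircuit

A lumped-parameter, electrical-analog simulator of cerebrospinal-fluid (CSF)
dynamics, intracranial pressure (ICP) and hydrocephalus shunting.

CSF is secreted from arterial blood at the choroid plexus, circulates through
the ventricles and subarachnoid space, and is absorbed through the arachnoid
granulations into the sagittal sinus. When absorption is impaired
(communicating hydrocephalus), CSF accumulates and ICP rises; the standard
treatment is a shunt — a catheter with a one-way valve that drains the excess
fluid along a low-resistance bypass. `csfcircuit` is aimed at people studying
shunt design and CSF physiology: it predicts the steady ICP of a given
pathology/shunt combination and the resulting shunt efficiency before any
hardware exists, and maps catheter geometry to hydraulic resistance.

## The model

The cranial system is a resistor–capacitor–diode network in the classical
electrical–hydraulic analogy (pressure ↔ voltage in Pa, flow ↔ current,
compliance ↔ capacitance, one-way valve ↔ ideal diode):

- a pulsatile arterial source
  `P(t) = 17 sin(2πt − π/2) − 12.5 sin(4πt) + 16000` Pa drives the network
  through a series resistance `R1`;
- the blood pathway is `R2` (arterial) → capillary node → `R3` (venous) →
  `R4` to reference;
- CSF formation is a resistance `Rf` with a series diode from the capillary
  node into the intracranial compartment (choroid plexus secretion is
  unidirectional);
- CSF absorption is `Ro` with a series diode from the intracranial
  compartment to the sagittal-sinus reference; a shunt adds `Rshunt` with
  its valve diode in parallel with `Ro`;
- compliances `Cai`, `Cvi`, `Ctiss` couple the arterial, venous and
  intracranial nodes.

The rigid cranium fixes the total intracranial volume, so the four
compartment volume rates (arterial, venous, tissue, CSF) sum to zero at
every instant — this conservation law *is* the intracranial pressure
equation. Hydrocephalus severity is the outflow resistance: `Ro = 1` Ω-analog
(≈ 8 mmHg/ml/min) healthy, `Ro = 5` moderate, `Ro = 10` severe. A shunt is
judged by

```
efficiency = (1 − (ICP_after − ICP_healthy) / ICP_before) × 100 %
```

and catheter geometry enters through Poiseuille's law `R = 8μl/(πr⁴)`.

## Worked example

```python
from csfcircuit import run_scenario, run_shunt_sweep

result, trace = run_scenario("severe")   # Ro = 10, no shunt, 60 s run
print(result.to_dict())
```

```
{'scenario_id': 'severe', 'mean_icp_pa': 3644.645974489143,
 'mean_icp_mmhg': 27.337168467988352, 'percent_increase': 416.17374097082785,
 'efficiency': None, 'rshunt': None}
```

Untreated severe hydrocephalus settles at a mean ICP of ≈3645 Pa
(27.3 mmHg), about a five-fold elevation (+416%) over the healthy baseline
of ≈706 Pa (5.3 mmHg). Sweeping the shunt resistance under the same
pathology:

```python
print(run_shunt_sweep().to_string(index=False))
```

```
 rshunt_ohm      icp_pa  icp_mmhg  efficiency_pct
    1.11111  706.088424  5.296113      100.000016
    1.50000  892.690001  6.695744       94.880134
    2.00000 1100.411534  8.253788       89.180772
    2.50000 1278.975689  9.593133       84.281417
    3.00000 1434.118980 10.756807       80.024672
```

The 1.11111 Ω shunt is the "perfect" design: in parallel with the diseased
`Ro = 10` it restores exactly the healthy outflow resistance of 1 Ω, so the
ICP returns to the healthy value and the efficiency is 100%. Stiffer shunts
leave a residual ICP elevation and proportionally lower efficiency.

The same experiments are available from the shell:

```sh
csfcircuit run --scenario severe --out-trace trace.csv --out-summary summary.json
csfcircuit sweep --out sweep.csv
csfcircuit timevarying --out failing_shunt.csv   # failing-valve experiment
```

Any model parameter can be overridden with a flat YAML file via
`--config` (e.g. `Ro: 5`).

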