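# msureach

Travel-time modelling of **mobile stroke unit (MSU)** deployment in a
metropolitan area. An MSU is an ambulance carrying a CT scanner (optionally
CT angiography, CT perfusion and telemedicine), so intravenous thrombolysis
(tPA) can be given at the patient's location and candidates for endovascular
clot retrieval (ECR) can be triaged directly to a thrombectomy hub. The
strategic questions for a health service are *where* an MSU beats the
conventional ambulance pathway, *how far* from base it remains useful, and
*how much* each minute of added on-board workup (CTA, CTP, telemedicine)
costs in coverage. `msureach` answers these with a deterministic
travel-time model over an origin–destination matrix — either a real one
exported from a distance-matrix service, or a seeded synthetic city so the
whole pipeline runs with no map API at all.

Audience: stroke-service planners, health-services researchers, and anyone
doing spatial accessibility / time-to-treatment analysis.

## The model

For each zone *z* (postcode-like unit with a centroid), with travel times in
minutes from an origin–destination matrix *T*, alarm-to-treatment totals are

```
MSU,  tPA:   T(base, z) + t_scene + t_CTA + t_CTP + t_tele
MSU,  ECR:   MSU_tPA(z) + min_{h in H_MSU} T(z, h) + t_hub
usual, tPA:  t_dispatch + t_onscene + min_{s in S_tPA} T(z, s) + t_needle
usual, ECR:  t_dispatch + t_onscene + min_{s in S_ECR} T(z, s) + t_groin
```

with defaults (minutes): `t_scene = 30`, `t_CTA = 10`, `t_CTP = t_tele = 0`,
`t_hub = 30`; `t_dispatch = 15`, `t_onscene = 20`, `t_needle = 60`,
`t_groin = 90`. The fixed (travel-independent) conventional components are
therefore **95 min** for tPA and **125 min** for ECR, and the default MSU
on-scene total is **40 min**. A zone is *MSU-superior* for a treatment when
the MSU total is no larger than the conventional total (the tie rule is
configurable). Headline statistics are **coverage** (percentage of zones
MSU-superior, rounded half-up to one decimal) and the **operating range**
(maximum base→zone travel time over tPA-superior zones). The sweep engine
evaluates a grid of parameter settings under both a single-hub and a
two-hub MSU return policy, with the conventional pathway pinned to the full
hub protocol.

## Worked example

```sh
msureach evaluate --config examples/synthetic_default.yaml
```

prints (seed 7, the shipped 200-zone synthetic city):

```
superior tPA 100.0% | ECR single-hub 87.0% | ECR two-hub 95.0% | max range 61.6 min
```

meaning: under default parameters the MSU beats the conventional pathway for
thrombolysis in every zone, out to 61.6 minutes of driving from base; for
thrombectomy it is superior in 87.0% of zones if it must return to its base
hub, rising to 95.0% when it may deliver to either hub. The command also
writes `zone_results.csv`, an RFC 7946 `zone_results.geojson` (per-zone
Point features coloured green/yellow/blue for map display) and
`summary.json` into the config's output directory.

```sh
msureach sweep --config examples/synthetic_default.yaml
```

runs the canonical sensitivity grid (`examples/table1_grid.yaml`); the first
rows of `sweep.csv`:

```
usual_fixed_tpa_min  usual_fixed_ecr_min  ctp_min  tele_min  pct_superior_tpa  pct_superior_ecr_single  pct_superior_ecr_multi
95.0                 125.0                0.0      0.0       100.0             87.0                     95.0
95.0                 125.0                10.0     0.0       98.5              77.0                     87.0
95.0                 125.0                0.0      10.0      98.5              77.0                     87.0
```

Note the second and third rows are identical: adding 10 min of CT perfusion
and adding 10 min of telemedicine shift the MSU side by the same amount, so
they produce the same superiority pattern — an exact *shift equivalence*
the test suite verifies in general. Other subcommands: `msureach synth`
(emit a synthetic city as CSVs) and `msureach check-matrix` (verify a matrix
covers every pair an evaluation needs).

The same pipeline runs on real data: provide zone and hospital CSVs and a
long- or wide-form travel-time matrix in the run config instead of the
`synthetic` block. Travel-time backends plug in behind the `MatrixProvider`
contract; the synthetic speed kernel is the only built-in implementation.

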