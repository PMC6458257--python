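# Methods

## Model

`msureach` compares two prehospital pathways for acute ischaemic stroke on
a per-zone basis, using total alarm-to-treatment time as the sole metric.
Both pathways are linear sums of fixed durations and travel-time lookups;
there is no queueing, no fleet, and no stochastic service component — given
a travel matrix and a parameter set, every number is deterministic.

**MSU pathway.** The unit departs its base at alarm (no dispatch constant:
the vehicle is assumed staged at base), drives to the zone centroid, and
performs its full on-scene workup: patient processing incl. blood tests
(`scene_min`, default 30), CT angiography (`cta_min`, 10), and optional CT
perfusion (`ctp_min`) and telemedicine consultation (`tele_min`), both 0 by
default (10–15 min are realistic enabled values; telemedicine includes image
transfer back to base). Thrombolysis happens at the scene, so the tPA total
has no hospital leg. For thrombectomy the MSU carries the patient to the
closest of its candidate hubs (travel-time nearest, ties broken by site id);
no repeat imaging is needed there, only hub processing (`hub_proc_min`, 30)
for image review and angiography-suite set-up.

**Conventional pathway.** An ambulance reaches the patient in
`dispatch_min` (15), spends `scene_min` (20) on scene, then drives to the
nearest capable site: any thrombolysis-capable hospital for tPA
(door-to-needle 60, a figure that already absorbs in-hospital advanced
imaging), or the nearest hub of the designated thrombectomy protocol for ECR
(door-to-groin 90). The travel-independent components are thus 95 min (tPA)
and 125 min (ECR).

**Travel inclusion.** The 95/125 figures are interpreted as the *fixed*
components, with the zone→hospital leg added on top. The alternative
reading — 95/125 as travel-inclusive totals — is arithmetically inconsistent
with an MSU that stays tPA-superior out to ~76 min from base (76 + 40 > 95),
but is retained as a sensitivity variant via
`Scenario(usual_travel_included=False)`.

**Hub policies.** The MSU's candidate hub set is the scenario's
`ecr_hub_ids`; the single-hub policy is the length-1 set (return to base).
The conventional pathway's ECR destination set defaults to the same hubs but
is pinned independently (`usual_ecr_site_ids`) when policies are compared:
in the sweep, the single-hub and two-hub rows restrict only the MSU while
the conventional route keeps the full two-hub protocol, which is how a
fixed statewide protocol behaves while an MSU return policy is varied. Had
the conventional set shrunk along with the MSU's, the zone→hub leg would
cancel from both sides and the two policies would be indistinguishable.

**Superiority and ties.** A zone is MSU-superior when the MSU total is
strictly smaller; equality counts as superior under the default
`tie_msu_superior=True`. Ties have measure zero under continuous travel
times, so the flag only matters for hand-built integer matrices; it is
explicit rather than implicit so that classifications are reproducible.

Two exact structural properties follow from linearity and are tested as
invariants: *shift equivalence* (moving δ minutes from MSU add-ons onto
both conventional door times leaves every flag unchanged — the reason
distinct sensitivity-table rows print identical percentages) and *two-hub
dominance* (enlarging the MSU hub set can only grow the ECR-superior set).
Coverage is weakly monotone in every duration parameter.

## Aggregation

Coverage counts zones, unweighted — the planning question is phrased in
suburbs, not residents — with a population-weighted variant available
(`coverage(..., weights=...)`). Percentages are reported to one decimal,
rounded half-up via exact decimal arithmetic (so 199/200 prints 99.5 and
1/16 prints 6.3); raw counts are kept alongside so nothing is lost to
rounding. The operating range is the maximum base→zone travel time over
tPA-superior zones, with an explicit `None` when no zone qualifies. The
sweep grid is an explicit list of settings rather than a cross-product
builder, so irregular published-table layouts can be reproduced verbatim
from a config file (`examples/table1_grid.yaml`).

## Synthetic city

The generator emulates a monocentric metropolis at desk scale. Zone radial
distances are |Normal(0, R/2)| truncated at the city radius R (40 km) by
rejection, with uniform angles — density decays smoothly from the centre.
The MSU base sits 2 km from the centre co-located with the first ECR hub;
the second hub is 20 km out; six thrombolysis-only hospitals ring the city
at R/2. Travel time between two points is

```
minutes = 60 · (haversine_km · circuity) / v_eff · exp(σ·z)
v_eff   = v_c + (v_e − v_c) · min(d_mid / s, 1)
```

with circuity 1.3, congested-centre speed v_c = 25 km/h, edge speed
v_e = 60 km/h, speed scale s = 20 km, d_mid the trip midpoint's distance
from the centre, and z a seeded standard-normal draw per directed pair
(σ = 0.1 by default; σ = 0 gives the symmetric deterministic kernel). The
congested-centre profile was chosen so catchments are genuinely
non-Euclidean and the one-hub/two-hub comparison is non-trivial; under the
defaults base→zone times span roughly 1–80 min, matching the envelope a
large metropolitan deployment would see. Earth radius is fixed at
6371.0088 km (IUGG mean). Everything is reproducible from the config seed;
in CLI runs the run seed overrides the generator block's seed so one flag
controls all randomness.

What the generator does *not* emulate: road-network topology (rivers,
freeways, one-way systems), time-of-day traffic, and the triangle
inequality (the noisy kernel can violate it, as real road networks do —
nothing in the model relies on it). Passing tests on synthetic cities
therefore validate the *model mechanics and invariants*, not any specific
city's percentages; real-data conclusions require a real travel matrix,
supplied as CSV or through a `MatrixProvider` backend.

## Numerical choices

- All computations are plain sums in minutes; totals are exact up to float
  addition, and each formula sums its terms in the documented order so
  independent recomputations agree bitwise.
- Percentage rounding uses `decimal` with ROUND_HALF_UP, not binary-float
  `round`.
- Nearest-site ties break lexicographically by site id; zone order is
  preserved from input to output.
- Validation is front-loaded: negative or non-finite durations, unknown or
  capability-inconsistent site ids, and absent matrix pairs all raise
  immediately with the offending name or pair — travel times are never
  imputed.
- File writes are atomic (temp-then-rename), so a failed run leaves no
  partial artifact.

## Problem sizes

The shipped default city has 200 zones and 8 sites (~3,200 matrix entries),
which resolves 0.5 percentage points per zone — fine-grained enough that
sweep rows order strictly. Property suites use 20 seeded cities for shift
equivalence and 1,000 random ≤10-zone instances against the brute-force
oracle; the full test suite and the acceptance script each run in a few
seconds on one CPU.

## Known limitations

- Single-vehicle, single-call model: no availability, return-to-service or
  demand competition effects, which penalise long-range MSU operation in
  practice.
- Time is the only metric: clinical eligibility, large-vessel-occlusion
  prediction accuracy, stroke mimics and cost-effectiveness are out of
  scope.
- The MSU base location is an input, not an optimisation variable.
- One discrepancy inherited from the model's provenance: a narrative figure
  set for the combined CT-perfusion + telemedicine setting disagrees with
  the corresponding sensitivity-table row; this package implements the
  table convention (both add-ons as pure additive on-scene minutes).
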