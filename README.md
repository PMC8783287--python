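# phenokit

A desk-scale digital-phenotyping data platform for smartphone-based
mental-health research: a patient-generated-health-data (PGHD) resource
model, spec-validated event ingestion with cross-platform sensor
harmonization, a temporal-resolution query/subscription engine, a
dependency-graph-planned behavioral feature extractor, lossless FHIR R4
export, and a seeded synthetic-data simulator that stands in for real
devices.

It is written for researchers and data engineers who need the
*computational core* of such a platform — the data model, validation,
harmonization, query and featurization semantics — as an importable,
fully testable Python library, without the mobile apps, dashboards, or
deployment machinery of a production system.

## The data model and pipeline

The resource model declares exactly **12 core PGHD-centric kinds**
arranged in a shallow forest: `Researcher → Study → {Participant,
Activity, Sensor}`, with `ActivityEvent`/`SensorEvent` carrying
recorded data under a participant, `ActivitySpec`/`SensorSpec`/`TagSpec`
describing the semantic context of data as JSON Schema documents, and
`Credential`/`Tag` providing access control and extensibility.
Participants own append-only, chronologically ordered event streams.

Active data (surveys, breathing sessions, leveled cognitive tests)
arrive as sessions of *temporal slices* — one validated interaction
atom per answer or test level, each with its value and elapsed
duration. Passive data arrive as sensor samples in device-native
conventions and are harmonized on ingestion. For the accelerometer the
canonical convention is the Apple G-frame: a stationary face-up device
reads −1 G on the downward-facing axis. Android devices report m/s² in
the opposite frame, so each axis is converted by

```
g_axis = −(ms2_axis / 9.80665)
```

which maps a stationary Android reading (0, 0, +9.80665) m/s² to
(0, 0, −1) G, exactly.

On top of harmonized streams, behavioral features are organized in
layers: **primary** features computed from raw events (total seconds in
calls per day, screen-on count per day with de-bouncing, unique nearby
Wi-Fi/Bluetooth devices per day, rolling 24-hour step sum sampled
hourly, haversine GPS distance per day with accuracy gating) and
**secondary** features composed only of primary features (e.g. time
spent meditating per day). Requesting a feature set builds a dependency
graph, topologically orders it deterministically, and deduplicates raw
fetches: each (participant, stream, window) is downloaded exactly once
per execution and served from a cache to every dependent.

Everything exports to FHIR R4 (`Participant→Patient`,
`ActivityEvent→QuestionnaireResponse`, `SensorEvent→Observation`, …)
with raw data, metadata, a schema identifier and a generated narrative
on every resource; a namespaced extension carries the full internal
payload so `from_fhir(to_fhir(x)) == x` field-for-field.

## Worked example

Simulate one participant for three days with four calls/day
(exponential durations, mean 90 s) and fifteen screen-unlocks/day, push
the device-native batches through ingestion, and extract two per-day
features:

```python
from phenokit import SimulationConfig, populate, run_features
from phenokit.cortex import table_to_csv

config = SimulationConfig(
    n_participants=1, days=3, adherence=1.0, seed=7,
    sensors={"lamp.telephony": {"daily_rate": 4.0, "mean_duration_s": 90.0},
             "lamp.screen_state": {"daily_rate": 15.0}})
sim, reports = populate(config)
pid = sim.participant_ids[0]
print("accepted:", reports[pid].accepted, "rejected:", reports[pid].rejected)

tables = run_features(sim.deployment,
                      ["call_duration_per_day", "screen_on_count_per_day"],
                      window=config.window)
print(table_to_csv(tables["call_duration_per_day"]))
print(table_to_csv(tables["screen_on_count_per_day"]))
```

prints

```
accepted: 96 rejected: 0
participant_id,bin_start,value
8d116ece1738f7d93d9c172411e20b8f,2024-01-01T00:00:00+00:00,419.4
8d116ece1738f7d93d9c172411e20b8f,2024-01-02T00:00:00+00:00,148.7
8d116ece1738f7d93d9c172411e20b8f,2024-01-03T00:00:00+00:00,208.39999999999998

participant_id,bin_start,value
8d116ece1738f7d93d9c172411e20b8f,2024-01-01T00:00:00+00:00,8
8d116ece1738f7d93d9c172411e20b8f,2024-01-02T00:00:00+00:00,18
8d116ece1738f7d93d9c172411e20b8f,2024-01-03T00:00:00+00:00,16
```

All 96 simulated events (calls, screen on/off transitions, and three
daily survey sessions) validated against their specs and were accepted.
The first table is seconds spent in calls per calendar day (e.g. 419.4 s
on January 1); the second is the number of times the screen was turned
on per day, after de-bouncing consecutive duplicate states. Day-to-day
scatter around the configured rates (4 × 90 = 360 s and 15 unlocks) is
the expected Poisson/exponential sampling noise.

The same workflow is available from a shell:

```bash
phenokit simulate --config demo.yaml --seed 7 \
    --out events.ndjson --study-config study.json
phenokit features --feature call_duration_per_day \
    --events events.ndjson --study-config study.json --out calls.csv
phenokit export-fhir --events events.ndjson \
    --study-config study.json --out bundle.json
```

## Layout

| Module | Role |
| --- | --- |
| `phenokit.model` / `phenokit.store` | 12-kind resource model, hierarchy, credentials, tags, event streams |
| `phenokit.specs` | JSON-Schema spec registry + built-in activity/sensor catalog |
| `phenokit.ingestion` | validation (all violations reported), harmonization, session packaging, stream merge |
| `phenokit.query` | half-open window queries, binning at any resolution, subscriptions, triggers with audit log, study-config round trip |
| `phenokit.cortex` | feature registry (raw/primary/secondary), dependency planner, cached executor, built-in features |
| `phenokit.fhir` | lossless FHIR R4 bundle export/import + structural conformance checks |
| `phenokit.simulator` | seeded device-native study/stream/session generator |
| `phenokit.cli` | `phenokit` command: simulate / ingest / query / features / export-fhir / validate-config |

See `docs/methods.md` for the modeling decisions, parameter defaults,
and known limitations.
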