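# Methods

This note documents the models, conventions and defaults behind
phenokit, the reasoning where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## Time base and windows

All timestamps are integer milliseconds since the Unix epoch, UTC.
Every window and bin is half-open, `[start, end)`, with 0-based bin
indexing: bin *i* of resolution *r* covers `[start + i·r, start +
(i+1)·r)` intersected with the window, and `bin_count =
ceil((end − start)/r)`. Half-open intervals make adjacent windows
partition time without double counting, and they make binning
conservation exact: the count-aggregated bins of any resolution sum to
the number of matching events.

"Per day" features bin in 24-hour periods from the window start.
Callers who want calendar days pass a window aligned to local midnight
in their reporting time zone (the simulator and CLI do this by
default, UTC). We chose window-anchored bins over internally computed
midnights so that the feature-table invariant — bins exactly tile the
requested window — holds for every window, including deliberately
offset ones.

## Validation

Activity and sensor payloads are validated against JSON Schema
(draft 2020-12) documents carried by their specs. Validation collects
*every* violated schema path rather than stopping at the first
failure; rejected events come back with a machine-readable report,
which is what a device or gateway needs to debug a malformed batch.
Invalid client data is never an exception — batches are conserved:
`accepted + rejected == submitted`.

Duplicate detection is by event id only. Devices retrying an upload
resend the same ids, which makes ingestion idempotent; content-hash
deduplication was rejected because two legitimate samples can be
identical (e.g. two stationary GPS fixes).

## Sensor harmonization

The canonical accelerometer convention is the Apple G-frame
(stationary face-up device: (0, 0, −1) G). Android samples, natively
m/s² in the opposite frame, are converted axis-wise by
`g = −(ms2 / 9.80665)` with standard gravity fixed at 9.80665 m/s².
Harmonization is idempotent (harmonized events pass through
unchanged), norm-preserving up to the unit scale, and refuses samples
from an unknown platform, since their frame cannot be inferred. Other
sensors receive a unit annotation only; whether gyroscope-class
sensors need frame conversion is left to future spec revisions, so
none is applied.

## Queries, subscriptions, triggers

Subscriptions deliver *deltas*: each accepted event matching a
selector is delivered exactly once, synchronously, in ingest order;
prior events are never replayed (a post-hoc query serves that need,
and the equivalence of the two is a tested invariant). Transformations
are a registry of named pure functions (identity, dict conversion,
slice flattening, plus user-registered ones); accepting arbitrary code
in a query was rejected for safety.

Trigger rules evaluate named predicates (`field_gte`,
`any_slice_value_gte`, `inactivity_gap`) against each accepted event
and append exactly one audit record per firing. The audit log is the
generic, testable stand-in for notification/intervention delivery
(push services, messaging integrations are out of scope).

Study configurations export as a self-contained JSON document —
activities with settings and schedules, sensors with settings, and
embedded definitions of every referenced spec — so an empty deployment
can reimport them and re-export an identical document (modulo resource
ids, which are never exported).

## Feature extraction

Features form three layers. Raw nodes are event streams; primary
features may depend only on raw streams; secondary features may depend
only on primary/secondary features. The layer rules are enforced at
registration, which guarantees by construction that secondary code
never sees raw events.

Planning builds the transitive dependency graph and orders it with a
lexicographic topological sort, so plans are deterministic given the
registry. The fetch set is the set of distinct raw dependencies; the
executor fetches each (participant, stream, window) at most once per
execution and caches it in memory for every dependent. Cache lifetime
is one execution with no eviction — correct and simple at desk scale.
A failing fetch is recorded with the participant and stream named;
features transitively depending on it are unavailable for that
participant while all other work completes.

Built-in feature conventions, each pinned by tests:

- **call_duration_per_day** — sum of call durations (seconds) per day;
  a call straddling midnight is attributed to the day it started.
- **steps_rolling_24h** — hourly-sampled rolling sum: the value at bin
  start *t* is the steps recorded in `(t − 24 h, t]`. The phrase
  "cumulative steps per hour over a 24-hour rolling window" is
  ambiguous between this reading and a within-day cumulative counter;
  the rolling sum was chosen because it is translation-invariant and
  well defined across midnight, and the choice is test-pinned.
- **screen_on_count_per_day** — transitions into the "on" state, with
  consecutive duplicate states de-bounced (duplicate "on" reports are
  a device artifact, not two unlocks).
- **unique_nearby_devices_per_day** — cardinality of distinct device
  identifiers per day with Wi-Fi and Bluetooth pooled; an identifier
  seen on both radios is one device.
- **gps_distance_per_day** — haversine distance (Earth radius
  6371.0088 km) summed over consecutive accepted fixes; fixes with
  reported accuracy worse than 100 m (configurable) are dropped before
  pairing, because a single 500 m-error fix otherwise fabricates a
  kilometer of travel. A segment is attributed to the day of its
  earlier fix, consistent with the call convention. Haversine with
  accuracy gating is the simplest defensible mobility estimate; the
  registry accepts substitutes.
- **activity_duration_per_day** (secondary) — seconds per day in
  sessions whose activity spec matches a filter, composed from a
  primary per-session duration extraction rather than raw events.

## FHIR mapping

The R4 mapping is: Participant→Patient, Researcher→Practitioner,
Study→Group, ActivityEvent→QuestionnaireResponse (temporal slices as
items), SensorEvent→Observation (canonical units in the value
quantities), Activity→Questionnaire, Sensor→Device, Tag and
Credential→Basic. Every exported resource carries raw data, metadata,
a schema-identifier coding, and a generated narrative. FHIR has no
native home for several internal fields, so each resource carries one
namespaced extension holding the complete internal JSON payload; the
round trip `from_fhir(to_fhir(x)) == x` reads it back. One extension
per resource, rather than many micro-extensions, keeps the round trip
trivially lossless and the documents readable. Hand-built
Observation/QuestionnaireResponse documents without the extension are
also accepted and reconstructed from their native elements.

"FHIR-compatible" is asserted here as one defensible concrete mapping;
no canonical mapping for this resource model is standardized.
Conformance is checked against compact structural schemas for the
mapped R4 types (required elements, element types, status value sets)
— a deliberate subset of full R4 validation, sufficient to catch
structural regressions in what the package emits; profile-level (US
Core) conformance is out of scope.

## Synthetic-data generator

The simulator emulates per-participant device streams in *native*
conventions — Android accelerometer in m/s² with +g on the z axis,
Apple in G with −1 — precisely so the harmonization path is exercised
end to end; emitting canonical data would leave that code untested.

One master seed spawns per-(participant, stream) sub-seeds through
`numpy.random.SeedSequence` with a spawn key of (participant index,
CRC32 of the stream name). Runs are byte-reproducible, participants'
streams are mutually independent, and adding a sensor to a
configuration does not perturb the samples of existing streams.

Generative models and defaults:

- **Point-process sensors** (screen, calls, nearby devices): per-day
  event counts are Poisson with the configured daily rate, placed
  within the day by a two-level diurnal profile (85 % of events in
  08:00–22:00 by default). Because the configured rate is the mean of
  the daily count, per-day features recover it directly — the closure
  tested at 30 days within three standard errors.
- **Screen sessions**: each "on" is followed by an "off" after an
  exponential hold (mean 60 s), truncated just before the next "on"
  since a screen cannot turn on while already on; the configured rate
  therefore equals the de-bounced screen-on count exactly in
  expectation.
- **Calls**: exponential durations (default mean 120 s), incoming or
  outgoing with equal probability; default 6 calls/day.
- **Steps**: hourly Poisson increments whose diurnal weights sum to
  the configured daily total (default 7000).
- **GPS**: Gaussian random walk around a per-participant home
  coordinate (step scale 1e-4°/min by default), with mostly-good
  accuracy (5–30 m) and a 5 % fraction of poor fixes (>150 m) to
  exercise accuracy gating. One fix per minute.
- **Accelerometer**: stationary baseline plus Gaussian noise
  (0.02 G default) at 5 Hz. It is not in the default *study* sensor
  set — a continuous 5 Hz stream is orders of magnitude larger than
  the event-rate streams and is generated on demand for explicit
  windows instead.
- **Surveys**: a daily schedule at 18:00, thinned by an adherence
  probability (default 0.75, a typical ecological-momentary-assessment
  completion rate); likert answers uniform on 0–3, slice durations a
  few seconds; leveled cognitive tests produce monotonically harder
  levels (falling scores, rising response times).

What the generator does **not** emulate: physiological waveforms,
gait, real mobility patterns (home/work clustering, transport modes),
device clock skew, battery-driven gaps, or platform-specific payload
quirks beyond the accelerometer conventions. Tests passing on
simulated data therefore demonstrate the correctness of the pipeline's
*semantics* (validation, harmonization, ordering, planning,
aggregation, round trips) — not that the feature values are clinically
realistic for any population.

## Numerical and problem-size choices

Resource ids are random 128-bit hex strings from a per-deployment
seedable generator; retired ids are never reused. Stream order ties
are broken by (event kind, id) so iteration is deterministic. Means
over empty bins are null, not zero; counts and sums over empty bins
are zero. The executor-equivalence and round-trip suites run on 100
random synthetic streams / resource sets; statistical closure uses 30
simulated days — sizes at which the checked invariants are exact or
have standard errors far below their tolerances, while the whole suite
runs in seconds.

## Known limitations

- The in-memory store has no durability; `dump_resources` is a debug
  aid, not a database.
- Millisecond-resolution binning materializes its dense bin grid, so
  it is intended for short windows (the sparse aggregation itself is
  cheap; the dense output list is what grows).
- Credential grants are downward-only (a grant on a study covers its
  participants, never the reverse) with a three-action vocabulary
  (read/write/admin; admin implies the others); finer scopes would
  need a richer grant type.
- Subscriptions and triggers are synchronous in-process callbacks;
  networked delivery, retry and back-pressure are deployment concerns
  outside this library.
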