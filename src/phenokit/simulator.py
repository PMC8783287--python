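"""Seeded synthetic study generator: the stand-in for real devices.

Emits studies, participants and *device-native* event batches: Android
accelerometer samples in m/s² with the +9.80665 stationary frame, Apple
samples in G with the −1 frame, schedule-driven survey sessions thinned
by an adherence probability, and point-process sensor streams (screen,
calls, steps, nearby devices) with a two-level day/night diurnal
profile.  Emitting native rather than canonical units is deliberate: it
forces the ingestion/harmonization path to be exercised end to end.

Reproducibility: one master seed spawns per-(participant, stream)
sub-seeds through ``numpy.random.SeedSequence`` with a stable spawn key
(participant index, CRC32 of the stream name), so the same config+seed
is byte-identical and adding a sensor does not perturb other streams.

Rate parameters are per-day means of Poisson counts, so per-day
features recover them directly: a configured 40 screen-ons/day yields a
``screen_on_count_per_day`` mean of 40 (± binomial/Poisson noise).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field
from typing import Any, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .ingestion import IngestReport, STANDARD_GRAVITY, ingest_events
from .model import ScheduleEntry
from .query import MS_PER_DAY, MS_PER_HOUR, evaluate_schedule, import_study_config
from .store import Deployment

#: 2024-01-01T00:00:00Z — a fixed midnight so day bins align out of the box
DEFAULT_START = 1_704_067_200_000

#: two-level diurnal profile: "daytime" spans 08:00-22:00 local
DAY_START_MS = 8 * MS_PER_HOUR
DAY_END_MS = 22 * MS_PER_HOUR


def default_sensor_settings() -> dict[str, dict[str, Any]]:
    """Default sensor set and sampling settings for a simulated study.

    GPS samples once per minute; point-process sensors use per-day mean
    rates typical of smartphone use (≈40 screen unlocks, ≈6 calls,
    ≈7000 steps).  The continuous accelerometer is not in the default
    set — at its 5 Hz default it is generated on demand via
    :func:`simulate_sensor_stream` for explicit windows.
    """
    return {
        "lamp.gps": {"period_ms": 60_000, "step_std_deg": 1e-4,
                     "poor_fix_fraction": 0.05},
        "lamp.screen_state": {"daily_rate": 40.0},
        "lamp.telephony": {"daily_rate": 6.0, "mean_duration_s": 120.0},
        "lamp.steps": {"daily_steps": 7000.0},
        "lamp.nearby_device": {"daily_rate": 25.0, "pool_size": 40},
    }


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(default=4, ge=1)
    days: int = Field(default=7, ge=1)
    start_time: int = DEFAULT_START
    apple_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    adherence: float = Field(default=0.75, ge=0.0, le=1.0)
    survey_time_of_day_ms: int = Field(default=18 * MS_PER_HOUR, ge=0)
    survey_questions: int = Field(default=5, ge=1)
    diurnal_weight: float = Field(default=0.85, ge=0.0, le=1.0)
    sensors: dict[str, dict[str, Any]] = Field(
        default_factory=default_sensor_settings)
    seed: int = 0

    @field_validator("sensors")
    @classmethod
    def _positive_settings(cls, v):
        for name, settings in v.items():
            for key, val in settings.items():
                if key in ("period_ms", "frequency_hz", "daily_rate",
                           "daily_steps", "mean_duration_s", "pool_size") \
                        and not val > 0:
                    raise ValueError(f"{name}.{key} must be > 0")
        return v

    @property
    def window(self) -> tuple[int, int]:
        return (self.start_time, self.start_time + self.days * MS_PER_DAY)


@dataclass
class SimulatedStudy:
    """Output of :func:`simulate_study`: a populated deployment skeleton
    plus the device-native batches waiting to be ingested."""

    config: SimulationConfig
    deployment: Deployment
    study_id: str
    participant_ids: list[str]
    platforms: dict[str, str]
    batches: dict[str, list[dict[str, Any]]]
    config_doc: dict[str, Any] = dc_field(default_factory=dict)

    def ingest_all(self) -> dict[str, IngestReport]:
        """Push every batch through validation/harmonization/merge."""
        return {pid: ingest_events(self.deployment, pid, batch)
                for pid, batch in self.batches.items()}


def _rng_for(seed: int, participant_index: int, stream: str) -> np.random.Generator:
    key = (participant_index, zlib.crc32(stream.encode()) & 0x7FFFFFFF)
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


def _event_id(rng: np.random.Generator) -> str:
    return bytes(rng.integers(0, 256, size=16, dtype=np.uint8)).hex()


def _diurnal_offsets(rng: np.random.Generator, n: int,
                     weight: float) -> np.ndarray:
    """n within-day offsets (ms): fraction ``weight`` in 08:00-22:00."""
    day = rng.random(n) < weight
    out = np.where(
        day,
        DAY_START_MS + rng.random(n) * (DAY_END_MS - DAY_START_MS),
        np.where(rng.random(n) < (DAY_START_MS / (MS_PER_DAY - (DAY_END_MS - DAY_START_MS))),
                 rng.random(n) * DAY_START_MS,
                 DAY_END_MS + rng.random(n) * (MS_PER_DAY - DAY_END_MS)))
    return out.astype(np.int64)


def simulate_sensor_stream(kind: str, params: dict[str, Any], platform: str,
                           window: tuple[int, int],
                           rng: Optional[np.random.Generator] = None,
                           seed: int = 0,
                           diurnal_weight: float = 0.85,
                           participant_id: str = "",
                           ) -> list[dict[str, Any]]:
    """Device-native sensor event documents for one stream and window.

    ``kind`` must name a built-in sensor spec.  Accelerometer output is
    in the platform's native convention (Android m/s² with +g on z,
    Apple G with −1 on z); everything else is platform-neutral.
    """
    rng = rng if rng is not None else np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed)))
    start, end = window
    days = max(1, round((end - start) / MS_PER_DAY))

    def base(ts: int, data: dict[str, Any]) -> dict[str, Any]:
        doc = {"id": _event_id(rng), "sensor": kind, "timestamp": int(ts),
               "data": data, "source_platform": platform}
        if participant_id:
            doc["participant_id"] = participant_id
        return doc

    events: list[dict[str, Any]] = []
    if kind == "lamp.accelerometer":
        hz = float(params.get("frequency_hz", 5.0))
        noise_g = float(params.get("noise_g", 0.02))
        period = int(1000 / hz)
        times = np.arange(start, end, period, dtype=np.int64)
        noise = rng.normal(0.0, noise_g, size=(len(times), 3))
        baseline = np.array([0.0, 0.0, -1.0])
        samples = baseline + noise
        if platform == "android":  # native: m/s², flipped frame
            samples = -samples * STANDARD_GRAVITY
        for t, (x, y, z) in zip(times, samples):
            events.append(base(t, {"x": float(x), "y": float(y),
                                   "z": float(z)}))
    elif kind == "lamp.gps":
        period = int(params.get("period_ms", 60_000))
        step = float(params.get("step_std_deg", 1e-4))
        poor = float(params.get("poor_fix_fraction", 0.05))
        home_lat = 42.33 + rng.normal(0, 0.05)
        home_lon = -71.10 + rng.normal(0, 0.05)
        lat, lon = home_lat, home_lon
        for t in range(start, end, period):
            lat += rng.normal(0, step)
            lon += rng.normal(0, step)
            accuracy = 150.0 + rng.random() * 100 if rng.random() < poor \
                else 5.0 + rng.random() * 25
            events.append(base(t, {
                "latitude": float(np.clip(lat, -90, 90)),
                "longitude": float(np.clip(lon, -180, 180)),
                "accuracy": float(round(accuracy, 1))}))
    elif kind == "lamp.screen_state":
        rate = float(params.get("daily_rate", 40.0))
        for d in range(days):
            n = int(rng.poisson(rate))
            offsets = np.sort(_diurnal_offsets(rng, n, diurnal_weight))
            day_start = start + d * MS_PER_DAY
            ons = [day_start + int(off) for off in offsets]
            for i, t_on in enumerate(ons):
                events.append(base(t_on, {"state": "on"}))
                t_off = t_on + 1 + int(rng.exponential(60_000))
                if i + 1 < len(ons):  # a screen cannot turn on while on
                    t_off = min(t_off, ons[i + 1] - 1)
                if t_off > t_on and t_off < end:
                    events.append(base(t_off, {"state": "off"}))
    elif kind == "lamp.steps":
        daily = float(params.get("daily_steps", 7000.0))
        weights = np.full(24, (1 - diurnal_weight) / 10.0)
        weights[8:22] = diurnal_weight / 14.0
        for d in range(days):
            for h in range(24):
                t = start + d * MS_PER_DAY + h * MS_PER_HOUR
                if not start <= t < end:
                    continue
                steps = int(rng.poisson(daily * weights[h]))
                events.append(base(t, {"steps": steps}))
    elif kind == "lamp.telephony":
        rate = float(params.get("daily_rate", 6.0))
        mean_s = float(params.get("mean_duration_s", 120.0))
        for d in range(days):
            n = int(rng.poisson(rate))
            offsets = np.sort(_diurnal_offsets(rng, n, diurnal_weight))
            for off in offsets:
                call_type = "incoming" if rng.random() < 0.5 else "outgoing"
                events.append(base(start + d * MS_PER_DAY + int(off), {
                    "call_type": call_type,
                    "call_duration": float(round(rng.exponential(mean_s), 1))}))
    elif kind == "lamp.nearby_device":
        rate = float(params.get("daily_rate", 25.0))
        pool = int(params.get("pool_size", 40))
        addresses = [f"device-{rng.integers(0, 2**31):08x}" for _ in range(pool)]
        for d in range(days):
            n = int(rng.poisson(rate))
            offsets = np.sort(_diurnal_offsets(rng, n, diurnal_weight))
            for off in offsets:
                events.append(base(start + d * MS_PER_DAY + int(off), {
                    "type": "wifi" if rng.random() < 0.6 else "bluetooth",
                    "address": addresses[int(rng.integers(0, pool))]}))
    else:
        raise KeyError(f"unknown sensor kind {kind!r}")
    return events


def simulate_activity_session(spec_name: str, settings: dict[str, Any],
                              activity_id: str, timestamp: int,
                              rng: np.random.Generator,
                              participant_id: str = "",
                              ) -> dict[str, Any]:
    """One synthetic interaction session as a raw activity event document."""
    slices: list[dict[str, Any]] = []
    static: dict[str, Any] = {}
    if spec_name == "lamp.survey":
        for q in settings.get("questions", []):
            qtype = q.get("type", "likert")
            if qtype == "likert":
                value: Any = int(rng.integers(0, 4))
            elif qtype == "boolean":
                value = bool(rng.random() < 0.5)
            elif qtype == "list":
                options = q.get("options") or ["none"]
                value = str(options[int(rng.integers(0, len(options)))])
            else:
                value = "free text response"
            slices.append({"item": q["text"], "value": value, "type": qtype,
                           "duration": int(2000 + rng.exponential(3000))})
        static["score"] = float(sum(
            s["value"] for s in slices
            if isinstance(s["value"], (int, float))
            and not isinstance(s["value"], bool)))
    elif spec_name == "lamp.breathe":
        target = int(settings.get("duration_seconds", 300))
        slices.append({"item": "breathing session", "value": None,
                       "type": "session",
                       "duration": int(target * 1000 * (0.8 + 0.4 * rng.random()))})
    elif spec_name == "lamp.jewels":
        levels = int(settings.get("levels", 5))
        for lvl in range(1, levels + 1):
            # monotone difficulty: scores fall, response times rise
            score = float(max(0.0, round(100 - 12 * (lvl - 1)
                                         - rng.normal(0, 5), 1)))
            slices.append({"item": f"level {lvl}", "value": score,
                           "type": "score", "level": lvl,
                           "duration": int(3000 + 1500 * lvl
                                           + rng.exponential(1000))})
        static["total_score"] = float(round(sum(s["value"] for s in slices), 1))
    else:
        raise KeyError(f"no simulatable output for activity spec {spec_name!r}")
    doc = {
        "id": _event_id(rng),
        "activity_id": activity_id,
        "spec_name": spec_name,
        "timestamp": int(timestamp),
        "duration": int(sum(s["duration"] for s in slices)),
        "static_data": static,
        "temporal_slices": slices,
    }
    if participant_id:
        doc["participant_id"] = participant_id
    return doc


def build_config_doc(config: SimulationConfig) -> dict[str, Any]:
    """Study-configuration document for the simulated study (importable)."""
    questions = [{"text": f"How is your mood today? (item {i + 1})",
                  "type": "likert"}
                 for i in range(config.survey_questions)]
    return {
        "format": "phenokit.study-config.v1",
        "researcher_name": "Simulated Lab",
        "study_name": "simulated-study",
        "activities": [{
            "spec_name": "lamp.survey",
            "settings": {"questions": questions},
            "schedule": [{
                "start_time": config.start_time + config.survey_time_of_day_ms,
                "repeat": "daily", "custom_times": []}],
        }],
        "sensors": [{"spec_name": name, "settings": settings}
                    for name, settings in sorted(config.sensors.items())],
        "specs": {},
    }


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Build a deployment skeleton and device-native batches per participant.

    Fully deterministic given ``config.seed``: resource ids, platform
    assignment, schedules and every sample repeat byte-for-byte.
    Scheduled activity sessions occur independently with probability
    ``config.adherence``.
    """
    deployment = Deployment(seed=config.seed)
    study_id = import_study_config(deployment, build_config_doc(config))
    activities = deployment.resolve_children(study_id, "Activity")
    window = config.window

    participant_ids: list[str] = []
    platforms: dict[str, str] = {}
    batches: dict[str, list[dict[str, Any]]] = {}
    for p_idx in range(config.n_participants):
        participant = deployment.create_resource("Participant", study_id, {})
        pid = participant.id
        participant_ids.append(pid)
        platform_rng = _rng_for(config.seed, p_idx, "platform")
        platform = "apple" if platform_rng.random() < config.apple_fraction \
            else "android"
        platforms[pid] = platform

        batch: list[dict[str, Any]] = []
        for sensor_name in sorted(config.sensors):
            rng = _rng_for(config.seed, p_idx, sensor_name)
            batch.extend(simulate_sensor_stream(
                sensor_name, config.sensors[sensor_name], platform, window,
                rng=rng, diurnal_weight=config.diurnal_weight,
                participant_id=pid))
        for activity in activities:
            rng = _rng_for(config.seed, p_idx, f"activity:{activity.spec_name}")
            for t in evaluate_schedule(activity.schedule, window):
                if rng.random() < config.adherence:
                    batch.append(simulate_activity_session(
                        activity.spec_name, activity.settings, activity.id,
                        t, rng, participant_id=pid))
        batches[pid] = batch

    return SimulatedStudy(config=config, deployment=deployment,
                          study_id=study_id,
                          participant_ids=participant_ids,
                          platforms=platforms, batches=batches,
                          config_doc=build_config_doc(config))


def populate(config: SimulationConfig) -> tuple[SimulatedStudy,
                                                dict[str, IngestReport]]:
    """Simulate a study and ingest every batch; the common front door."""
    sim = simulate_study(config)
    return sim, sim.ingest_all()
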