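"""Shared fixtures: a seeded deployment with a small configured study."""

from __future__ import annotations

import random

import pytest

from phenokit import Deployment, ingest_events
from phenokit.query import MS_PER_DAY, MS_PER_HOUR

START = 1_704_067_200_000  # 2024-01-01T00:00:00Z, a midnight


@pytest.fixture
def deployment() -> Deployment:
    return Deployment(seed=42)


@pytest.fixture
def study(deployment):
    researcher = deployment.create_resource("Researcher", None,
                                            {"name": "Lab A"})
    return deployment.create_resource("Study", researcher.id,
                                      {"name": "pilot"})


@pytest.fixture
def participant(deployment, study):
    return deployment.create_resource("Participant", study.id, {})


@pytest.fixture
def survey_activity(deployment, study):
    return deployment.create_resource("Activity", study.id, {
        "spec_name": "lamp.survey",
        "settings": {"questions": [
            {"text": "How is your mood?", "type": "likert"},
            {"text": "Did you sleep well?", "type": "boolean"},
        ]},
    })


def make_sensor_doc(rng: random.Random, participant_id: str, sensor: str,
                    timestamp: int) -> dict:
    """One random raw (device-native) sensor event document."""
    data: dict
    platform = "other"
    if sensor == "lamp.accelerometer":
        platform = rng.choice(["apple", "android"])
        vec = [rng.gauss(0, 0.05), rng.gauss(0, 0.05), -1 + rng.gauss(0, 0.05)]
        if platform == "android":
            vec = [-v * 9.80665 for v in vec]
        data = {"x": vec[0], "y": vec[1], "z": vec[2]}
    elif sensor == "lamp.gps":
        data = {"latitude": 42.3 + rng.gauss(0, 0.01),
                "longitude": -71.1 + rng.gauss(0, 0.01),
                "accuracy": rng.uniform(5, 150)}
    elif sensor == "lamp.screen_state":
        data = {"state": rng.choice(["on", "off", "locked", "unlocked"])}
    elif sensor == "lamp.steps":
        data = {"steps": rng.randrange(0, 500)}
    elif sensor == "lamp.telephony":
        data = {"call_type": rng.choice(["incoming", "outgoing"]),
                "call_duration": round(rng.uniform(1, 600), 1)}
    elif sensor == "lamp.nearby_device":
        data = {"type": rng.choice(["wifi", "bluetooth"]),
                "address": f"device-{rng.randrange(20):04d}"}
    else:
        raise ValueError(sensor)
    return {"id": f"{rng.getrandbits(128):032x}", "sensor": sensor,
            "participant_id": participant_id, "timestamp": timestamp,
            "data": data, "source_platform": platform}


def random_stream(deployment, participant_id: str, seed: int,
                  n_events: int = 60, days: int = 3,
                  sensors: tuple[str, ...] = (
                      "lamp.gps", "lamp.screen_state", "lamp.steps",
                      "lamp.telephony", "lamp.nearby_device"),
                  ) -> None:
    """Ingest a random mixed sensor stream for one participant."""
    rng = random.Random(seed)
    docs = [make_sensor_doc(rng, participant_id, rng.choice(sensors),
                            START + rng.randrange(days * MS_PER_DAY))
            for _ in range(n_events)]
    report = ingest_events(deployment, participant_id, docs)
    assert report.rejected == 0, report.errors


@pytest.fixture
def populated(deployment, study, survey_activity):
    """Three participants with random 3-day streams plus survey sessions."""
    from phenokit import package_session

    pids = []
    for k in range(3):
        p = deployment.create_resource("Participant", study.id, {})
        random_stream(deployment, p.id, seed=100 + k)
        ev = package_session(
            deployment, p.id, survey_activity.id,
            START + k * MS_PER_DAY + 18 * MS_PER_HOUR,
            [{"item": "How is your mood?", "value": k, "type": "likert",
              "duration": 1500}],
            {"score": float(k)})
        ingest_events(deployment, p.id, [ev])
        pids.append(p.id)
    return pids
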