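"""Bit-exact model serialization and run manifests.

A saved pooler is a single ``.npz`` archive holding the permanence matrix, the
potential pool, boosts, duty cycles, lesion masks, the inhibition radius, the
step counter, the full configuration and the state of the pooler's RNG.  A
round trip restores the pooler exactly: resumed training produces the same
trajectory as an uninterrupted run.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SPConfig
from .pooler import SpatialPooler

__all__ = ["save_state", "load_state", "SerializationError", "RunManifest"]

FORMAT_VERSION = 1


class SerializationError(RuntimeError):
    """The archive is unreadable, incomplete, or of an unknown version."""


def save_state(sp: SpatialPooler, path) -> None:
    rng_state = json.dumps(sp.rng.bit_generator.state)
    np.savez_compressed(
        path,
        format_version=np.int64(FORMAT_VERSION),
        config=np.bytes_(json.dumps(sp.config.to_dict()).encode()),
        permanences=sp.permanences,
        potential=sp.potential,
        boosts=sp.boosts,
        duty_cycles=sp.duty_cycles,
        alive_mask=sp.alive_mask,
        input_mask=sp.input_mask,
        inhibition_radius=np.float64(sp.inhibition_radius),
        step_count=np.int64(sp.step_count),
        rng_state=np.bytes_(rng_state.encode()),
    )


def load_state(path) -> SpatialPooler:
    required = ("format_version", "config", "permanences", "potential", "boosts",
                "duty_cycles", "alive_mask", "input_mask", "inhibition_radius",
                "step_count", "rng_state")
    try:
        with np.load(path, allow_pickle=False) as z:
            missing = [k for k in required if k not in z.files]
            if missing:
                raise SerializationError(f"archive missing fields: {missing}")
            version = int(z["format_version"])
            if version != FORMAT_VERSION:
                raise SerializationError(
                    f"state format version {version} not supported "
                    f"(expected {FORMAT_VERSION})")
            config = SPConfig.from_dict(json.loads(bytes(z["config"]).decode()))
            sp = SpatialPooler(config)
            sp.permanences = np.array(z["permanences"])
            sp.potential = np.array(z["potential"])
            sp.boosts = np.array(z["boosts"])
            sp.duty_cycles = np.array(z["duty_cycles"])
            sp.alive_mask = np.array(z["alive_mask"])
            sp.input_mask = np.array(z["input_mask"])
            sp.inhibition_radius = float(z["inhibition_radius"])
            sp.step_count = int(z["step_count"])
            sp.rng.bit_generator.state = json.loads(bytes(z["rng_state"]).decode())
    except (OSError, ValueError, KeyError) as exc:
        if isinstance(exc, SerializationError):
            raise
        raise SerializationError(f"cannot read pooler state from {path}: {exc}") from exc
    sp.connected = (sp.permanences >= config.connection_threshold) & sp.potential
    sp._Wf = sp.connected.astype(np.float64)
    sp._rebuild_neighborhoods()
    return sp


@dataclass
class RunManifest:
    """Everything needed to re-run an experiment bit-identically."""

    experiment: str
    seed: int
    config: dict
    dataset: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    code_version: str = "spool 0.1.0"
    timings: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def add_timing(self, stage: str, seconds: float) -> None:
        self.timings[stage] = round(seconds, 3)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


class Stopwatch:
    def __init__(self):
        self.t0 = time.perf_counter()

    def lap(self) -> float:
        now = time.perf_counter()
        dt, self.t0 = now - self.t0, now
        return dt
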