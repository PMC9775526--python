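"""Run configuration, seed management and run manifests.

One YAML file configures the whole pipeline; its sections mirror the
``GanConfig`` and ``RmConfig`` fields one-for-one, so the full-scale
hyperparameters are the checked-in defaults and a desk-scale run only
overrides sizes.  A single root seed deterministically derives one child
seed per pipeline step via ``numpy.random.SeedSequence([root, step_index])``
(reduced mod 2^31), so re-running any step with the manifest reproduces
its outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .gan import GanConfig
from .relmem import RmConfig

#: Named pipeline steps in execution order; each gets its own derived seed.
PIPELINE_STEPS = (
    "fixtures",
    "train_epochs",
    "restore",
    "train_seq",
    "sample_seq",
    "synthesize",
    "evaluate",
)


def derive_seed(root_seed: int, step: str, extra: int = 0) -> int:
    """Deterministic child seed for a named step (< 2^31)."""
    import numpy as np

    idx = PIPELINE_STEPS.index(step)
    return int(np.random.SeedSequence([root_seed, idx, extra]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything a full run needs."""

    data: str = "fixtures"          # "fixtures" or a directory of real epochs
    stages: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
    n_per_stage: int = 8            # few-shot real epochs per stage
    n_generated_per_stage: int = 16
    restore_strategy: str = "random"  # or "smote"
    smote_k: int = 5
    n_sequences: int = 4
    sequence_length: int = 180
    n_train_hypnograms: int = 50
    eval_trials: int = 4
    eval_n_per_side: int = 200
    gan: GanConfig = field(default_factory=GanConfig)
    rm: RmConfig = field(default_factory=RmConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        gan = raw.pop("gan", {})
        rm = raw.pop("rm", {})
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        for req in ("data",):
            if req in raw and raw[req] is None:
                raise ValueError(f"config field {req!r} must not be null")
        cfg = cls(**raw)
        if gan:
            cfg.gan = GanConfig(**{**dataclasses.asdict(GanConfig()), **gan})
        if rm:
            cfg.rm = RmConfig(**{**dataclasses.asdict(RmConfig()), **rm})
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


@dataclass
class RunManifest:
    """Record of one CLI/pipeline invocation; written next to its outputs."""

    command: str
    seed: int
    config: dict
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    status: str = "running"
    failed_step: str | None = None
    version: str = __version__
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def finish(self, status: str = "complete", failed_step: str | None = None):
        self.status = status
        self.failed_step = failed_step
        self.finished = time.time()
        return self

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path
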