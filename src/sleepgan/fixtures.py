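"""Stage-conditional synthetic EEG epochs and synthetic hypnograms.

Real overnight polysomnography is large and access-controlled, so the
package ships a parametric surrogate that reproduces the features the
generators and diagnostics actually depend on: 30 s epochs (3000 samples
at 100 Hz) whose dominant spectral band is stage-characteristic, per-epoch
amplitude spread, and hypnograms with first-order stage-transition
structure over the five AASM symbols.

Band conventions (standard AASM usage):

=====  ==========================================================
stage  dominant content
=====  ==========================================================
W      alpha, 8-12 Hz
N1     theta, 4-7 Hz
N2     theta background plus one 12-14 Hz spindle burst (0.5-1.5 s)
N3     delta, 0.5-2 Hz, at >= 2x the amplitude of other stages
REM    low-amplitude theta, 4-7 Hz
=====  ==========================================================

Every epoch gets additive white Gaussian noise at 20% of the signal RMS.
All randomness flows through seeded generators derived from the fixture
seed; ``draw_index`` offsets the stream so individual epochs are
reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signal import STAGE_INDEX, STAGES, Epoch

#: Fixed per-stage peak-amplitude multipliers applied on top of the drawn
#: base amplitude: deep sleep is high-voltage, REM is low-voltage.
_STAGE_AMP = {"W": 1.0, "N1": 1.0, "N2": 1.0, "N3": 2.2, "REM": 0.5}

_STAGE_BAND = {
    "W": (8.0, 12.0),
    "N1": (4.0, 7.0),
    "N2": (4.0, 7.0),
    "N3": (0.5, 2.0),
    "REM": (4.0, 7.0),
}

#: First-order transition matrix for synthetic hypnograms (rows/cols in
#: ``STAGES`` order).  Strong self-transition on the diagonal plus a
#: W -> N1 -> N2 -> N3 -> N2 -> REM -> N1 cyclic bias, emulating the
#: roughly periodic structure of human sleep cycles.
TRANSITION_MATRIX = np.array(
    [
        # W     N1    N2    N3    REM
        [0.80, 0.15, 0.02, 0.01, 0.02],  # W
        [0.05, 0.75, 0.15, 0.01, 0.04],  # N1
        [0.01, 0.03, 0.80, 0.10, 0.06],  # N2
        [0.01, 0.01, 0.20, 0.75, 0.03],  # N3
        [0.04, 0.08, 0.08, 0.00, 0.80],  # REM
    ]
)


def stationary_distribution(P: np.ndarray = TRANSITION_MATRIX) -> np.ndarray:
    """Left eigenvector of the transition matrix with eigenvalue 1."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    return pi / pi.sum()


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture set.

    ``amplitude_range`` is the uniform draw of the per-epoch base peak
    amplitude in microvolts, before the stage multiplier.
    """

    sampling_rate: float = 100.0
    epoch_len: int = 3000
    n_per_stage: int = 20
    seed: int = 0
    amplitude_range: tuple[float, float] = (20.0, 60.0)

    def __post_init__(self):
        if self.epoch_len != int(round(30 * self.sampling_rate)):
            raise ValueError("epoch_len must equal 30 s x sampling_rate")
        lo, hi = self.amplitude_range
        if not 0 < lo <= hi:
            raise ValueError("amplitude_range must be a positive (low, high) pair")


def _epoch_rng(spec: FixtureSpec, stage: str, draw_index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, STAGE_INDEX[stage], draw_index])


def generate_stage_epoch(stage: str, spec: FixtureSpec = FixtureSpec(), draw_index: int = 0) -> Epoch:
    """One synthetic epoch whose dominant band depends on the stage.

    The oscillatory core is a sum of three sinusoids with random
    frequencies inside the stage band and random phases; N2 additionally
    carries one Hann-windowed 12-14 Hz spindle burst of 0.5-1.5 s at a
    random onset.  Peak amplitude is drawn uniformly from
    ``spec.amplitude_range`` (times the fixed stage multiplier), then
    white noise at 20% of the signal RMS is added.
    """
    if stage not in STAGE_INDEX:
        raise ValueError(f"unknown sleep stage {stage!r}; expected one of {STAGES}")
    rng = _epoch_rng(spec, stage, draw_index)
    t = np.arange(spec.epoch_len) / spec.sampling_rate
    lo, hi = _STAGE_BAND[stage]
    sig = np.zeros_like(t)
    for _ in range(3):
        f = rng.uniform(lo, hi)
        sig += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if stage == "N2":
        dur = rng.uniform(0.5, 1.5)
        onset = rng.uniform(0.0, 30.0 - dur)
        fs_spindle = rng.uniform(12.0, 14.0)
        mask = (t >= onset) & (t < onset + dur)
        env = np.zeros_like(t)
        env[mask] = np.hanning(int(mask.sum()))
        sig = sig + 1.5 * env * np.sin(2 * np.pi * fs_spindle * t + rng.uniform(0, 2 * np.pi))
    peak = rng.uniform(*spec.amplitude_range) * _STAGE_AMP[stage]
    sig *= peak / np.abs(sig).max()
    noise = rng.standard_normal(spec.epoch_len)
    sig = sig + noise * (0.2 * np.sqrt(np.mean(sig**2)))
    return Epoch(samples=sig, stage=stage, sampling_rate=spec.sampling_rate)


def generate_fixture_set(spec: FixtureSpec) -> dict[str, list[Epoch]]:
    """``n_per_stage`` epochs for each of the five stages, keyed by stage."""
    return {
        s: [generate_stage_epoch(s, spec, i) for i in range(spec.n_per_stage)] for s in STAGES
    }


def generate_hypnogram(spec: FixtureSpec, length: int = 180) -> list[str]:
    """Sample a stage sequence of the given length from the fixed
    first-order chain, starting from W.  Deterministic under the spec seed
    (one substream per fixture set; successive calls on a fresh spec with
    the same seed give the same sequence)."""
    if length < 2:
        raise ValueError(f"hypnogram length must be >= 2, got {length}")
    rng = np.random.default_rng([spec.seed, 10_001])
    return sample_markov(TRANSITION_MATRIX, length, rng)


def generate_hypnogram_corpus(spec: FixtureSpec, n_records: int, length: int = 180) -> list[list[str]]:
    """A corpus of independent hypnograms from the same chain."""
    if length < 2:
        raise ValueError(f"hypnogram length must be >= 2, got {length}")
    return [
        sample_markov(TRANSITION_MATRIX, length, np.random.default_rng([spec.seed, 10_001, r]))
        for r in range(n_records)
    ]


def sample_markov(P: np.ndarray, length: int, rng: np.random.Generator, start: int = 0) -> list[str]:
    states = np.empty(length, dtype=int)
    states[0] = start
    # inverse-CDF sampling keeps the draw count independent of the path
    cdf = np.cumsum(P, axis=1)
    u = rng.random(length - 1)
    for i in range(1, length):
        states[i] = int(np.searchsorted(cdf[states[i - 1]], u[i - 1], side="right"))
    return [STAGES[s] for s in states]


def empirical_transition_matrix(seq: list[str]) -> np.ndarray:
    """Row-normalized bigram counts over the five stages."""
    counts = np.zeros((5, 5))
    idx = [STAGE_INDEX[s] for s in seq]
    for a, b in zip(idx[:-1], idx[1:]):
        counts[a, b] += 1
    rows = counts.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return counts / rows


# ----------------------------------------------------------------- on-disk IO
def write_fixture_set(out_dir, spec: FixtureSpec) -> None:
    """Write one ``<stage>.csv`` per stage (epochs as rows) plus a JSON
    sidecar with the spec, and ``hypnogram.txt`` (one symbol per line)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage, epochs in generate_fixture_set(spec).items():
        np.savetxt(out / f"{stage}.csv", np.stack([e.samples for e in epochs]), delimiter=",")
    (out / "fixture_spec.json").write_text(
        json.dumps(
            {
                "sampling_rate": spec.sampling_rate,
                "epoch_len": spec.epoch_len,
                "n_per_stage": spec.n_per_stage,
                "seed": spec.seed,
                "amplitude_range": list(spec.amplitude_range),
            },
            indent=2,
        )
    )
    (out / "hypnogram.txt").write_text("\n".join(generate_hypnogram(spec, 180)) + "\n")


def load_fixture_set(in_dir) -> dict[str, list[Epoch]]:
    src = Path(in_dir)
    spec = json.loads((src / "fixture_spec.json").read_text())
    out: dict[str, list[Epoch]] = {}
    for stage in STAGES:
        arr = np.atleast_2d(np.loadtxt(src / f"{stage}.csv", delimiter=","))
        out[stage] = [Epoch(row, stage, spec["sampling_rate"]) for row in arr]
    return out


def read_hypnogram_file(path) -> list[list[str]]:
    """Plain-text hypnogram dialect: one symbol per line, blank line
    between records.  Returns a list of records."""
    records: list[list[str]] = [[]]
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            if records[-1]:
                records.append([])
            continue
        records[-1].append(line)
    if not records[-1]:
        records.pop()
    return records


def write_hypnogram_file(path, records: list[list[str]]) -> None:
    Path(path).write_text("\n\n".join("\n".join(r) for r in records) + "\n")
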