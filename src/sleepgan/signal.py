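"""Core data types and the normalization/denormalization contract.

An :class:`Epoch` is one 30 s single-channel EEG trace (3000 samples at
100 Hz at full resolution) carrying an AASM stage label.  Generators work
on mean-normalized epochs whose amplitudes lie in [-1, 1]; the original
scale is recorded as a (mean, max, min) triple so any normalized epoch can
be mapped back to microvolts exactly.

Also here: the hypnogram preprocessing rules for R&K-scored recordings —
S3/S4 merge into N3, MOVEMENT/UNKNOWN epochs are dropped, and wake epochs
are kept only within 30 minutes of the sleep period boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The five AASM stage symbols, in canonical order.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")

STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

#: Raw R&K labels accepted by :func:`preprocess_hypnogram`.
RK_LABELS = ("W", "S1", "S2", "S3", "S4", "REM", "MOVEMENT", "UNKNOWN")

_RK_TO_AASM = {"W": "W", "S1": "N1", "S2": "N2", "S3": "N3", "S4": "N3", "REM": "REM"}

#: Epochs per 30 minutes at the standard 30 s epoch length.
W_BOUNDARY_EPOCHS = 60


@dataclass
class Epoch:
    """A 30 s single-channel EEG trace in microvolts with a stage label."""

    samples: np.ndarray
    stage: str
    sampling_rate: float = 100.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("epoch samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch contains non-finite samples")
        if self.stage not in STAGE_INDEX:
            raise ValueError(f"unknown sleep stage {self.stage!r}; expected one of {STAGES}")


@dataclass(frozen=True)
class NormalizationFactors:
    """The (mean, max, min) triple recorded when an epoch is normalized.

    These three numbers are the whole currency of amplitude restoration:
    together with the normalized trace they reconstruct the original
    microvolt signal exactly.
    """

    mean: float
    max: float
    min: float

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"invalid factors: need min <= mean <= max, got ({self.mean}, {self.max}, {self.min})"
            )
        if not self.max > self.min:
            raise ValueError("invalid factors: max must exceed min (constant epoch)")

    @property
    def scale(self) -> float:
        """The one-sided excursion used as the normalization denominator."""
        return max(self.max - self.mean, self.mean - self.min)

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.max, self.min])


@dataclass
class NormalizedEpoch:
    """A dimensionless zero-mean epoch with samples in [-1, 1]."""

    samples: np.ndarray
    stage: str
    factors: NormalizationFactors | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.stage not in STAGE_INDEX:
            raise ValueError(f"unknown sleep stage {self.stage!r}; expected one of {STAGES}")


def normalize_epoch(epoch: Epoch) -> NormalizedEpoch:
    """Mean-center and scale an epoch into [-1, 1], recording its factors.

    The output is ``y = (x - mean(x)) / s`` with
    ``s = max(max(x) - mean(x), mean(x) - min(x))`` — the larger one-sided
    excursion.  This is the unique simple rule that gives a zero-mean
    output, a range inside [-1, 1] with at least one endpoint attaining
    |y| = 1, and exact invertibility from the stored (mean, max, min).
    """
    x = epoch.samples
    mx, mn = float(x.max()), float(x.min())
    if mx == mn:
        raise ValueError(f"cannot normalize a constant epoch (stage {epoch.stage}, value {mx})")
    mu = float(x.mean())
    factors = NormalizationFactors(mean=mu, max=mx, min=mn)
    y = (x - mu) / factors.scale
    return NormalizedEpoch(samples=y, stage=epoch.stage, factors=factors)


def denormalize_epoch(norm: NormalizedEpoch, factors: NormalizationFactors) -> Epoch:
    """Map a normalized epoch back to microvolts with the given factors.

    Pure affine map ``x = y * s + mean``; the exact inverse of
    :func:`normalize_epoch` when given the epoch's own factors.  No
    clipping is applied: resampled factor sets may imply excursions
    slightly outside the recorded extrema.
    """
    y = np.asarray(norm.samples, dtype=np.float64)
    return Epoch(samples=y * factors.scale + factors.mean, stage=norm.stage)


@dataclass
class PreprocessResult:
    """Cleaned labels plus the original indices that were removed, so that
    co-indexed signal epochs can be dropped in lockstep."""

    labels: list[str]
    removed_indices: list[int] = field(default_factory=list)


def preprocess_hypnogram(labels) -> PreprocessResult:
    """Apply the R&K → AASM cleaning rules to a raw label sequence.

    S1→N1, S2→N2, S3/S4→N3; MOVEMENT and UNKNOWN epochs are removed; wake
    epochs are kept only within 30 min (60 epochs) before the first
    non-wake epoch and 30 min after the last one.  "Sleep period" is
    operationally the span from the first to the last non-W epoch after
    merging.  Removed positions are reported against the *original*
    indexing so paired signal epochs stay aligned.
    """
    labels = list(labels)
    for pos, lab in enumerate(labels):
        if lab not in RK_LABELS:
            raise ValueError(f"unknown raw label {lab!r} at position {pos}")

    kept: list[tuple[int, str]] = []  # (original index, mapped label)
    removed: list[int] = []
    for pos, lab in enumerate(labels):
        if lab in ("MOVEMENT", "UNKNOWN"):
            removed.append(pos)
        else:
            kept.append((pos, _RK_TO_AASM[lab]))

    non_w = [i for i, (_, lab) in enumerate(kept) if lab != "W"]
    if non_w:
        lo = non_w[0] - W_BOUNDARY_EPOCHS
        hi = non_w[-1] + W_BOUNDARY_EPOCHS
        final: list[tuple[int, str]] = []
        for j, (pos, lab) in enumerate(kept):
            if lab == "W" and not (lo <= j <= hi):
                removed.append(pos)
            else:
                final.append((pos, lab))
        kept = final
    # an all-wake recording has no sleep period to bound; keep everything

    removed.sort()
    return PreprocessResult(labels=[lab for _, lab in kept], removed_indices=removed)


def read_sleepedf(psg_path, hypnogram_path, channel: str = "EEG Fpz-Cz"):
    """Optional adapter for SleepEDF-style EDF+ recordings.

    Returns ``(epochs, raw_labels)`` where epochs are 30 s slices of the
    requested channel in microvolts and raw_labels are R&K strings ready
    for :func:`preprocess_hypnogram`.  Requires :mod:`mne` (extra ``edf``).
    """
    import mne  # local import: heavy and optional

    raw = mne.io.read_raw_edf(psg_path, include=[channel], preload=True, verbose="error")
    sf = raw.info["sfreq"]
    sig = raw.get_data(units="uV")[0]
    ann = mne.read_annotations(hypnogram_path)
    mapping = {
        "Sleep stage W": "W",
        "Sleep stage 1": "S1",
        "Sleep stage 2": "S2",
        "Sleep stage 3": "S3",
        "Sleep stage 4": "S4",
        "Sleep stage R": "REM",
        "Movement time": "MOVEMENT",
        "Sleep stage ?": "UNKNOWN",
    }
    epoch_len = int(round(30 * sf))
    epochs: list[np.ndarray] = []
    raw_labels: list[str] = []
    for onset, duration, desc in zip(ann.onset, ann.duration, ann.description):
        if desc not in mapping:
            continue
        start = int(round(onset * sf))
        for k in range(int(duration // 30)):
            seg = sig[start + k * epoch_len : start + (k + 1) * epoch_len]
            if len(seg) < epoch_len:
                break
            epochs.append(seg)
            raw_labels.append(mapping[desc])
    return epochs, raw_labels
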