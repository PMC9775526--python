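"""Restore microvolt amplitudes to generated normalized epochs.

Two strategies, both driven by the (mean, max, min) factor triples
recorded while normalizing the real training epochs:

1. ``restore_random`` — pick one recorded factor set uniformly at random
   and apply the inverse affine map.
2. ``restore_smote`` — synthesize a *new* factor set by SMOTE-style
   interpolation between a random bank entry and one of its k nearest
   neighbours in (mean, max, min) space, then apply it.  Interpolation
   uses one scalar lambda ~ U(0,1) per new set, so every synthesized set
   lies on the segment between its two parents; the min <= mean <= max
   ordering is preserved by convexity.

Banks are per-stage: a generated N3 epoch can only draw N3 amplitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal import (
    STAGES,
    Epoch,
    NormalizationFactors,
    NormalizedEpoch,
    denormalize_epoch,
    normalize_epoch,
)


@dataclass
class FactorBank:
    """Per-stage collection of recorded normalization factors."""

    stage: str
    entries: list[NormalizationFactors] = field(default_factory=list)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown sleep stage {self.stage!r}")

    def __len__(self):
        return len(self.entries)

    @classmethod
    def from_epochs(cls, epochs: list[Epoch]) -> "FactorBank":
        """Normalize real epochs (discarding the traces) and bank their
        factors; all epochs must share one stage."""
        if not epochs:
            raise ValueError("cannot build a factor bank from zero epochs")
        stage = epochs[0].stage
        bank = cls(stage=stage)
        for e in epochs:
            if e.stage != stage:
                raise ValueError(f"mixed stages in bank: {stage} and {e.stage}")
            bank.entries.append(normalize_epoch(e).factors)
        return bank

    def as_array(self) -> np.ndarray:
        return np.array([[f.mean, f.max, f.min] for f in self.entries])

    # ------------------------------------------------------------- JSON I/O
    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                [
                    {"stage": self.stage, "mean": f.mean, "max": f.max, "min": f.min}
                    for f in self.entries
                ],
                indent=2,
            )
        )

    @classmethod
    def load(cls, path) -> "FactorBank":
        rows = json.loads(Path(path).read_text())
        if not rows:
            raise ValueError(f"empty factor bank file: {path}")
        bank = cls(stage=rows[0]["stage"])
        for r in rows:
            bank.entries.append(NormalizationFactors(r["mean"], r["max"], r["min"]))
        return bank


def _check(norm: NormalizedEpoch, bank: FactorBank) -> None:
    if len(bank) == 0:
        raise ValueError(f"factor bank for stage {bank.stage} is empty")
    if norm.stage != bank.stage:
        raise ValueError(f"stage mismatch: epoch is {norm.stage}, bank is {bank.stage}")


def restore_random(norm: NormalizedEpoch, bank: FactorBank, seed: int) -> Epoch:
    """Denormalize with one uniformly selected recorded factor set."""
    _check(norm, bank)
    rng = np.random.default_rng(seed)
    entry = bank.entries[int(rng.integers(0, len(bank)))]
    return denormalize_epoch(norm, entry)


@dataclass(frozen=True)
class SmoteFactors:
    """A synthesized factor set with its parent pair and mixing weight,
    kept so the convexity of the construction is auditable."""

    factors: NormalizationFactors
    parent_a: NormalizationFactors
    parent_b: NormalizationFactors
    lam: float


def smote_factors(
    bank: FactorBank, k_neighbors: int = 5, n_new: int = 1, seed: int = 0
) -> list[SmoteFactors]:
    """SMOTE over the bank's (mean, max, min) triples.

    For each new set: pick a random entry, pick one of its ``k_neighbors``
    nearest other entries (Euclidean, unstandardized — all three
    coordinates are microvolts), and emit ``e + lam * (e' - e)`` with
    ``lam ~ U(0, 1)`` shared across the three coordinates.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if len(bank) <= k_neighbors:
        raise ValueError(
            f"bank of size {len(bank)} too small for k_neighbors={k_neighbors} "
            "(need size > k_neighbors)"
        )
    pts = bank.as_array()
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    neighbor_idx = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]

    rng = np.random.default_rng(seed)
    out: list[SmoteFactors] = []
    for _ in range(n_new):
        i = int(rng.integers(0, len(bank)))
        j = int(neighbor_idx[i, rng.integers(0, k_neighbors)])
        lam = float(rng.random())
        a, b = pts[i], pts[j]
        mixed = a + lam * (b - a)
        out.append(
            SmoteFactors(
                factors=NormalizationFactors(*mixed),
                parent_a=bank.entries[i],
                parent_b=bank.entries[j],
                lam=lam,
            )
        )
    return out


def restore_smote(
    norm: NormalizedEpoch, bank: FactorBank, k_neighbors: int = 5, seed: int = 0
) -> Epoch:
    """Denormalize with one freshly SMOTE-synthesized factor set."""
    _check(norm, bank)
    new = smote_factors(bank, k_neighbors=k_neighbors, n_new=1, seed=seed)[0]
    return denormalize_epoch(norm, new.factors)


def restore_pool(
    norms: list[NormalizedEpoch],
    bank: FactorBank,
    strategy: str = "random",
    k_neighbors: int = 5,
    seed: int = 0,
) -> list[Epoch]:
    """Restore a whole pool of generated epochs with one strategy.

    For SMOTE, ``k_neighbors`` is clamped to the bank size minus one so
    small few-shot banks still work.
    """
    if strategy not in ("random", "smote"):
        raise ValueError(f"unknown restoration strategy {strategy!r}")
    seeds = np.random.SeedSequence(seed).generate_state(max(len(norms), 1)) % (2**31)
    if strategy == "random":
        return [restore_random(n, bank, int(s)) for n, s in zip(norms, seeds)]
    k = min(k_neighbors, len(bank) - 1)
    return [restore_smote(n, bank, k, int(s)) for n, s in zip(norms, seeds)]
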