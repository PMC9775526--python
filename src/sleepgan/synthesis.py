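"""Assemble labeled EEG-epoch sequences from a stage sequence and
per-stage pools of (restored) epochs.

Each entry of the driving stage sequence is paired with an epoch drawn
uniformly from the matching stage's pool — with replacement by default,
since few-shot pools are often smaller than the stage counts in a long
sequence.  Pools may mix generated and real epochs; provenance strings
are carried through so mixing ratios stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signal import STAGES, Epoch


@dataclass
class EpochSequence:
    """An ordered list of (epoch, stage) pairs plus per-entry provenance."""

    epochs: list[Epoch]
    stages: list[str]
    provenance: list[str]

    def __len__(self):
        return len(self.epochs)

    def write(self, out_dir) -> None:
        """Paired array file (epochs as CSV rows) + one-stage-per-line
        label file — the layout downstream sequence classifiers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "epochs.csv", np.stack([e.samples for e in self.epochs]), delimiter=",")
        (out / "labels.txt").write_text("\n".join(self.stages) + "\n")
        (out / "provenance.txt").write_text("\n".join(self.provenance) + "\n")


def synthesize(
    seq: list[str],
    epoch_pools: dict[str, list[Epoch]],
    seed: int = 0,
    replacement: bool = True,
    provenance: dict[str, list[str]] | None = None,
) -> EpochSequence:
    """Pair every stage symbol in ``seq`` with an epoch from its pool.

    ``provenance`` optionally maps stage -> per-epoch origin strings
    (e.g. ``"generated"`` / ``"real"``); defaults to the pool name.
    Without replacement, a pool must hold at least as many epochs as its
    stage occurs in ``seq``.
    """
    for s in seq:
        if s not in STAGES:
            raise ValueError(f"unknown sleep stage {s!r} in sequence")
        if not epoch_pools.get(s):
            raise ValueError(f"no epoch pool for stage {s!r} present in the sequence")

    rng = np.random.default_rng(seed)
    picks: dict[str, list[int]] = {}
    for s in set(seq):
        count = seq.count(s)
        pool_n = len(epoch_pools[s])
        if replacement:
            picks[s] = list(rng.integers(0, pool_n, size=count))
        else:
            if count > pool_n:
                raise ValueError(
                    f"stage {s} occurs {count} times but its pool holds only "
                    f"{pool_n} epochs (replacement disabled)"
                )
            picks[s] = list(rng.permutation(pool_n)[:count])

    cursor = {s: 0 for s in picks}
    epochs, prov = [], []
    for s in seq:
        j = picks[s][cursor[s]]
        cursor[s] += 1
        epochs.append(epoch_pools[s][j])
        prov.append(provenance[s][j] if provenance else f"pool:{s}[{j}]")
    return EpochSequence(epochs=epochs, stages=list(seq), provenance=prov)
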