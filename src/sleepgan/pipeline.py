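"""End-to-end orchestration: epochs -> amplitudes -> sequences -> synthesis
-> evaluation, with a manifest recording every step and seed."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import fixtures, gan, relmem, restore, synthesis
from .config import PipelineConfig, RunManifest, derive_seed
from .evaluate import format_1nn_table, per_stage_1nn_report
from .signal import normalize_epoch

log = logging.getLogger("sleepgan")


def run_pipeline(config: PipelineConfig, seed: int, out_dir) -> RunManifest:
    """Execute the full augmentation pipeline.

    Steps: per-stage GAN training -> sampling -> amplitude restoration ->
    sequence-model training -> sequence sampling -> epoch-sequence
    synthesis -> 1-NN evaluation.  On a failure, completed artifacts stay
    on disk and the manifest marks the failed step.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="run-all", seed=seed, config=config.to_dict())
    step = "fixtures"
    try:
        # ---------------------------------------------------------- real data
        if config.data == "fixtures":
            spec = fixtures.FixtureSpec(
                n_per_stage=config.n_per_stage, seed=derive_seed(seed, "fixtures")
            )
            real = fixtures.generate_fixture_set(spec)
            hypnograms = fixtures.generate_hypnogram_corpus(
                spec, config.n_train_hypnograms, config.sequence_length
            )
        else:
            real = fixtures.load_fixture_set(config.data)
            hypnograms = fixtures.read_hypnogram_file(Path(config.data) / "hypnogram.txt")
        manifest.inputs["n_real_per_stage"] = {s: len(v) for s, v in real.items()}

        # ------------------------------------------- per-stage GAN + restore
        step = "train_epochs"
        pools: dict[str, list] = {}
        norm_pools: dict[str, list] = {}
        for stage in config.stages:
            norms = [normalize_epoch(e) for e in real[stage]]
            bank = restore.FactorBank.from_epochs(real[stage])
            gen, _disc, traces = gan.train_progressive(
                stage,
                np.stack([n.samples for n in norms]),
                config.gan,
                derive_seed(seed, "train_epochs", fixtures.STAGE_INDEX[stage]),
            )
            np.savetxt(
                out / f"loss_trace_{stage}.csv",
                np.column_stack(
                    [
                        np.concatenate([t.d_losses for t in traces]),
                        np.concatenate([t.g_losses for t in traces]),
                    ]
                ),
                delimiter=",",
                header="d_loss,g_loss",
            )
            generated = gan.sample_epochs(
                gen, config.n_generated_per_stage, derive_seed(seed, "sample_seq", 100 + fixtures.STAGE_INDEX[stage])
            )
            norm_pools[stage] = generated
            pools[stage] = restore.restore_pool(
                generated,
                bank,
                strategy=config.restore_strategy,
                k_neighbors=config.smote_k,
                seed=derive_seed(seed, "restore", fixtures.STAGE_INDEX[stage]),
            )
            log.info("stage %s: trained GAN, generated %d epochs", stage, len(pools[stage]))
        for stage, pool in pools.items():
            np.savetxt(
                out / f"generated_{stage}.csv",
                np.stack([e.samples for e in pool]),
                delimiter=",",
            )

        # ------------------------------------------------------ sequence model
        step = "train_seq"
        trained = relmem.train_mle(hypnograms, config.rm, derive_seed(seed, "train_seq"))
        np.savetxt(out / "seq_loss_trace.csv", trained.loss_trace, delimiter=",")

        step = "sample_seq"
        sequences = [
            relmem.generate_sequence(
                trained, config.sequence_length, derive_seed(seed, "sample_seq", i)
            )
            for i in range(config.n_sequences)
        ]
        fixtures.write_hypnogram_file(out / "generated_sequences.txt", sequences)

        step = "synthesize"
        for i, seq in enumerate(sequences):
            missing = [s for s in set(seq) if s not in pools or not pools[s]]
            usable = [s for s in seq if s not in missing]
            if missing:
                log.warning("sequence %d: no pool for stages %s; entries dropped", i, missing)
            synth = synthesis.synthesize(usable, pools, derive_seed(seed, "synthesize", i))
            synth.write(out / f"sequence_{i:03d}")

        # ----------------------------------------------------------- evaluate
        step = "evaluate"
        real_norm = {
            s: [normalize_epoch(e).samples for e in real[s]] for s in config.stages
        }
        gen_norm = {s: [n.samples for n in norm_pools[s]] for s in config.stages}
        report = per_stage_1nn_report(
            real_norm,
            gen_norm,
            n_trials=config.eval_trials,
            n_per_side=config.eval_n_per_side,
            seed=derive_seed(seed, "evaluate"),
        )
        (out / "evaluation.json").write_text(json.dumps(report, indent=2))
        (out / "evaluation.txt").write_text(format_1nn_table(report) + "\n")
        manifest.outputs["evaluation"] = report
    except Exception:
        manifest.finish(status="failed", failed_step=step).write(out)
        raise
    manifest.finish().write(out)
    return manifest
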