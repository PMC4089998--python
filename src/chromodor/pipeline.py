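"""End-to-end orchestration: simulate/load -> consistency -> classify -> RSA.

``run_pipeline`` is a pure function of its :class:`PipelineConfig`: every
stochastic stage draws from a stream derived from the config seed, all
delimited outputs are written with fixed float formatting, and a
provenance manifest (config hash, seed, package versions) suffices to
re-run the bundle identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import AccuracyResult, permutation_test
from .consistency import consistency_table
from .data import Dataset, read_responses, write_responses
from .errors import ChromodorError
from .palette import N_COLORS, load_palette
from .rsa import Rdm, bootstrap_rdm_null, compute_rdm, second_order_rdm
from .simulate import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full analysis run depends on."""

    input_path: Optional[str] = None  # response CSV; None -> simulate
    generator: Optional[GeneratorConfig] = None
    palette_path: Optional[str] = None
    output_dir: str = "chromodor_out"
    seed: int = 0
    n_folds: int = 3
    n_shuffles: int = 1000
    n_permutations: int = 10000
    rdm_null_reps: int = 1000
    shrinkage: object = "auto"
    per_trial_null: bool = True
    congruent_only: bool = False
    second_order_method: str = "pearson"
    alpha: float = 0.05
    bonferroni_m: Optional[int] = None
    figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            g = dataclasses.asdict(self.generator)
            g["groups"] = dict(self.generator.groups)
            g["odors"] = list(self.generator.odors)
            g["group_pairs_shared"] = [list(p) for p in self.generator.group_pairs_shared]
            d["generator"] = g
        return d


@dataclass
class ResultBundle:
    dataset: Dataset
    consistency: pd.DataFrame
    accuracy: dict[str, AccuracyResult]
    rdms: dict[str, Rdm]
    second_order: Rdm
    manifest: dict
    output_dir: Path


def _feature_mask(config: PipelineConfig) -> Optional[np.ndarray]:
    if not config.congruent_only:
        return None
    mask = np.zeros(2 * N_COLORS, dtype=bool)
    mask[:N_COLORS] = True
    return mask


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Run every analysis stage and write the result bundle to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = _stage("load")
    palette = load_palette(config.palette_path)
    if config.input_path is not None:
        dataset = read_responses(config.input_path, palette=palette)
    else:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        dataset = generate_dataset(gen, palette=palette)
        write_responses(dataset, str(out / "responses.csv"))
    timings["load"] = time.perf_counter() - t0

    mask = _feature_mask(config)
    root = np.random.SeedSequence(config.seed)
    group_seeds = {
        g: ss for g, ss in zip(dataset.groups, root.spawn(2 * len(dataset.groups)))
    }
    rsa_seeds = {
        g: ss
        for g, ss in zip(dataset.groups,
                         root.spawn(2 * len(dataset.groups))[len(dataset.groups):])
    }

    t0 = _stage("consistency")
    try:
        cons = consistency_table(dataset, alpha=config.alpha, m=config.bonferroni_m)
    except ChromodorError as exc:
        raise ChromodorError(f"stage consistency failed: {exc}") from exc
    cons.to_csv(out / "consistency.csv", index=False, float_format=_FLOAT_FMT)
    timings["consistency"] = time.perf_counter() - t0

    t0 = _stage("classification")
    accuracy: dict[str, AccuracyResult] = {}
    for g in dataset.groups:
        try:
            accuracy[g] = permutation_test(
                dataset, g,
                n_folds=config.n_folds,
                n_shuffles=config.n_shuffles,
                n_permutations=config.n_permutations,
                seed=int(group_seeds[g].generate_state(1)[0] % (2**31)),
                shrinkage=config.shrinkage,
                feature_mask=mask,
                per_trial=config.per_trial_null,
            )
        except ChromodorError as exc:
            raise ChromodorError(f"stage classification failed for {g!r}: {exc}") from exc
    acc_table = pd.DataFrame(
        {
            "group": list(accuracy),
            "mean_accuracy": [accuracy[g].mean_accuracy for g in accuracy],
            "sd_accuracy": [accuracy[g].sd_accuracy for g in accuracy],
            "null_mean": [float(accuracy[g].null_distribution.mean()) for g in accuracy],
            "p": [accuracy[g].p for g in accuracy],
        }
    )
    acc_table.to_csv(out / "accuracy.csv", index=False, float_format=_FLOAT_FMT)
    for g in accuracy:
        np.savetxt(out / f"accuracy_sample_{g}.csv",
                   accuracy[g].accuracy_sample, fmt=_FLOAT_FMT)
        np.savetxt(out / f"accuracy_null_{g}.csv",
                   accuracy[g].null_distribution, fmt=_FLOAT_FMT)
    timings["classification"] = time.perf_counter() - t0

    t0 = _stage("rsa")
    rdms: dict[str, Rdm] = {}
    for g in dataset.groups:
        try:
            rdm = compute_rdm(dataset, g, feature_mask=mask)
            null = bootstrap_rdm_null(
                dataset, g, n_reps=config.rdm_null_reps,
                seed=int(rsa_seeds[g].generate_state(1)[0] % (2**31)),
                per_trial=config.per_trial_null, feature_mask=mask,
            )
            rdms[g] = Rdm(rdm.labels, rdm.matrix, null.ravel())
        except ChromodorError as exc:
            raise ChromodorError(f"stage rsa failed for {g!r}: {exc}") from exc
        rdms[g].to_frame().to_csv(out / f"rdm_{g}.csv", float_format=_FLOAT_FMT)
        np.savetxt(out / f"rdm_null_{g}.csv", rdms[g].null_distribution,
                   fmt=_FLOAT_FMT)
    second = second_order_rdm(rdms, method=config.second_order_method)
    second.to_frame().to_csv(out / "rdm_second_order.csv", float_format=_FLOAT_FMT)
    timings["rsa"] = time.perf_counter() - t0

    if config.figures:
        t0 = _stage("figures")
        import matplotlib.pyplot as plt

        from .plotting import plot_congruency, plot_rdm

        for ext in ("png", "svg"):
            plt.close(plot_congruency(dataset, str(out / f"congruency.{ext}")))
            for g in dataset.groups:
                plt.close(plot_rdm(rdms[g], str(out / f"rdm_{g}.{ext}"),
                                   title=f"odor RDM: {g}"))
            plt.close(plot_rdm(second, str(out / f"rdm_second_order.{ext}"),
                               title="between-group RDM"))
        timings["figures"] = time.perf_counter() - t0

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "chromodor": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_groups": len(dataset.groups),
        "n_odors": len(dataset.odors),
        "n_participants": dataset.n_participants,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return ResultBundle(
        dataset=dataset, consistency=cons, accuracy=accuracy, rdms=rdms,
        second_order=second, manifest=manifest, output_dir=out,
    )
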