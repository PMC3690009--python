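"""Canned comparison experiments on simulated homes.

Composes the simulator, the feature representations, the trainers and the
leave-one-day-out harness into one call: simulate R independent homes,
run the per-home cross-validation for each model, and collect the per-home
mean macro F-measures.  This is the package's replication harness for the
central comparison (hybrid recognizers vs. their static counterparts vs.
the generative baseline).
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

from .evaluation import leave_one_day_out, summarize_folds
from .features import featurize
from .hybrid import Trainer, TrainOptions, make_hmm_trainer, make_hybrid_trainer, \
    make_static_trainer
from .emitters import EmitterConfig
from .sensor_data import split_days
from .simulate import SimConfig, sample_home, small_home

__all__ = ["default_model_suite", "compare_on_replicates"]


def default_model_suite(seed: int, emitter_subsample: int = 1
                        ) -> dict[str, Trainer]:
    """The five standard contenders: generative HMM, two hybrids, two
    sliding-window classifiers."""
    opts = TrainOptions(seed=seed, emitter_subsample=emitter_subsample)
    return {
        "hmm": make_hmm_trainer(),
        "hybrid_mlp": make_hybrid_trainer(EmitterConfig(kind="mlp", seed=seed),
                                          opts),
        "hybrid_svm": make_hybrid_trainer(EmitterConfig(kind="svm", seed=seed),
                                          opts),
        "static_mlp": make_static_trainer(EmitterConfig(kind="mlp", seed=seed),
                                          opts),
        "static_svm": make_static_trainer(EmitterConfig(kind="svm", seed=seed),
                                          opts),
    }


def compare_on_replicates(
    n_replicates: int,
    seed: int,
    config: SimConfig | None = None,
    representation: str = "raw",
    model_suite: Callable[[int], Mapping[str, Trainer]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-replicate leave-one-day-out mean macro F for each model.

    Each replicate simulates an independent home (seeds ``seed + r``) and
    evaluates every model on the same days.  Returns
    ``{model: array of n_replicates mean F values}``.
    """
    config = config or small_home()
    model_suite = model_suite or default_model_suite
    scores: dict[str, list[float]] = {}
    for r in range(n_replicates):
        rep_seed = int(seed) + r
        sim = sample_home(config, seed=rep_seed)
        days = [(featurize(o, representation), l)
                for o, l in split_days(*sim.truth)]
        for name, trainer in model_suite(rep_seed).items():
            folds = leave_one_day_out(days, trainer)
            scores.setdefault(name, []).append(
                summarize_folds(folds)["fmeasure_mean"])
    return {name: np.asarray(vals) for name, vals in scores.items()}
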