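"""End-to-end experiment: simulate -> segment -> train -> score -> evaluate.

Reproduces the study design at desk scale on synthetic phantoms: a training
cohort and a disjoint test cohort are generated, the selected candidate
network is trained on voxel triplets from the training cohort, every test
calcification is scored by per-voxel probability averaging, and the
semi-quantitative comparator is run on the same test cohort.  All
randomness fans out from one master seed through named substreams, so the
whole run — including the score file bytes — is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._random import substream_seed
from .cnn import TrainConfig, build_network, score_calcification, train
from .config import RunConfig
from .core import STONE, CalcMask, CTStack, CalcnetError, EmptySegmentationError
from .evaluation import confusion, metrics, roc_auc
from .io import write_manifest, write_scores
from .patches import build_training_set
from .phantom import CohortDistributions, generate_cohort
from .segmentation import segment_stack
from .semiquant import measure_stack, semiquant_classify

logger = logging.getLogger(__name__)


@dataclass
class ExperimentReport:
    """Consolidated outcome of one run_experiment call."""

    config: dict
    seeds: dict
    scores: pd.DataFrame
    semiquant: pd.DataFrame
    cnn_metrics: dict
    semiquant_metrics: dict
    training_log: pd.DataFrame
    n_train_examples: int
    excluded: list = field(default_factory=list)

    def metrics_json(self) -> str:
        payload = {
            "config": self.config,
            "seeds": self.seeds,
            "n_train_examples": self.n_train_examples,
            "excluded": self.excluded,
            "cnn": self.cnn_metrics,
            "semiquant": self.semiquant_metrics,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _segment_cohort(stacks: list[CTStack], threshold: float
                    ) -> tuple[list[tuple[CTStack, CalcMask, str]], list[str]]:
    kept, excluded = [], []
    for stack in stacks:
        try:
            mask = segment_stack(stack, threshold)
        except EmptySegmentationError:
            logger.warning("excluding %s: empty segmentation", stack.id)
            excluded.append(stack.id)
            continue
        kept.append((stack, mask, stack.label))
    return kept, excluded


def _metrics_block(pred, truth, scores, ci_method, level) -> dict:
    cm = confusion(pred, truth)
    rep = metrics(cm, ci_method=ci_method, level=level)
    block = rep.as_dict()
    block["confusion"] = {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn}
    if scores is not None:
        auc, _, _ = roc_auc(scores, truth)
        block["auc"] = auc
    return block


def run_permutation_control(config: RunConfig | None = None,
                            distributions: CohortDistributions | None = None
                            ) -> dict:
    """Label-permutation null: train on randomly permuted training labels,
    then evaluate on the untouched test cohort.

    With the class signal destroyed, held-out accuracy should sit at chance;
    a materially better result would reveal leakage between the cohorts.
    Returns {"accuracy": ..., "n": ...}.
    """
    config = config or RunConfig()
    seeds = {name: substream_seed(config.seed, name)
             for name in ("phantom-train", "phantom-test", "network-init",
                          "train-shuffle", "label-permutation")}
    train_stacks, _ = generate_cohort(
        config.n_train_stones, config.n_train_phleboliths,
        distributions=distributions, seed=seeds["phantom-train"],
        id_prefix="tr")
    test_stacks, _ = generate_cohort(
        config.n_test_stones, config.n_test_phleboliths,
        distributions=distributions, seed=seeds["phantom-test"],
        id_prefix="te")
    train_items, _ = _segment_cohort(train_stacks, config.threshold_hu)
    test_items, _ = _segment_cohort(test_stacks, config.threshold_hu)

    rng = np.random.default_rng(seeds["label-permutation"])
    labels = [label for _, _, label in train_items]
    permuted = [labels[i] for i in rng.permutation(len(labels))]
    shuffled_items = [(s, m, lab) for (s, m, _), lab
                      in zip(train_items, permuted)]

    training_set = build_training_set(shuffled_items,
                                      patch_size=config.patch_size,
                                      mirror=config.mirror,
                                      window=config.hu_window)
    model = build_network(config.candidate, config.patch_size,
                          seed=seeds["network-init"])
    train(model, training_set,
          TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                      learning_rate=config.learning_rate,
                      val_fraction=0.0, seed=seeds["train-shuffle"]))
    correct = 0
    for stack, mask, label in test_items:
        cs = score_calcification(model, stack, mask, cutoff=config.cutoff,
                                 patch_size=config.patch_size,
                                 window=config.hu_window)
        correct += int(cs.predicted_label == label)
    return {"accuracy": correct / len(test_items), "n": len(test_items)}


def run_experiment(config: RunConfig | None = None,
                   out_dir: str | Path | None = None,
                   distributions: CohortDistributions | None = None
                   ) -> ExperimentReport:
    """Run the full synthetic experiment described by `config`.

    When `out_dir` is given, writes scores.csv, semiquant.csv, metrics.json,
    manifests and the resolved config there.  Train and test cohorts carry
    disjoint id prefixes; an overlap is a hard error (leakage guard).
    """
    config = config or RunConfig()
    seeds = {name: substream_seed(config.seed, name)
             for name in ("phantom-train", "phantom-test", "network-init",
                          "train-shuffle")}

    train_stacks, train_manifest = generate_cohort(
        config.n_train_stones, config.n_train_phleboliths,
        distributions=distributions, seed=seeds["phantom-train"],
        id_prefix="tr")
    test_stacks, test_manifest = generate_cohort(
        config.n_test_stones, config.n_test_phleboliths,
        distributions=distributions, seed=seeds["phantom-test"],
        id_prefix="te")

    overlap = set(train_manifest["id"]) & set(test_manifest["id"])
    if overlap:
        raise CalcnetError(f"train/test id overlap: {sorted(overlap)[:5]}")

    train_items, excluded_train = _segment_cohort(train_stacks,
                                                  config.threshold_hu)
    test_items, excluded_test = _segment_cohort(test_stacks, config.threshold_hu)
    if not train_items or not test_items:
        raise CalcnetError("no usable calcifications after segmentation")

    training_set = build_training_set(train_items, patch_size=config.patch_size,
                                      mirror=config.mirror,
                                      window=config.hu_window)
    model = build_network(config.candidate, config.patch_size,
                          seed=seeds["network-init"])
    log = train(model, training_set,
                TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                            learning_rate=config.learning_rate,
                            val_fraction=config.val_fraction,
                            seed=seeds["train-shuffle"]))

    score_rows, sq_rows = [], []
    for stack, mask, label in test_items:
        cs = score_calcification(model, stack, mask, cutoff=config.cutoff,
                                 patch_size=config.patch_size,
                                 window=config.hu_window)
        score_rows.append({"id": stack.id, "n_voxels": cs.n_voxels,
                           "score": cs.score, "label": cs.predicted_label,
                           "truth": label})
        m = measure_stack(stack, mask)
        sq_rows.append({"id": stack.id, "W": round(m.W, 4), "L": round(m.L, 4),
                        "H": round(m.H, 4), "volume_mm3": round(m.volume, 4),
                        "mean_hu": round(m.mean_hu, 2),
                        "label": semiquant_classify(m.mean_hu, m.volume,
                                                    config.hu_cutoff,
                                                    config.vol_cutoff),
                        "truth": label})
    scores = pd.DataFrame(score_rows)
    semiquant = pd.DataFrame(sq_rows)

    cnn_block = _metrics_block(scores["label"], scores["truth"],
                               scores["score"], config.ci_method,
                               config.ci_level)
    sq_block = _metrics_block(semiquant["label"], semiquant["truth"], None,
                              config.ci_method, config.ci_level)
    # comparator AUCs for the two raw measurements
    truth_bin = (semiquant["truth"] == STONE).astype(int)
    if truth_bin.nunique() == 2:
        sq_block["auc_hu"] = roc_auc(semiquant["mean_hu"], truth_bin)[0]
        sq_block["auc_volume"] = roc_auc(semiquant["volume_mm3"], truth_bin)[0]

    report = ExperimentReport(
        config=config.to_dict(), seeds=seeds, scores=scores,
        semiquant=semiquant, cnn_metrics=cnn_block, semiquant_metrics=sq_block,
        training_log=log, n_train_examples=len(training_set),
        excluded=excluded_train + excluded_test)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_scores(scores, out / "scores.csv")
        semiquant.to_csv(out / "semiquant.csv", index=False)
        write_manifest(train_manifest, out / "train_manifest.csv")
        write_manifest(test_manifest, out / "test_manifest.csv")
        (out / "metrics.json").write_text(report.metrics_json())
        config.to_yaml(out / "config.yaml")
        log.to_csv(out / "training_log.csv", index=False)
    return report
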