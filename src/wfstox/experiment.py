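"""Configuration-driven experiment runner.

Reproduces the model-set comparison workflow end to end: build feature
blocks (from files or the synthetic generator), optionally screen and
select DTA / assay-readout features, fit WFS models per ADE under a
repeated 50/50 holdout shared across model sets, and emit tidy CSV
reports — per-ADE per-split AUCs, a summary table (best AUC, mean AUC,
count of ADEs above 0.75), a pairwise comparison report, and optional
permutation nulls.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import selection
from .evaluation import (
    ModelSetSummary,
    SplitPlan,
    compare_model_sets,
    permutation_null,
    permute_feature_block,
    run_repeated_holdout,
)
from .matrices import (
    ADELabelMatrix,
    FeatureMatrix,
    align_compounds,
    filter_ades,
    read_ade_labels,
    read_feature_matrix,
)
from .synthetic import GeneratorConfig, generate

__all__ = ["ExperimentConfig", "run_experiment"]

logger = logging.getLogger(__name__)

_BASE_BLOCKS = ("assay", "dta", "structure", "animal")
_SELECTED = {"dta_selected": ("dta", selection.DTA_THRESHOLD),
             "assay_selected": ("assay", selection.READOUT_THRESHOLD)}


@dataclasses.dataclass
class ExperimentConfig:
    """One experiment: inputs, model sets, split plan, permutations.

    ``model_sets`` maps a label to the blocks concatenated column-wise
    for that model, e.g. ``{"assay": ["assay"], "assay+dta": ["assay",
    "dta"], "assay+dta_selected": ["assay", "dta_selected"]}``.
    """

    model_sets: dict[str, list[str]]
    input_dir: str | None = None
    generator: GeneratorConfig | None = None
    min_drugs: int = 1
    n_splits: int = 10
    split_fraction: float = 0.5
    seed: int = 0
    n_label_perm: int = 0
    permute_block: str | None = None
    out_dir: str = "wfstox_out"

    def __post_init__(self) -> None:
        if not self.model_sets:
            raise ValueError("define at least one model set")
        if self.input_dir is None and self.generator is None:
            raise ValueError("provide input_dir or a generator config")
        known = set(_BASE_BLOCKS) | set(_SELECTED)
        for label, blocks in self.model_sets.items():
            unknown = set(blocks) - known
            if unknown:
                raise ValueError(f"model set {label!r} references unknown blocks {sorted(unknown)}")
        if self.input_dir is not None:
            base = Path(self.input_dir)
            needed = {b for bl in self.model_sets.values() for b in bl}
            needed = {_SELECTED.get(b, (b,))[0] for b in needed}
            for name in sorted(needed | {"ades"}):
                if not (base / f"{name}.csv").exists():
                    raise FileNotFoundError(base / f"{name}.csv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig(**gen)
        return cls(generator=gen, **raw)


def _load_blocks(
    config: ExperimentConfig,
) -> tuple[dict[str, FeatureMatrix], ADELabelMatrix]:
    if config.input_dir is not None:
        base = Path(config.input_dir)
        blocks = {}
        for name in _BASE_BLOCKS:
            path = base / f"{name}.csv"
            if path.exists():
                blocks[name] = read_feature_matrix(path, name)
        labels = read_ade_labels(base / "ades.csv")
        return blocks, labels
    dataset = generate(config.generator)
    return dataset.blocks(), dataset.ades


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full workflow; returns summaries and writes the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    blocks, labels = _load_blocks(config)
    labels = filter_ades(labels, config.min_drugs)
    block_list, labels, dropped = align_compounds(list(blocks.values()), labels)
    blocks = dict(zip(blocks.keys(), block_list))
    logger.info("aligned %d compounds (dropped: %s)", len(labels.compound_ids), dropped)

    # feature selection for *_selected pseudo-blocks
    selections: dict[str, set[str]] = {}
    needed = {b for bl in config.model_sets.values() for b in bl}
    for pseudo, (base_name, threshold) in _SELECTED.items():
        if pseudo in needed:
            records = selection.screen_block(blocks[base_name], labels)
            chosen = selection.select_features(records, threshold)
            selections[pseudo] = chosen
            selection.records_to_frame(records).to_csv(
                out / f"screen_{base_name}.csv", index=False
            )
            with open(out / f"selected_{base_name}.csv", "w") as fh:
                fh.write("feature_id\n" + "\n".join(sorted(chosen)) + "\n")
            logger.info("%s: %d/%d features selected at >%s",
                        pseudo, len(chosen), blocks[base_name].shape[1], threshold)

    def materialise(name: str) -> FeatureMatrix:
        if name in _SELECTED:
            base_name, _ = _SELECTED[name]
            base = blocks[base_name]
            cols = [f for f in base.feature_ids if f in selections[name]]
            if not cols:
                raise ValueError(f"{name}: no features passed selection")
            return FeatureMatrix(base.data[cols], name)
        return blocks[name]

    plan = SplitPlan(
        n_compounds=len(labels.compound_ids),
        n_splits=config.n_splits,
        split_fraction=config.split_fraction,
        seed=config.seed,
    )

    summaries: list[ModelSetSummary] = []
    for label, names in config.model_sets.items():
        merged = materialise(names[0])
        for name in names[1:]:
            merged = merged.concat(materialise(name))
        results, summary = run_repeated_holdout(merged, labels, plan, model_label=label)
        summaries.append(summary)
        pd.DataFrame(
            {
                "ade_id": [r.ade_id for r in results],
                "split": [r.split_index for r in results],
                "auc": [r.auc_roc for r in results],
            }
        ).to_csv(out / f"results_{label.replace('+', '_')}.csv", index=False)
        logger.info("model set %s: mean AUC %.3f", label, summary.grand_mean_auc)

    summary_df = pd.concat([s.to_frame() for s in summaries], ignore_index=True)
    summary_df.to_csv(out / "summary.csv", index=False)

    comparison = None
    if len(summaries) >= 2:
        comparison = compare_model_sets(summaries)
        comparison.to_csv(out / "comparison.csv", index=False)

    null_means = None
    if config.n_label_perm > 0:
        first_label, first_names = next(iter(config.model_sets.items()))
        merged = materialise(first_names[0])
        for name in first_names[1:]:
            merged = merged.concat(materialise(name))
        null_means, p = permutation_null(
            merged,
            labels,
            plan,
            n_perm=config.n_label_perm,
            observed_mean=summaries[0].grand_mean_auc,
            seed=config.seed + 1,
        )
        pd.DataFrame({"null_mean_auc": null_means}).to_csv(
            out / "label_permutation_null.csv", index=False
        )
        logger.info("label-permutation null mean %.3f, empirical p %.4g",
                    null_means.mean(), p)

    run_log = {
        "seed": config.seed,
        "n_splits": config.n_splits,
        "split_fraction": config.split_fraction,
        "n_compounds": len(labels.compound_ids),
        "n_ades": len(labels.ade_ids),
        "model_sets": config.model_sets,
        "dropped": dropped,
        "mean_auc": {s.model_label: s.grand_mean_auc for s in summaries},
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return {
        "summaries": summaries,
        "summary_table": summary_df,
        "comparison": comparison,
        "null_means": null_means,
        "labels": labels,
    }
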