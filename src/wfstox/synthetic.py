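"""Synthetic benchmark generator for the ADE-prediction pipeline.

Real inputs for this kind of analysis — qHTS activity profiles, curated
drug-target annotations (DTAs), structure fingerprints, animal-toxicity
endpoints, and adverse-effect labels — are proprietary or large.  This
module generates linked matrices with the same statistical skeleton so
that every pipeline stage can be exercised and, crucially, so that
ground truth is known for recovery tests.

The generative model: each compound interacts with latent protein
targets.  Only a subset of targets is covered by the assay panel
(emulating the limited biological space of a real screening battery);
assay readouts are noisy, partially missing reporters of interactions
with *assayed* targets.  DTA columns annotate true interactions with any
target, at partial coverage and with no false annotations.  Each adverse
effect is caused by a few targets — biased toward the *unassayed* pool —
and a compound's label probability grows additively with the number of
causal targets it hits (a noisy-OR-like link, capped at 1).  Structure
bits report latent scaffold membership, and scaffolds bias interaction
probabilities toward favoured targets, so structure correlates with
toxicity without reading it directly.  Animal endpoints are noisy OR
readouts of random target subsets.

All randomness flows from one seed; each matrix draws from its own
deterministic sub-stream, so adding a block never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrices import ADELabelMatrix, FeatureMatrix, write_matrix
from .qc import TriplicateCallTable

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "generate_triplicates"]

_PROB_FIELDS = (
    "p_interact",
    "flip_noise",
    "missing_rate",
    "dta_coverage",
    "ade_background",
    "ade_link",
    "unassayed_bias",
    "scaffold_boost",
    "struct_noise",
    "animal_noise",
)


@dataclasses.dataclass
class GeneratorConfig:
    """Knobs of the generative model.

    Defaults are sized for a desk-scale study: 300 compounds, a 30-readout
    assay panel covering 15 of 40 targets, 40 DTAs (one per target at 90%
    coverage), 20 ADEs each caused by 3 targets drawn with 0.8 weight on
    the unassayed pool.  Interaction, noise and link rates are set so that
    a DTA annotating a causal target is a useful but imperfect univariate
    predictor and assay-only models retain modest signal.
    """

    n_compounds: int = 300
    n_targets: int = 40
    n_assayed_targets: int = 15
    n_readouts: int = 30
    n_dtas: int = 40
    n_fingerprint_bits: int = 64
    n_ades: int = 20
    p_interact: float = 0.15
    flip_noise: float = 0.05
    missing_rate: float = 0.02
    dta_coverage: float = 0.9
    ade_background: float = 0.1
    ade_link: float = 0.5
    targets_per_ade: int = 3
    unassayed_bias: float = 0.8
    n_scaffolds: int = 8
    scaffold_boost: float = 0.2
    struct_noise: float = 0.1
    n_animal_endpoints: int = 12
    animal_targets_per_endpoint: int = 3
    animal_noise: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for field in _PROB_FIELDS:
            v = getattr(self, field)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{field} must be in [0, 1], got {v}")
        if self.n_assayed_targets > self.n_targets:
            raise ValueError("n_assayed_targets cannot exceed n_targets")
        if self.targets_per_ade > self.n_targets:
            raise ValueError("targets_per_ade cannot exceed n_targets")
        if self.n_readouts < self.n_assayed_targets:
            raise ValueError("need at least one readout per assayed target")
        for field in (
            "n_compounds", "n_targets", "n_assayed_targets", "n_readouts",
            "n_dtas", "n_fingerprint_bits", "n_ades", "targets_per_ade",
            "n_scaffolds", "n_animal_endpoints", "animal_targets_per_endpoint",
        ):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")


@dataclasses.dataclass
class SyntheticDataset:
    """The generated matrices plus the latent ground truth.

    ``truth`` records the compound×target interaction matrix, the per-ADE
    causal target sets, the scaffold assignment, and the readout→target
    and DTA→target maps, for parameter-recovery tests.
    """

    assay: FeatureMatrix
    dta: FeatureMatrix
    structure: FeatureMatrix
    animal: FeatureMatrix
    ades: ADELabelMatrix
    truth: dict

    def blocks(self) -> dict[str, FeatureMatrix]:
        return {
            "assay": self.assay,
            "dta": self.dta,
            "structure": self.structure,
            "animal": self.animal,
        }

    def write(self, out_dir: str | Path) -> None:
        """Write all matrices as CSV plus the truth as JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, block in self.blocks().items():
            write_matrix(block, out / f"{name}.csv")
        write_matrix(self.ades, out / "ades.csv")
        truth = dict(self.truth)
        truth["interactions"] = self.truth["interactions"].to_dict(orient="split")
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # one sub-stream per matrix: adding a block never perturbs the others
    return np.random.default_rng([config.seed, stream])


def _mask_missing(values: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = values.astype(float)
    if rate > 0:
        out[rng.random(values.shape) < rate] = np.nan
    return out


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one dataset from the generative model (reproducible from seed)."""
    compounds = [f"C{i:04d}" for i in range(config.n_compounds)]

    # scaffolds and their favoured targets
    rng_s = _rng(config, 0)
    scaffold_of = rng_s.integers(config.n_scaffolds, size=config.n_compounds)
    n_fav = max(1, config.n_targets // 8)
    favoured = np.zeros((config.n_scaffolds, config.n_targets), dtype=bool)
    for s in range(config.n_scaffolds):
        favoured[s, rng_s.choice(config.n_targets, size=n_fav, replace=False)] = True

    # latent compound-target interactions, scaffold-biased
    rng_z = _rng(config, 1)
    p = np.clip(
        config.p_interact + config.scaffold_boost * favoured[scaffold_of], 0.0, 1.0
    )
    interactions = rng_z.random((config.n_compounds, config.n_targets)) < p

    # assay readouts: noisy, partially missing reporters of assayed targets
    rng_a = _rng(config, 2)
    readout_target = np.arange(config.n_readouts) % config.n_assayed_targets
    assay_true = interactions[:, readout_target]
    flips = rng_a.random(assay_true.shape) < config.flip_noise
    assay_vals = _mask_missing(
        (assay_true ^ flips).astype(float), config.missing_rate, rng_a
    )
    assay = FeatureMatrix(
        pd.DataFrame(
            assay_vals,
            index=compounds,
            columns=[f"readout_{j:03d}" for j in range(config.n_readouts)],
        ),
        "assay",
    )

    # DTAs: annotate true interactions only, at partial coverage
    rng_d = _rng(config, 3)
    dta_target = np.arange(config.n_dtas) % config.n_targets
    annotated = interactions[:, dta_target] & (
        rng_d.random((config.n_compounds, config.n_dtas)) < config.dta_coverage
    )
    dta = FeatureMatrix(
        pd.DataFrame(
            annotated.astype(float),
            index=compounds,
            columns=[f"dta_{j:03d}" for j in range(config.n_dtas)],
        ),
        "dta",
    )

    # structure bits report scaffold membership with noise
    rng_f = _rng(config, 4)
    bit_scaffold = np.arange(config.n_fingerprint_bits) % config.n_scaffolds
    bit_true = scaffold_of[:, None] == bit_scaffold[None, :]
    bit_flips = rng_f.random(bit_true.shape) < config.struct_noise
    structure = FeatureMatrix(
        pd.DataFrame(
            (bit_true ^ bit_flips).astype(float),
            index=compounds,
            columns=[f"bit_{j:03d}" for j in range(config.n_fingerprint_bits)],
        ),
        "structure",
    )

    # animal endpoints: noisy OR over random target subsets
    rng_v = _rng(config, 5)
    animal_vals = np.empty((config.n_compounds, config.n_animal_endpoints))
    animal_targets = []
    for e in range(config.n_animal_endpoints):
        subset = rng_v.choice(
            config.n_targets, size=config.animal_targets_per_endpoint, replace=False
        )
        animal_targets.append([int(t) for t in subset])
        true_val = interactions[:, subset].any(axis=1)
        flips = rng_v.random(config.n_compounds) < config.animal_noise
        animal_vals[:, e] = (true_val ^ flips).astype(float)
    animal_vals = _mask_missing(animal_vals, config.missing_rate, rng_v)
    animal = FeatureMatrix(
        pd.DataFrame(
            animal_vals,
            index=compounds,
            columns=[f"endpoint_{j:02d}" for j in range(config.n_animal_endpoints)],
        ),
        "animal",
    )

    # ADEs: additive link from causal targets, biased toward unassayed ones
    rng_e = _rng(config, 6)
    assayed = np.zeros(config.n_targets, dtype=bool)
    assayed[: config.n_assayed_targets] = True
    weights = np.empty(config.n_targets)
    n_un = int((~assayed).sum())
    if n_un == 0 or assayed.sum() == 0:
        weights[:] = 1.0 / config.n_targets
    else:
        weights[~assayed] = config.unassayed_bias / n_un
        weights[assayed] = (1.0 - config.unassayed_bias) / assayed.sum()
    causal_map: dict[str, list[int]] = {}
    labels = np.empty((config.n_compounds, config.n_ades), dtype=int)
    for a in range(config.n_ades):
        ade_id = f"ade_{a:03d}"
        causal = rng_e.choice(
            config.n_targets, size=config.targets_per_ade, replace=False, p=weights
        )
        causal_map[ade_id] = sorted(int(t) for t in causal)
        hits = interactions[:, causal].sum(axis=1)
        p_ade = np.clip(config.ade_background + config.ade_link * hits, 0.0, 1.0)
        labels[:, a] = (rng_e.random(config.n_compounds) < p_ade).astype(int)
    ades = ADELabelMatrix(
        pd.DataFrame(labels, index=compounds, columns=list(causal_map))
    )

    truth = {
        "interactions": pd.DataFrame(
            interactions.astype(int),
            index=compounds,
            columns=[f"target_{t:03d}" for t in range(config.n_targets)],
        ),
        "causal_targets": causal_map,
        "scaffold_of": {c: int(s) for c, s in zip(compounds, scaffold_of)},
        "readout_target": {
            f"readout_{j:03d}": int(t) for j, t in enumerate(readout_target)
        },
        "dta_target": {f"dta_{j:03d}": int(t) for j, t in enumerate(dta_target)},
        "animal_targets": {
            f"endpoint_{j:02d}": ts for j, ts in enumerate(animal_targets)
        },
        "assayed_targets": [int(t) for t in np.flatnonzero(assayed)],
    }
    return SyntheticDataset(assay, dta, structure, animal, ades, truth)


def generate_triplicates(
    config: GeneratorConfig,
    call_noise: float,
    states: Sequence[str] = ("activation", "inhibition", "inactive"),
) -> TriplicateCallTable:
    """Three independent noisy activity calls per (compound, assay).

    Each assay has a fixed direction; a compound's latent call is that
    direction when it interacts with the assay's target, ``inactive``
    otherwise.  Each replicate reports the latent call, except with
    probability ``call_noise`` it is replaced by a uniform draw from
    ``states`` (which may coincide with the latent call).
    """
    if not (0.0 <= call_noise <= 1.0):
        raise ValueError("call_noise must be in [0, 1]")
    rng = _rng(config, 7)
    compounds = [f"C{i:04d}" for i in range(config.n_compounds)]
    readout_target = np.arange(config.n_readouts) % config.n_assayed_targets
    interactions = rng.random((config.n_compounds, config.n_targets)) < config.p_interact
    directions = rng.choice(["activation", "inhibition"], size=config.n_readouts)
    rows = []
    states = list(states)
    for j in range(config.n_readouts):
        assay_id = f"readout_{j:03d}"
        latent = np.where(
            interactions[:, readout_target[j]], directions[j], "inactive"
        )
        for rep in (1, 2, 3):
            noisy = rng.random(config.n_compounds) < call_noise
            random_calls = rng.choice(states, size=config.n_compounds)
            calls = np.where(noisy, random_calls, latent)
            rows.append(
                pd.DataFrame(
                    {
                        "compound_id": compounds,
                        "assay_id": assay_id,
                        "replicate": rep,
                        "call": calls,
                    }
                )
            )
    return TriplicateCallTable(pd.concat(rows, ignore_index=True))
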