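"""Synthetic expression data with planted reversed gene pairs.

The generator emulates the data regime the panel is built for: gene-level
expression matrices (log-intensity-like scale) over five lung tumor subtypes
(SCLC, LCNEC, CARCI, ADC, SCC) or a plain two-group contrast, with

* i.i.d. Gaussian background genes carrying no class signal,
* *planted* gene pairs per hierarchy step whose within-sample ordering flips
  between the step's positive and negative group — gene_a is shifted up and
  gene_b down by ``effect_size`` standard deviations in the positive group
  and the reverse in the negative group, while both stay at baseline outside
  the step's sample universe,
* optional missing-at-random dropout (FFPE / small-biopsy emulation), and
* optional label corruption (pathological misdiagnosis emulation) that
  changes a sample's *observed* label while its expression keeps following
  the true subtype.

Default subtype sizes are balanced at every binary split of the hierarchy
(20 SCLC + 20 LCNEC vs 40 CARCI vs 40 ADC + 40 SCC), so each step's planted
pairs are informative exactly for their own step.  Every draw flows from one
seed; a fixed seed reproduces the dataset bit for bit.  The planted truth is
recorded exactly, so recovery metrics need no external reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    GenePair,
    LabelTable,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SyntheticDataset",
    "simulate",
    "degrade",
    "corrupt_labels",
    "train_test_split",
    "DEFAULT_SUBTYPE_SIZES",
    "FINAL_LABEL_BY_SUBTYPE",
]

#: Default five-subtype cohort, balanced at each binary split of the
#: hierarchy: NE (80) vs non-NE (80); CARCI (40) vs SCLC+LCNEC (40);
#: SCLC (20) vs LCNEC (20).
DEFAULT_SUBTYPE_SIZES: dict[str, int] = {
    "SCLC": 20,
    "LCNEC": 20,
    "CARCI": 40,
    "ADC": 40,
    "SCC": 40,
}

#: Expected terminal panel label for each true subtype.
FINAL_LABEL_BY_SUBTYPE: dict[str, str] = {
    "SCLC": "SCLC",
    "LCNEC": "LCNEC",
    "CARCI": "CARCI",
    "ADC": "non-NE",
    "SCC": "non-NE",
}

_FIVE = ("SCLC", "LCNEC", "CARCI", "ADC", "SCC")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``samples_per_group`` maps group label → sample count.  With the five
    canonical subtype labels, three hierarchy steps are planted (NE vs
    non-NE, CARCI vs non-CARCI within NE, SCLC vs LCNEC); with exactly two
    labels, a single step is planted and the *first* label is the positive
    group.  ``effect_size`` is the per-gene mean shift in units of
    ``noise_sd``; planted pairs use disjoint genes across all steps.
    """

    n_genes: int = 300
    samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_SIZES)
    )
    n_planted_pairs: int = 15
    effect_size: float = 3.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    dropout_rate: float = 0.0
    label_corruption_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        groups = dict(self.samples_per_group)
        if len(groups) not in (2, 5):
            raise ValidationError("samples_per_group must have 2 or 5 groups")
        if len(groups) == 5 and set(groups) != set(_FIVE):
            raise ValidationError(f"five-group mode requires labels {_FIVE}")
        if any(n < 1 for n in groups.values()):
            raise ValidationError("every group needs >=1 sample")
        for name in ("dropout_rate", "label_corruption_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        n_steps = 3 if len(groups) == 5 else 1
        needed = 2 * self.n_planted_pairs * n_steps
        if needed > self.n_genes:
            raise ValidationError(
                f"planted pairs need {needed} genes but n_genes={self.n_genes}"
            )

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_group.values())


@dataclass(frozen=True)
class PlantedTruth:
    """Exact ground truth of one simulated dataset."""

    planted_pairs: dict  # step name -> tuple[GenePair, ...]
    corrupted_samples: tuple[str, ...]

    def genes_for_step(self, step: str) -> set[str]:
        return {g for p in self.planted_pairs[step] for g in p.genes}

    @property
    def all_planted_genes(self) -> set[str]:
        return {g for pairs in self.planted_pairs.values() for p in pairs for g in p.genes}


@dataclass(frozen=True)
class SyntheticDataset:
    matrix: ExpressionMatrix
    true_labels: LabelTable
    observed_labels: LabelTable
    truth: PlantedTruth
    config: SimulationConfig


def _hierarchy_steps(groups: Sequence[str]) -> list[tuple[str, set, set]]:
    """(step name, positive subtypes, sample universe) per planted step."""
    if len(groups) == 2:
        pos, neg = groups[0], groups[1]
        return [(pos, {pos}, {pos, neg})]
    return [
        ("NE", {"SCLC", "LCNEC", "CARCI"}, set(_FIVE)),
        ("CARCI", {"CARCI"}, {"SCLC", "LCNEC", "CARCI"}),
        ("SCLC", {"SCLC"}, {"SCLC", "LCNEC"}),
    ]


def simulate(config: SimulationConfig = SimulationConfig()) -> SyntheticDataset:
    """Draw one dataset under ``config``; fixed seed ⇒ bit-identical output."""
    rng = np.random.default_rng(config.rng_seed)
    groups = list(config.samples_per_group)
    sizes = dict(config.samples_per_group)

    sample_ids: list[str] = []
    subtype_of: dict[str, str] = {}
    for g in groups:
        for i in range(sizes[g]):
            sid = f"{g}_{i + 1:03d}"
            sample_ids.append(sid)
            subtype_of[sid] = g
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]

    values = rng.normal(
        config.baseline_mean, config.noise_sd, size=(config.n_genes, len(sample_ids))
    )
    col_of = {s: j for j, s in enumerate(sample_ids)}

    steps = _hierarchy_steps(groups)
    shift = config.effect_size * config.noise_sd
    planted: dict[str, tuple[GenePair, ...]] = {}
    next_gene = 0
    for step_name, positive, universe in steps:
        pairs: list[GenePair] = []
        for _ in range(config.n_planted_pairs):
            ia, ib = next_gene, next_gene + 1
            next_gene += 2
            pairs.append(
                GenePair(gene_ids[ia], gene_ids[ib], positive_class=step_name)
            )
            for sid in sample_ids:
                sub = subtype_of[sid]
                if sub not in universe:
                    continue
                j = col_of[sid]
                sign = 1.0 if sub in positive else -1.0
                values[ia, j] += sign * shift
                values[ib, j] -= sign * shift
        planted[step_name] = tuple(pairs)

    if config.dropout_rate > 0:
        mask = rng.random(values.shape) < config.dropout_rate
        values = np.where(mask, np.nan, values)

    true_labels = LabelTable(subtype_of, vocabulary=groups)
    observed = dict(subtype_of)
    corrupted: list[str] = []
    if config.label_corruption_rate > 0:
        flips = rng.random(len(sample_ids)) < config.label_corruption_rate
        for sid, flip in zip(sample_ids, flips):
            if flip:
                others = [g for g in groups if g != subtype_of[sid]]
                observed[sid] = others[int(rng.integers(len(others)))]
                corrupted.append(sid)
    observed_labels = LabelTable(observed, vocabulary=groups)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    )
    return SyntheticDataset(
        matrix=matrix,
        true_labels=true_labels,
        observed_labels=observed_labels,
        truth=PlantedTruth(planted, tuple(corrupted)),
        config=config,
    )


def degrade(
    matrix: ExpressionMatrix, dropout_rate: float, seed: int
) -> ExpressionMatrix:
    """Mask a random fraction of entries as missing (FFPE/biopsy-like loss).

    ``dropout_rate`` must be in ``[0, 1)``; a rate of 1 would erase the
    matrix and is refused.  Same seed ⇒ same mask.
    """
    if not 0 <= dropout_rate < 1:
        raise ValidationError("dropout_rate must be in [0, 1)")
    if dropout_rate == 0:
        return ExpressionMatrix(matrix.data)
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.shape) < dropout_rate
    data = matrix.data.where(~mask, np.nan)
    return ExpressionMatrix(data)


def corrupt_labels(
    labels: LabelTable, n_swaps: int, seed: int
) -> tuple[LabelTable, tuple[str, ...]]:
    """Swap exactly ``n_swaps`` samples' labels to a random other label.

    Used to plant a known number of misdiagnosed samples.  Returns the
    corrupted table and the affected sample ids.
    """
    ids = labels.sample_ids
    if n_swaps > len(ids):
        raise ValidationError("cannot swap more samples than exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n_swaps, replace=False)
    vocab = sorted(labels.vocabulary)
    out = {s: labels[s] for s in ids}
    swapped = []
    for k in sorted(int(c) for c in chosen):
        sid = ids[k]
        others = [v for v in vocab if v != labels[sid]]
        out[sid] = others[int(rng.integers(len(others)))]
        swapped.append(sid)
    return LabelTable(out, vocabulary=labels.vocabulary), tuple(swapped)


def train_test_split(
    dataset: SyntheticDataset, test_fraction: float = 0.5, seed: int = 0
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Stratified split of a simulated dataset into train and test halves.

    Stratifies on the *true* label so both halves keep the subtype
    proportions; the planted-pair truth is shared.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    for subtype in sorted(dataset.true_labels.vocabulary):
        ids = [s for s in dataset.matrix.sample_ids if dataset.true_labels[s] == subtype]
        n_test = int(round(test_fraction * len(ids)))
        picked = rng.choice(len(ids), size=n_test, replace=False)
        test_ids.extend(ids[int(i)] for i in sorted(picked))
    test_set = set(test_ids)
    train_ids = [s for s in dataset.matrix.sample_ids if s not in test_set]

    def _subset(ids: list[str]) -> SyntheticDataset:
        return SyntheticDataset(
            matrix=dataset.matrix.subset_samples(ids),
            true_labels=dataset.true_labels.subset(ids),
            observed_labels=dataset.observed_labels.subset(ids),
            truth=PlantedTruth(
                dataset.truth.planted_pairs,
                tuple(s for s in dataset.truth.corrupted_samples if s in set(ids)),
            ),
            config=dataset.config,
        )

    return _subset(train_ids), _subset(test_ids)
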