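"""Within-sample REO classification: pair votes, majority calls, panel routing.

Each gene pair casts one vote per sample by comparing the two genes' expression
values *within that sample*: ``E(gene_a) > E(gene_b)`` (pattern GT) votes for
the signature's positive class, ``E(gene_a) <= E(gene_b)`` (pattern LE,
including exact ties) votes for the negative class.  Pairs touching a missing
or absent gene are removed from the tally and the majority rule runs over the
remaining evaluable pairs — this is what makes the classifier usable on
degraded FFPE and low-input biopsy profiles.

Decision rules, stated once and applied everywhere:

* a positive call requires a *strict* majority (more than half) of evaluable
  pairs; an exact 50/50 split calls the negative class and flags the result as
  borderline;
* zero evaluable pairs yields an explicit ABSTAIN, never a default class;
* panel routing follows the signature chain until a terminal label; an ABSTAIN
  at any step terminates with the UNDETERMINED label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    ExpressionMatrix,
    GenePair,
    LabelTable,
    Panel,
    Signature,
    UNDETERMINED,
    ValidationError,
)

__all__ = [
    "Pattern",
    "ABSTAIN",
    "PairVote",
    "VoteResult",
    "ClassificationResult",
    "AccuracyStats",
    "evaluate_pair",
    "score_signature",
    "classify_sample",
    "classify_matrix",
    "evaluate_predictions",
    "results_to_frame",
]

#: Sentinel call when no pair of a signature could be evaluated.
ABSTAIN = "ABSTAIN"

#: Fraction of a signature's pairs that must be evaluable before the result
#: is considered well-supported; below it a low-coverage flag is attached.
DEFAULT_MIN_EVALUABLE_FRACTION = 0.5


class Pattern(enum.Enum):
    """REO pattern of one gene pair in one sample."""

    GT = "GT"  # E(gene_a) >  E(gene_b)
    LE = "LE"  # E(gene_a) <= E(gene_b), ties included
    MISSING = "MISSING"  # either gene absent or its value undetected


@dataclass(frozen=True)
class PairVote:
    pair: GenePair
    pattern: Pattern


@dataclass(frozen=True)
class VoteResult:
    """Majority-vote outcome of one signature on one sample."""

    signature_name: str
    positive_label: str
    negative_label: str
    votes_for: int
    votes_against: int
    n_missing: int
    call: str
    flags: tuple[str, ...] = ()

    @property
    def n_evaluable(self) -> int:
        return self.votes_for + self.votes_against


@dataclass(frozen=True)
class ClassificationResult:
    """Final panel label for one sample plus the per-step vote trail."""

    sample_id: str
    final_label: str
    step_results: tuple[VoteResult, ...]

    @property
    def flags(self) -> tuple[str, ...]:
        out: list[str] = []
        for step in self.step_results:
            out.extend(f"{step.signature_name}:{f}" for f in step.flags)
        return tuple(out)


def evaluate_pair(sample_values: Mapping[str, float], pair: GenePair) -> PairVote:
    """REO pattern of ``pair`` in one sample (a total function, never raises).

    GT iff both genes have detected values and ``value(gene_a) > value(gene_b)``;
    ties fall into the LE branch by the exhaustive dichotomy GT / LE; any
    absent or undetected value yields MISSING.
    """
    try:
        va = sample_values[pair.gene_a]
        vb = sample_values[pair.gene_b]
    except KeyError:
        return PairVote(pair, Pattern.MISSING)
    if pd.isna(va) or pd.isna(vb):
        return PairVote(pair, Pattern.MISSING)
    return PairVote(pair, Pattern.GT if va > vb else Pattern.LE)


def score_signature(
    sample_values: Mapping[str, float],
    signature: Signature,
    min_evaluable_fraction: float = DEFAULT_MIN_EVALUABLE_FRACTION,
) -> VoteResult:
    """Majority vote of a signature's pairs on one sample.

    The call is the positive label iff strictly more than half of the
    evaluable pairs show GT.  An exact split calls the negative label with a
    ``borderline-vote`` flag.  If no pair is evaluable the call is ABSTAIN
    (flag ``no-evaluable-pairs``); if fewer than ``min_evaluable_fraction`` of
    the signature's pairs are evaluable a ``low-evaluable`` flag is attached.
    """
    votes_for = votes_against = n_missing = 0
    for pair in signature.pairs:
        pattern = evaluate_pair(sample_values, pair).pattern
        if pattern is Pattern.GT:
            votes_for += 1
        elif pattern is Pattern.LE:
            votes_against += 1
        else:
            n_missing += 1
    n_evaluable = votes_for + votes_against
    flags: list[str] = []
    if n_evaluable == 0:
        call = ABSTAIN
        flags.append("no-evaluable-pairs")
    else:
        if votes_for > n_evaluable / 2:
            call = signature.positive_label
        else:
            call = signature.negative_label
            if votes_for * 2 == n_evaluable:
                flags.append("borderline-vote")
        if n_evaluable < min_evaluable_fraction * len(signature):
            flags.append("low-evaluable")
    return VoteResult(
        signature_name=signature.name,
        positive_label=signature.positive_label,
        negative_label=signature.negative_label,
        votes_for=votes_for,
        votes_against=votes_against,
        n_missing=n_missing,
        call=call,
        flags=tuple(flags),
    )


def classify_sample(
    sample_values: Mapping[str, float],
    panel: Panel,
    sample_id: str = "sample",
    min_evaluable_fraction: float = DEFAULT_MIN_EVALUABLE_FRACTION,
) -> ClassificationResult:
    """Walk the panel's decision tree for one sample.

    Evaluates the root signature, then follows the positive/negative route to
    either a terminal label or the next signature.  An ABSTAIN at any step
    stops with final label UNDETERMINED and the abstaining step recorded.
    """
    step = panel.steps[0]
    trail: list[VoteResult] = []
    while True:
        result = score_signature(sample_values, step.signature, min_evaluable_fraction)
        trail.append(result)
        if result.call == ABSTAIN:
            return ClassificationResult(sample_id, UNDETERMINED, tuple(trail))
        route = (
            step.on_positive
            if result.call == step.signature.positive_label
            else step.on_negative
        )
        kind, target = route
        if kind == "label":
            return ClassificationResult(sample_id, target, tuple(trail))
        step = panel.step_named(target)


def classify_matrix(
    matrix: ExpressionMatrix,
    panel: Panel,
    min_evaluable_fraction: float = DEFAULT_MIN_EVALUABLE_FRACTION,
) -> list[ClassificationResult]:
    """Classify every sample of a matrix independently (batch = map).

    The result for sample *i* depends only on column *i*; sample order is
    preserved.
    """
    # restrict the row lookup to panel genes once, for speed on large matrices
    panel_genes = {g for s in panel.steps for g in s.signature.genes}
    present = [g for g in matrix.gene_ids if g in panel_genes]
    sub = matrix.data.loc[present] if present else matrix.data.iloc[:0]
    out: list[ClassificationResult] = []
    for sample_id in matrix.sample_ids:
        values = sub[sample_id].to_dict()
        out.append(
            classify_sample(values, panel, sample_id, min_evaluable_fraction)
        )
    return out


@dataclass(frozen=True)
class AccuracyStats:
    """Apparent concordance of predictions with (imperfect) reference labels.

    All three statistics are ``S / N × 100`` over a sample stratum: accuracy
    over every labelled sample, sensitivity over reference-positive samples,
    specificity over reference-negative samples.  ``None`` marks an empty
    stratum (undefined, not zero).  UNDETERMINED predictions count as
    incorrect.
    """

    n_total: int
    n_correct: int
    n_positive: int
    n_correct_positive: int
    n_negative: int
    n_correct_negative: int

    @staticmethod
    def _pct(s: int, n: int) -> float | None:
        return None if n == 0 else s / n * 100.0

    @property
    def accuracy(self) -> float | None:
        return self._pct(self.n_correct, self.n_total)

    @property
    def sensitivity(self) -> float | None:
        return self._pct(self.n_correct_positive, self.n_positive)

    @property
    def specificity(self) -> float | None:
        return self._pct(self.n_correct_negative, self.n_negative)


def _predictions_mapping(
    results: Iterable[ClassificationResult] | Mapping[str, str],
) -> dict[str, str]:
    if isinstance(results, Mapping):
        return {str(k): str(v) for k, v in results.items()}
    return {r.sample_id: r.final_label for r in results}


def evaluate_predictions(
    results: Iterable[ClassificationResult] | Mapping[str, str],
    labels: LabelTable,
    positive_labels: str | Iterable[str],
) -> AccuracyStats:
    """Apparent accuracy / sensitivity / specificity of predictions.

    ``labels`` must use the same vocabulary as the predicted labels (coarsen
    with :meth:`LabelTable.relabel` first if needed).  A prediction is correct
    iff it equals the reference label exactly; the positive stratum is the set
    of samples whose *reference* label is in ``positive_labels``.
    """
    preds = _predictions_mapping(results)
    if not preds:
        raise ValidationError("no predictions to evaluate")
    labels.require_samples(preds)
    if isinstance(positive_labels, str):
        positive_labels = {positive_labels}
    else:
        positive_labels = set(positive_labels)
    n_total = n_correct = n_pos = n_pos_ok = n_neg = n_neg_ok = 0
    for sample_id, predicted in preds.items():
        truth = labels[sample_id]
        ok = predicted == truth
        n_total += 1
        n_correct += ok
        if truth in positive_labels:
            n_pos += 1
            n_pos_ok += ok
        else:
            n_neg += 1
            n_neg_ok += ok
    return AccuracyStats(n_total, n_correct, n_pos, n_pos_ok, n_neg, n_neg_ok)


def results_to_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Flatten classification results into a tidy per-sample table."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "sample_id": r.sample_id,
            "final_label": r.final_label,
            "flags": ";".join(r.flags),
        }
        for step in r.step_results:
            row[f"{step.signature_name}.votes_for"] = step.votes_for
            row[f"{step.signature_name}.n_evaluable"] = step.n_evaluable
            row[f"{step.signature_name}.call"] = step.call
        rows.append(row)
    return pd.DataFrame(rows)
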