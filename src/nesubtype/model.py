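"""Core domain types for within-sample relative expression ordering (REO) analysis.

The central object is an :class:`ExpressionMatrix` — a genes × samples table of
expression values on *any* monotone-consistent within-sample scale (log2
microarray intensity, TPM, counts).  Every downstream computation in this
package uses only the ordering of values *within* a sample, never the values
themselves, so no normalisation assumptions are attached to the matrix.

A :class:`GenePair` encodes the convention that observing
``expression(gene_a) > expression(gene_b)`` in a sample is a vote *for* the
pair's positive class.  A :class:`Signature` is a de-redundant set of such
pairs (no gene occurs twice) with declared positive/negative labels, and a
:class:`Panel` chains binary signatures into a decision tree whose leaves are
terminal subtype labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NesubtypeError",
    "FormatError",
    "ValidationError",
    "ResourceIntegrityError",
    "ExpressionMatrix",
    "GenePair",
    "Signature",
    "PanelStep",
    "Panel",
    "LabelTable",
    "UNDETERMINED",
]

#: Sentinel final label for samples on which a panel step could not vote
#: (all pairs unevaluable).  Deliberately not a subtype name.
UNDETERMINED = "UNDETERMINED"


class NesubtypeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NesubtypeError):
    """Malformed input table (wrong shape, no samples, no genes...)."""


class ValidationError(NesubtypeError):
    """Semantically invalid object (degenerate pair, duplicated gene...)."""


class ResourceIntegrityError(NesubtypeError):
    """The packaged panel resource failed its self-check."""


@dataclass(frozen=True)
class GenePair:
    """An ordered gene pair; ``E(gene_a) > E(gene_b)`` votes for ``positive_class``.

    Gene identifiers are strings (canonically Entrez IDs); an optional symbol
    alias may accompany each for readability, but identity is decided on the
    primary identifier only.
    """

    gene_a: str
    gene_b: str
    positive_class: str | None = None
    symbol_a: str | None = None
    symbol_b: str | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(
                f"degenerate gene pair: gene_a == gene_b == {self.gene_a!r}"
            )

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    def flipped(self, positive_class: str | None = None) -> "GenePair":
        """The reversed ordering convention (gene_b > gene_a votes positive)."""
        return GenePair(
            gene_a=self.gene_b,
            gene_b=self.gene_a,
            positive_class=self.positive_class if positive_class is None else positive_class,
            symbol_a=self.symbol_b,
            symbol_b=self.symbol_a,
        )


@dataclass(frozen=True)
class Signature:
    """A named, de-redundant collection of gene pairs for one binary decision.

    Invariants enforced at construction: at least one pair, and every gene
    participates in at most one pair (the de-redundancy contract that makes the
    majority vote robust to single-gene dropout).
    """

    name: str
    pairs: tuple[GenePair, ...]
    positive_label: str
    negative_label: str

    def __init__(
        self,
        name: str,
        pairs: Iterable[GenePair],
        positive_label: str,
        negative_label: str,
    ) -> None:
        pairs = tuple(pairs)
        if not pairs:
            raise ValidationError(f"signature {name!r} has no gene pairs")
        seen: set[str] = set()
        for p in pairs:
            for g in p.genes:
                if g in seen:
                    raise ValidationError(
                        f"signature {name!r}: gene {g!r} occurs in more than one pair"
                    )
                seen.add(g)
        if positive_label == negative_label:
            raise ValidationError("positive and negative labels must differ")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "positive_label", positive_label)
        object.__setattr__(self, "negative_label", negative_label)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> tuple[str, ...]:
        out: list[str] = []
        for p in self.pairs:
            out.extend(p.genes)
        return tuple(out)


@dataclass(frozen=True)
class PanelStep:
    """One node of the panel decision tree.

    ``on_positive`` / ``on_negative`` are either ``("label", <terminal>)`` or
    ``("step", <signature name>)`` pointing at a later step.
    """

    signature: Signature
    on_positive: tuple[str, str]
    on_negative: tuple[str, str]

    def __post_init__(self) -> None:
        for route in (self.on_positive, self.on_negative):
            if len(route) != 2 or route[0] not in ("label", "step"):
                raise ValidationError(f"invalid route {route!r}")


@dataclass(frozen=True)
class Panel:
    """An ordered hierarchy of signatures; routing must form a tree.

    The first step is the root.  Each ``("step", name)`` route must point at a
    step that occurs later in ``steps`` and is referenced exactly once, so the
    routing cannot form cycles and every leaf carries one terminal label.
    """

    name: str
    steps: tuple[PanelStep, ...]

    def __init__(self, name: str, steps: Iterable[PanelStep]) -> None:
        steps = tuple(steps)
        if not steps:
            raise ValidationError("panel has no steps")
        names = [s.signature.name for s in steps]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate signature names in panel")
        referenced: list[str] = []
        for i, step in enumerate(steps):
            for kind, target in (step.on_positive, step.on_negative):
                if kind == "step":
                    if target not in names[i + 1 :]:
                        raise ValidationError(
                            f"step {step.signature.name!r} routes to {target!r}, "
                            "which is not a later step"
                        )
                    referenced.append(target)
        if len(set(referenced)) != len(referenced):
            raise ValidationError("a panel step is referenced by more than one route")
        for name_ in names[1:]:
            if name_ not in referenced:
                raise ValidationError(f"unreachable panel step {name_!r}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "steps", steps)

    def step_named(self, name: str) -> PanelStep:
        for s in self.steps:
            if s.signature.name == name:
                return s
        raise KeyError(name)

    @property
    def terminal_labels(self) -> tuple[str, ...]:
        out: list[str] = []
        for step in self.steps:
            for kind, target in (step.on_positive, step.on_negative):
                if kind == "label" and target not in out:
                    out.append(target)
        return tuple(out)


class ExpressionMatrix:
    """A genes × samples expression table with explicit missing values.

    Thin wrapper around a float :class:`pandas.DataFrame` (rows = gene IDs,
    columns = sample IDs) that enforces unique gene and sample identifiers.
    ``NaN`` entries denote undetected expression and are first-class: the
    classifier removes pairs touching them rather than imputing.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise FormatError("expression matrix must have >=1 gene and >=1 sample")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids (collapse first): {dups[:5]}")
        if data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        data = data.copy()
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        self._data = data.astype(float)

    # -- basic introspection -------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._data.index

    # -- access --------------------------------------------------------------
    def sample_values(self, sample_id: str) -> pd.Series:
        """Expression values of one sample, indexed by gene id (NaN = missing)."""
        return self._data[sample_id]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self._data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._data[list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        if self.shape != other.shape:
            return False
        if self.gene_ids != other.gene_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self._data.to_numpy(), other._data.to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        return bool(np.all((a == b) | both_nan))


class LabelTable:
    """Mapping sample id → subtype label with a declared label vocabulary."""

    def __init__(
        self,
        labels: Mapping[str, str] | pd.Series,
        vocabulary: Iterable[str] | None = None,
    ) -> None:
        if isinstance(labels, pd.Series):
            labels = labels.to_dict()
        self._labels = {str(k): str(v) for k, v in labels.items()}
        if not self._labels:
            raise ValidationError("empty label table")
        vocab = set(vocabulary) if vocabulary is not None else set(self._labels.values())
        bad = sorted(set(self._labels.values()) - vocab)
        if bad:
            raise ValidationError(f"labels outside declared vocabulary: {bad}")
        self._vocabulary = frozenset(vocab)

    @property
    def vocabulary(self) -> frozenset[str]:
        return self._vocabulary

    @property
    def sample_ids(self) -> list[str]:
        return list(self._labels)

    def __getitem__(self, sample_id: str) -> str:
        return self._labels[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def items(self):
        return self._labels.items()

    def as_series(self) -> pd.Series:
        return pd.Series(self._labels, dtype=object)

    def subset(self, sample_ids: Sequence[str]) -> "LabelTable":
        return LabelTable(
            {s: self._labels[s] for s in sample_ids}, vocabulary=self._vocabulary
        )

    def relabel(self, mapping: Mapping[str, str]) -> "LabelTable":
        """Coarsen labels, e.g. {'ADC': 'non-NE', 'SCC': 'non-NE', ...}."""
        new = {s: mapping.get(l, l) for s, l in self._labels.items()}
        return LabelTable(new)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self._labels]
        if missing:
            raise ValidationError(f"samples missing from label table: {missing[:5]}")
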