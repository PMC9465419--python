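"""Readers and writers for expression matrices, signatures and panels.

Expression input is delimited text (TSV/CSV, optionally gzipped) with genes as
rows and samples as columns — the series-matrix convention.  Signatures travel
as small TSV files, panels as JSON; the 92-pair lung neuroendocrine subtyping
panel ships with the package as a JSON resource and is loaded with
:func:`load_builtin_panel`.
"""

from __future__ import annotations

import json
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .model import (
    ExpressionMatrix,
    FormatError,
    GenePair,
    LabelTable,
    Panel,
    PanelStep,
    ResourceIntegrityError,
    Signature,
    ValidationError,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_label_table",
    "write_label_table",
    "read_signature_file",
    "write_signature_file",
    "read_panel_json",
    "write_panel_json",
    "load_builtin_panel",
    "BUILTIN_PANEL_RESOURCE",
]

BUILTIN_PANEL_RESOURCE = "nesubtype_panel.json"

#: Expected pair counts of the packaged panel, keyed by signature name.
_BUILTIN_PAIR_COUNTS = {"NE-signature": 22, "CARCI-signature": 30, "SCLC-signature": 40}


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_expression_matrix(
    path: str | Path,
    id_column: str | int = 0,
    id_type: str = "entrez",
    duplicate_policy: str = "mean",
) -> ExpressionMatrix:
    """Read a genes × samples delimited text file into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    path
        TSV/CSV file (``.gz`` accepted); genes are rows, samples columns.
    id_column
        Name or position of the gene-identifier column (default: first).
    id_type
        ``"entrez"`` or ``"symbol"`` — recorded convention only; identifiers
        are treated as opaque strings either way.
    duplicate_policy
        How to collapse rows sharing a gene id after probe → gene mapping.
        ``"mean"`` (default) averages per sample; ``"error"`` refuses.

    Non-numeric cells (``NA``, empty, ...) become explicit missing values.
    """
    if id_type not in ("entrez", "symbol"):
        raise ValueError(f"id_type must be 'entrez' or 'symbol', got {id_type!r}")
    if duplicate_policy not in ("mean", "error"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    try:
        raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot read expression table {path}: {exc}") from exc
    if raw.shape[0] == 0:
        raise FormatError(f"{path}: no gene rows")
    if isinstance(id_column, int):
        try:
            id_name = raw.columns[id_column]
        except IndexError as exc:
            raise FormatError(f"{path}: no column at position {id_column}") from exc
    else:
        if id_column not in raw.columns:
            raise FormatError(f"{path}: id column {id_column!r} not found")
        id_name = id_column
    ids = raw[id_name].astype(str).str.strip()
    values = raw.drop(columns=[id_name])
    if values.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    values = values.apply(pd.to_numeric, errors="coerce")
    values.index = ids

    if values.index.has_duplicates:
        if duplicate_policy == "error":
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"{path}: duplicate gene ids {dups[:5]}")
        # mean-collapse preserves row order of first occurrence
        order = values.index.drop_duplicates()
        values = values.groupby(level=0, sort=False).mean().loc[order]
    if values.shape[0] < 2:
        raise FormatError(f"{path}: fewer than 2 genes after duplicate collapse")
    return ExpressionMatrix(values)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, id_column: str = "gene_id"
) -> None:
    df = matrix.data.copy()
    df.index.name = id_column
    df.to_csv(path, sep=_sep_for(path), na_rep="NA")


def read_label_table(
    path: str | Path, vocabulary: Iterable[str] | None = None
) -> LabelTable:
    """Read a two-column (sample_id, label) delimited file."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read label table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns sample_id, label")
    return LabelTable(
        dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))),
        vocabulary=vocabulary,
    )


def write_label_table(labels: LabelTable, path: str | Path) -> None:
    ser = labels.as_series()
    pd.DataFrame({"sample_id": ser.index, "label": ser.values}).to_csv(
        path, sep=_sep_for(path), index=False
    )


# --------------------------------------------------------------------------
# signature TSV
# --------------------------------------------------------------------------

_SIG_COLUMNS = ["gene_a_entrez", "gene_b_entrez", "gene_a_symbol", "gene_b_symbol"]


def write_signature_file(signature: Signature, path: str | Path) -> None:
    """Write a signature as TSV; a ``#`` header line carries name and labels."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# signature={signature.name}\t"
            f"positive_label={signature.positive_label}\t"
            f"negative_label={signature.negative_label}\n"
        )
        fh.write("\t".join(_SIG_COLUMNS) + "\n")
        for p in signature.pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.symbol_a or ''}\t{p.symbol_b or ''}\n"
            )


def read_signature_file(path: str | Path) -> Signature:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing '# signature=...' header line")
        meta: dict[str, str] = {}
        for tok in header.lstrip("#").strip().split("\t"):
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k.strip()] = v.strip()
        for key in ("signature", "positive_label", "negative_label"):
            if key not in meta:
                raise FormatError(f"{path}: header lacks {key}=")
        body = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    if not set(_SIG_COLUMNS[:2]).issubset(body.columns):
        raise FormatError(f"{path}: expected columns {_SIG_COLUMNS[:2]}")
    pairs = [
        GenePair(
            gene_a=row["gene_a_entrez"],
            gene_b=row["gene_b_entrez"],
            positive_class=meta["positive_label"],
            symbol_a=row.get("gene_a_symbol") or None,
            symbol_b=row.get("gene_b_symbol") or None,
        )
        for _, row in body.iterrows()
    ]
    return Signature(
        name=meta["signature"],
        pairs=pairs,
        positive_label=meta["positive_label"],
        negative_label=meta["negative_label"],
    )


# --------------------------------------------------------------------------
# panel JSON
# --------------------------------------------------------------------------


def _signature_from_dict(d: dict) -> Signature:
    pairs = [
        GenePair(
            gene_a=str(p["gene_a"]),
            gene_b=str(p["gene_b"]),
            positive_class=d["positive_label"],
            symbol_a=p.get("symbol_a"),
            symbol_b=p.get("symbol_b"),
        )
        for p in d["pairs"]
    ]
    return Signature(
        name=d["name"],
        pairs=pairs,
        positive_label=d["positive_label"],
        negative_label=d["negative_label"],
    )


def _signature_to_dict(sig: Signature) -> dict:
    return {
        "name": sig.name,
        "positive_label": sig.positive_label,
        "negative_label": sig.negative_label,
        "pairs": [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "symbol_a": p.symbol_a,
                "symbol_b": p.symbol_b,
            }
            for p in sig.pairs
        ],
    }


def panel_from_dict(d: dict) -> Panel:
    steps = [
        PanelStep(
            signature=_signature_from_dict(s["signature"]),
            on_positive=tuple(s["on_positive"]),
            on_negative=tuple(s["on_negative"]),
        )
        for s in d["steps"]
    ]
    return Panel(name=d.get("name", "panel"), steps=steps)


def panel_to_dict(panel: Panel) -> dict:
    return {
        "name": panel.name,
        "steps": [
            {
                "signature": _signature_to_dict(s.signature),
                "on_positive": list(s.on_positive),
                "on_negative": list(s.on_negative),
            }
            for s in panel.steps
        ],
    }


def read_panel_json(path: str | Path) -> Panel:
    with open(path, encoding="utf-8") as fh:
        return panel_from_dict(json.load(fh))


def write_panel_json(panel: Panel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(panel_to_dict(panel), fh, indent=1)
        fh.write("\n")


def load_builtin_panel() -> Panel:
    """Load the packaged 92-pair lung NE subtyping panel.

    Three chained binary signatures: NE vs non-NE (22 pairs), CARCI vs
    non-CARCI (30 pairs), SCLC vs LCNEC (40 pairs); terminal labels are
    non-NE, CARCI, SCLC and LCNEC.  The resource is integrity-checked on
    every load (pair counts, unique genes within each signature).
    """
    ref = _importlib_resources.files("nesubtype.resources") / BUILTIN_PANEL_RESOURCE
    try:
        with ref.open(encoding="utf-8") as fh:
            panel = panel_from_dict(json.load(fh))
    except (ValidationError, KeyError, json.JSONDecodeError) as exc:
        raise ResourceIntegrityError(f"packaged panel is corrupted: {exc}") from exc
    for step in panel.steps:
        expected = _BUILTIN_PAIR_COUNTS.get(step.signature.name)
        if expected is None or len(step.signature) != expected:
            raise ResourceIntegrityError(
                f"packaged panel: {step.signature.name} has {len(step.signature)} "
                f"pairs, expected {expected}"
            )
    return panel
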