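"""TSV/JSON readers and writers for the pipeline's data products.

One dialect throughout: tab-separated, UTF-8, header row, '.' decimal, no
quoting. Writers can prepend '#'-prefixed provenance comments (config hash
and seed); readers skip them. Floats round-trip at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EmptyInputError",
    "DuplicateIDError",
    "NonNumericError",
    "MissingSampleError",
    "read_expression_tsv",
    "read_detection_tsv",
    "read_design_tsv",
    "write_matrix_tsv",
    "write_design_tsv",
    "write_truth_json",
    "read_truth_json",
]


class EmptyInputError(ValueError):
    """The input file is empty or has no data rows."""


class DuplicateIDError(ValueError):
    """Gene or sample identifiers are not unique."""


class NonNumericError(ValueError):
    """A matrix body cell could not be parsed as a finite number."""


class MissingSampleError(ValueError):
    """An expression sample is absent from the design table."""


def _provenance_header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"empty input file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty input file: {path}") from exc
    if df.empty and len(df.columns) == 0:
        raise EmptyInputError(f"no data rows in {path}")
    return df


def _validate_matrix(df: pd.DataFrame, path) -> pd.DataFrame:
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise DuplicateIDError(f"duplicate gene IDs in {path}: {dupes}")
    if pd.Index(df.columns).duplicated().any():
        raise DuplicateIDError(f"duplicate sample IDs in {path}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise NonNumericError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.isfinite(values.to_numpy()).all():
        raise NonNumericError(f"non-finite value in {path}")
    values.index.name = "gene_id"
    return values


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 expression matrix."""
    return _validate_matrix(_read_tsv(path), path)


def read_detection_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples detection P-value matrix (values in [0, 1])."""
    df = _validate_matrix(_read_tsv(path), path)
    vals = df.to_numpy()
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError(f"detection P-values outside [0, 1] in {path}")
    return df


def read_design_tsv(
    path: str | Path, expression: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read a sample annotation table (sample_id, group[, trait]).

    When ``expression`` is given, every expression sample must be annotated
    (raises :class:`MissingSampleError` naming the offender). A missing
    trait column is derived from the group labels (1 for exercise and
    fluoxetine, 0 otherwise).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"empty input file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise EmptyInputError(f"no data rows in {path}")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"design table {path} lacks column '{col}'")
    if df["sample_id"].duplicated().any():
        raise DuplicateIDError(f"duplicate sample IDs in design {path}")
    if "trait" not in df.columns:
        from .config import TRAIT_OF_GROUP

        df["trait"] = df["group"].map(lambda g: TRAIT_OF_GROUP.get(g, 0)).astype(int)
    if expression is not None:
        missing = set(expression.columns) - set(df["sample_id"])
        if missing:
            raise MissingSampleError(
                f"sample(s) missing from design: {sorted(missing)}"
            )
    return df


def write_matrix_tsv(
    df: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(provenance))
        df.to_csv(fh, sep="\t", lineterminator="\n")


def write_design_tsv(
    design: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(provenance))
        design.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_truth_json(truth, path: str | Path, provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = truth.to_dict()
    if provenance:
        payload["_provenance"] = provenance
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
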