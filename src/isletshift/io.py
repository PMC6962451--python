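"""Reading, writing and validation of abundance matrices and sample annotations.

The on-disk formats are plain delimited text:

* abundance matrix — first column ``protein_id``, remaining columns one per
  sample, strictly positive linear-scale values, missing cells empty or equal
  to a missing token (default ``NA``);
* sample annotation — columns ``sample_id``, ``condition``, ``replicate``,
  where condition is one of the five study groups;
* result tables — TSV or a JSON array of records, round-trippable exactly.

The delimiter is chosen by extension (``.tsv`` → tab, ``.csv`` → comma); no
sniffing. All values are consumed on the linear scale; log2 transformation
happens exactly once, downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    ParseError,
    StructuralError,
    ValidationError,
    VocabularyError,
)

#: The five condition groups of the encapsulated-differentiation design.
#: S5/S7 are 2D-culture differentiation stages, the *_bead conditions their
#: alginate-encapsulated counterparts, ISLET the native human islet reference.
CONDITIONS: tuple[str, ...] = ("S5", "S7", "S5_bead", "S7_bead", "ISLET")

#: Condition used as the abundance reference in every anchored contrast.
REFERENCE_CONDITION = "ISLET"

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _delimiter_for(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".tsv":
        return "\t"
    if suffix == ".csv":
        return ","
    raise ParseError(f"unsupported extension {suffix!r} for {path}; use .tsv or .csv")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbundanceMatrix:
    """Proteins x samples table of strictly positive abundances.

    ``data`` is a float DataFrame indexed by protein id with one column per
    sample; missing observations are NaN. Order of rows and columns is
    preserved from the source — no silent reordering.
    """

    data: pd.DataFrame

    def __post_init__(self):
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise StructuralError(f"duplicate protein id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise StructuralError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy(dtype=float)
        bad = ~np.isnan(values) & ~(np.isfinite(values) & (values > 0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"abundance must be finite and > 0; got {values[i, j]!r} "
                f"at protein {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def log2(self) -> pd.DataFrame:
        """Log2-transformed values (NaN preserved). The single log step."""
        return np.log2(self.data)


@dataclass(frozen=True)
class SampleAnnotation:
    """Sample → (condition, replicate) mapping for the five-group design."""

    entries: pd.DataFrame  # columns: sample_id, condition, replicate

    def __post_init__(self):
        df = self.entries
        required = {"sample_id", "condition", "replicate"}
        if not required.issubset(df.columns):
            raise StructuralError(
                f"annotation needs columns {sorted(required)}, got {list(df.columns)}"
            )
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise StructuralError(f"duplicate sample id {dup!r}")
        unknown = set(df["condition"]) - set(CONDITIONS)
        if unknown:
            raise VocabularyError(
                f"unknown condition(s) {sorted(unknown)}; expected one of {CONDITIONS}"
            )
        reps = df["replicate"]
        if not ((reps.astype(float) == reps.astype(float).round()) & (reps.astype(float) >= 1)).all():
            raise ValidationError("replicate indices must be positive integers")
        counts = df["condition"].value_counts()
        thin = counts[counts < 2]
        if not thin.empty:
            raise ValidationError(
                f"every condition used needs >= 2 samples; got {thin.to_dict()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries["sample_id"])

    @property
    def conditions_present(self) -> list[str]:
        present = set(self.entries["condition"])
        return [c for c in CONDITIONS if c in present]

    def samples_for(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise VocabularyError(f"unknown condition {condition!r}")
        sel = self.entries.loc[self.entries["condition"] == condition, "sample_id"]
        return list(sel)

    def check_covers(self, matrix: AbundanceMatrix) -> None:
        """Require the annotation to describe every matrix sample."""
        missing = set(matrix.sample_ids) - set(self.sample_ids)
        if missing:
            raise ConsistencyError(
                f"samples absent from annotation: {sorted(missing)}"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_abundance_matrix(path: str | Path, missing_token: str = "NA") -> AbundanceMatrix:
    """Read a proteins x samples abundance table.

    Empty cells and cells equal to ``missing_token`` are recorded as missing;
    any other non-numeric cell raises :class:`ParseError` naming its position,
    and any value <= 0 raises :class:`ValidationError`.
    """
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise StructuralError(f"duplicate sample id {sid!r} in header")
        seen.add(sid)
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
    raw.columns = sample_ids  # undo pandas' mangling of duplicate headers
    cleaned = raw.replace({missing_token: np.nan, "": np.nan})
    probe = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna() & cleaned.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {raw.iat[i, j]!r} at protein {raw.index[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    # astype(float) round-trips %.17g exactly (pandas' fast parser does not)
    return AbundanceMatrix(cleaned.astype(float))


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample annotation table (columns sample_id, condition, replicate)."""
    path = Path(path)
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "condition": str})
    return SampleAnnotation(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_abundance_matrix(
    matrix: AbundanceMatrix, path: str | Path, missing_token: str = "NA"
) -> None:
    path = Path(path)
    sep = _delimiter_for(path)
    matrix.data.to_csv(
        path, sep=sep, index_label="protein_id", na_rep=missing_token,
        float_format=_FLOAT_FMT,
    )


def write_sample_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    path = Path(path)
    sep = _delimiter_for(path)
    annotation.entries.to_csv(path, sep=sep, index=False)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = list(records)
    if rows and hasattr(rows[0], "__dataclass_fields__"):
        from dataclasses import asdict

        rows = [asdict(r) for r in rows]
    return pd.DataFrame(rows)


def write_results(records, path: str | Path, format: str = "tsv") -> None:
    """Write a result collection as TSV or a JSON array of objects.

    A subsequent :func:`read_results` reproduces the records exactly
    (floats are serialized with 17 significant digits).
    """
    path = Path(path)
    frame = _as_frame(records)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)
    elif format == "json":
        def _clean(v):
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating, float)):
                v = float(v)
                return None if math.isnan(v) else v
            if isinstance(v, (np.bool_, bool)):
                return bool(v)
            return v

        payload = [
            {k: _clean(v) for k, v in row.items()}
            for row in frame.to_dict(orient="records")
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise VocabularyError(f"unknown result format {format!r}; use 'tsv' or 'json'")


def read_results(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "tsv":
        return pd.read_csv(
            path, sep="\t", na_values=["NA"], keep_default_na=False,
            float_precision="round_trip",
        )
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise VocabularyError(f"unknown result format {format!r}")
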