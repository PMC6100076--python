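"""Reading and writing artifact data: molecule tables, descriptor
matrices, predictions, and persisted models.

Tables are delimited text, comma by default with tab accepted; the
missing-value marker is "NA" (empty cells also count as missing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

__all__ = [
    "MoleculeRecord",
    "ValidationError",
    "ModelPersistenceError",
    "read_molecule_table",
    "write_molecule_table",
    "read_descriptor_table",
    "write_descriptor_table",
    "persist_model",
    "load_model",
    "write_predictions",
]

MISSING_MARKERS = ("NA", "")
SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """Input table violates a structural invariant."""


class ModelPersistenceError(RuntimeError):
    """Persisted model bundle is unreadable or incompatible."""


@dataclass
class MoleculeRecord:
    """One compound: identifier, optional structure, and response.

    ``er`` is the monolayer efflux ratio Papp(B->A)/Papp(A->B); ``log_er``
    its base-10 logarithm, the modeling response.  ER is consumed as
    given, never derived from permeabilities here.
    """

    id: str
    log_er: float
    er: float | None = None
    smiles: str | None = None
    cas: str | None = None

    def __post_init__(self) -> None:
        if self.er is not None:
            if self.er <= 0:
                raise ValidationError(f"molecule {self.id!r}: er must be > 0, got {self.er}")
            if abs(self.log_er - math.log10(self.er)) > 1e-9:
                raise ValidationError(
                    f"molecule {self.id!r}: log_er {self.log_er} inconsistent with "
                    f"log10(er) = {math.log10(self.er)}"
                )


def _read_delimited(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    return pd.read_csv(
        path, sep=sep, na_values=list(MISSING_MARKERS), keep_default_na=False, dtype=str
    )


def read_molecule_table(
    path: str | Path, sep: str | None = None, aggregate_duplicates: bool = False
) -> list[MoleculeRecord]:
    """Read a molecule table (columns: id, optionally smiles/cas, er and/or
    log_er) into records in file order.

    When both ``er`` and ``log_er`` are present they must agree; when only
    one is given the other is derived.  Duplicate ids raise a
    :class:`ValidationError` naming the offending ids unless
    ``aggregate_duplicates`` is set, in which case replicate measurements
    sharing an id are averaged on the ER scale.
    """
    df = _read_delimited(path, sep)
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols:
        raise ValidationError("molecule table must have an 'id' column")
    if "er" not in cols and "log_er" not in cols:
        raise ValidationError("molecule table needs at least one of 'er', 'log_er'")

    ids = df[cols["id"]].astype(str)
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes and not aggregate_duplicates:
        raise ValidationError(f"duplicate molecule id(s): {dupes}")

    def parse_float(raw, row: int, col: str) -> float | None:
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise ValidationError(f"row {row}: non-numeric {col!r} value {raw!r}") from None

    records: list[MoleculeRecord] = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=1):
        rid = str(row[cols["id"]])
        er = parse_float(row[cols["er"]], row_no, "er") if "er" in cols else None
        log_er = parse_float(row[cols["log_er"]], row_no, "log_er") if "log_er" in cols else None
        if er is not None and er <= 0:
            raise ValidationError(f"row {row_no} (id {rid!r}): er must be > 0, got {er}")
        if log_er is None:
            if er is None:
                raise ValidationError(f"row {row_no} (id {rid!r}): er and log_er both missing")
            log_er = math.log10(er)
        records.append(
            MoleculeRecord(
                id=rid,
                log_er=log_er,
                er=er,
                smiles=str(row[cols["smiles"]]) if "smiles" in cols and pd.notna(row[cols["smiles"]]) else None,
                cas=str(row[cols["cas"]]) if "cas" in cols and pd.notna(row[cols["cas"]]) else None,
            )
        )

    if dupes and aggregate_duplicates:
        merged: dict[str, list[MoleculeRecord]] = {}
        order: list[str] = []
        for rec in records:
            merged.setdefault(rec.id, []).append(rec)
            if rec.id not in order:
                order.append(rec.id)
        out = []
        for rid in order:
            group = merged[rid]
            if len(group) == 1:
                out.append(group[0])
                continue
            ers = [g.er if g.er is not None else 10.0**g.log_er for g in group]
            mean_er = float(np.mean(ers))
            out.append(
                MoleculeRecord(
                    id=rid,
                    er=mean_er,
                    log_er=math.log10(mean_er),
                    smiles=group[0].smiles,
                    cas=group[0].cas,
                )
            )
        return out
    return records


def write_molecule_table(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles if r.smiles is not None else "NA" for r in records],
            "cas": [r.cas if r.cas is not None else "NA" for r in records],
            "er": [repr(r.er) if r.er is not None else "NA" for r in records],
            "log_er": [repr(r.log_er) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_descriptor_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a sample-by-descriptor matrix keyed by the first (id) column.

    "NA" and empty cells are preserved as missing values for the filtering
    stage; any other non-numeric cell raises with its row and column.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    if path.exists():
        # pandas mangles duplicate header names, so check the raw header
        header = path.read_text().splitlines()[0].split(sep)
        seen: set[str] = set()
        dupes = sorted({h for h in header if h in seen or seen.add(h)})
        if dupes:
            raise ValidationError(f"duplicate descriptor name(s) in header: {dupes}")
    df = _read_delimited(path, sep)
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        raise ValidationError(
            f"duplicate sample id(s): {sorted(ids[ids.duplicated()].unique())}"
        )
    out = df.drop(columns=[id_col])
    numeric = pd.DataFrame(index=ids.to_list())
    for col in out.columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = out[col].notna() & converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric cell at row {row + 1}, column {col!r}: {out[col].iloc[row]!r}"
            )
        numeric[col] = converted.to_numpy()
    return numeric


def write_descriptor_table(X: pd.DataFrame, path: str | Path, id_label: str = "id") -> None:
    df = X.copy()
    df.insert(0, id_label, X.index)
    df.to_csv(path, index=False, na_rep="NA")


def write_predictions(
    ids: Sequence[str],
    predicted: Sequence[float],
    path: str | Path,
    observed: Sequence[float] | None = None,
) -> None:
    """Prediction table: id, observed_log_er (if known), predicted_log_er,
    residual."""
    df = pd.DataFrame({"id": list(ids), "predicted_log_er": np.asarray(predicted, float)})
    if observed is not None:
        obs = np.asarray(observed, dtype=float)
        df.insert(1, "observed_log_er", obs)
        df["residual"] = obs - df["predicted_log_er"]
    df.to_csv(path, index=False, na_rep="NA")


def persist_model(model, path: str | Path) -> None:
    """Persist a fitted model bundle (schema-versioned joblib archive)."""
    payload = {"schema_version": SCHEMA_VERSION, "model": model}
    joblib.dump(payload, path)


def load_model(path: str | Path):
    """Load a persisted model; corrupt or version-mismatched archives
    raise :class:`ModelPersistenceError`."""
    try:
        payload = joblib.load(path)
    except Exception as err:  # truncated/corrupt pickle
        raise ModelPersistenceError(f"cannot read model archive {path}: {err}") from err
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ModelPersistenceError(f"{path} is not a model bundle")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise ModelPersistenceError(
            f"schema version mismatch: archive {payload['schema_version']}, "
            f"supported {SCHEMA_VERSION}"
        )
    return payload["model"]
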