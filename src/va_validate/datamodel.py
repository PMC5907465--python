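"""Core data types and CSV readers/writers for verbal-autopsy validation.

A gold-standard VA dataset is a table with one row per death: a record id, an
age module (adult/child/neonate), a study site, a gold-standard cause from a
fixed cause list, and a vector of ternary symptom indicators (yes / no /
missing).  A *probbase* is the cause-by-symptom matrix of conditional
endorsement probabilities P(symptom endorsed | cause) used by probbase-style
classifiers.

On-disk formats (all plain CSV):

* dataset (wide):  ``record_id,module,site,gold_cause,<symptom_1>,...`` with
  symptom cells ``1`` (yes), ``0`` (no) or empty (missing / don't know);
* probbase: first column the cause id, remaining columns one per symptom,
  cells probabilities in [0, 1];
* symptom dictionary: ``symptom_id,hce_flag`` where the flag marks
  health-care-experience (HCE) items, i.e. questions about prior contact with
  health services.

Symptom values are held internally as int8 codes: 1 = yes, 0 = no,
-1 = missing.  Cause and symptom order is the file/construction order and is
authoritative for every matrix; nothing is sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "YES",
    "NO",
    "MISSING",
    "MODULES",
    "CauseList",
    "SymptomDictionary",
    "VADataset",
    "Probbase",
    "PredictionSet",
    "read_dataset",
    "write_dataset",
    "read_probbase",
    "write_probbase",
    "read_symptom_dictionary",
    "write_symptom_dictionary",
    "read_predictions",
    "write_predictions",
    "apply_hce_mask",
]

YES: int = 1
NO: int = 0
MISSING: int = -1

MODULES = ("adult", "child", "neonate")

#: default cause-list sizes by age module (most aggregated PHMRC cause lists)
DEFAULT_CAUSE_COUNTS = {"adult": 34, "child": 21, "neonate": 6}


@dataclass(frozen=True)
class CauseList:
    """Ordered list of cause-of-death identifiers for one age module."""

    module: str
    causes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise ValueError(f"unknown module {self.module!r}; expected one of {MODULES}")
        object.__setattr__(self, "causes", tuple(str(c) for c in self.causes))
        if any(not c for c in self.causes):
            raise ValueError("cause identifiers must be non-empty")
        if len(set(self.causes)) != len(self.causes):
            raise ValueError("cause identifiers must be unique")
        if len(self.causes) < 2:
            raise ValueError("a cause list needs at least 2 causes")

    @property
    def N(self) -> int:
        return len(self.causes)

    def index_of(self, cause: str) -> int:
        try:
            return self.causes.index(cause)
        except ValueError:
            raise KeyError(f"cause {cause!r} is not in the cause list") from None

    def indices_of(self, labels: Sequence[str]) -> np.ndarray:
        """Map cause labels to integer indices, erroring on unknown labels."""
        lookup = {c: i for i, c in enumerate(self.causes)}
        out = np.empty(len(labels), dtype=np.int64)
        for i, lab in enumerate(labels):
            try:
                out[i] = lookup[lab]
            except KeyError:
                raise KeyError(f"cause {lab!r} is not in the cause list") from None
        return out


@dataclass(frozen=True)
class SymptomDictionary:
    """Ordered symptom identifiers with health-care-experience flags."""

    ids: tuple[str, ...]
    hce_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(s) for s in self.ids))
        object.__setattr__(self, "hce_flags", tuple(bool(f) for f in self.hce_flags))
        if len(self.ids) != len(self.hce_flags):
            raise ValueError("ids and hce_flags must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("symptom identifiers must be unique")
        if any(not s for s in self.ids):
            raise ValueError("symptom identifiers must be non-empty")
        if all(self.hce_flags):
            raise ValueError("at least one symptom must be non-HCE")

    @property
    def S(self) -> int:
        return len(self.ids)

    def non_hce_indices(self) -> np.ndarray:
        return np.flatnonzero(~np.asarray(self.hce_flags, dtype=bool))


@dataclass
class VADataset:
    """Gold-standard VA records: causes, sites and ternary symptom vectors.

    ``symptoms`` is an ``(n_records, S)`` int8 array with codes
    ``YES=1 / NO=0 / MISSING=-1``.
    """

    record_ids: np.ndarray
    module: str
    sites: np.ndarray
    gold_causes: np.ndarray
    symptoms: np.ndarray
    cause_list: CauseList
    symptom_dict: SymptomDictionary

    def __post_init__(self) -> None:
        self.record_ids = np.asarray(self.record_ids, dtype=object)
        self.sites = np.asarray(self.sites, dtype=object)
        self.gold_causes = np.asarray(self.gold_causes, dtype=object)
        self.symptoms = np.asarray(self.symptoms, dtype=np.int8)
        n = len(self.record_ids)
        if not (len(self.sites) == len(self.gold_causes) == self.symptoms.shape[0] == n):
            raise ValueError("record_ids, sites, gold_causes and symptoms row counts differ")
        if self.symptoms.ndim != 2 or self.symptoms.shape[1] != self.symptom_dict.S:
            raise ValueError(
                f"symptom matrix has {self.symptoms.shape[1] if self.symptoms.ndim == 2 else '?'}"
                f" columns; symptom dictionary has {self.symptom_dict.S}"
            )
        if len(set(self.record_ids.tolist())) != n:
            raise ValueError("record ids must be unique")
        bad = ~np.isin(self.symptoms, (YES, NO, MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"symptom value {self.symptoms[r, c]} at record {self.record_ids[r]!r},"
                f" symptom {self.symptom_dict.ids[c]!r} is not in {{1, 0, -1}}"
            )
        known = set(self.cause_list.causes)
        for rid, cause in zip(self.record_ids, self.gold_causes):
            if cause not in known:
                raise ValueError(f"record {rid!r} has gold cause {cause!r} not in the cause list")

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    def gold_cause_indices(self) -> np.ndarray:
        return self.cause_list.indices_of(self.gold_causes.tolist())

    def subset(self, indices: Iterable[int]) -> "VADataset":
        """Return the dataset restricted to ``indices`` (must stay unique)."""
        idx = np.asarray(list(indices), dtype=np.int64)
        return VADataset(
            record_ids=self.record_ids[idx],
            module=self.module,
            sites=self.sites[idx],
            gold_causes=self.gold_causes[idx],
            symptoms=self.symptoms[idx],
            cause_list=self.cause_list,
            symptom_dict=self.symptom_dict,
        )


@dataclass
class Probbase:
    """Cause-by-symptom conditional endorsement probability matrix.

    ``provenance`` records whether the matrix was supplied as-is ("fixed") or
    estimated from training data ("trained").  ``zero_train_causes`` flags
    causes that had no training records and received the uninformative 0.5 row.
    """

    values: np.ndarray
    cause_list: CauseList
    symptom_dict: SymptomDictionary
    provenance: str = "fixed"
    zero_train_causes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.provenance not in ("fixed", "trained"):
            raise ValueError("provenance must be 'fixed' or 'trained'")
        expected = (self.cause_list.N, self.symptom_dict.S)
        if self.values.shape != expected:
            raise ValueError(f"probbase shape {self.values.shape} != expected {expected}")
        if not np.isfinite(self.values).all():
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite probbase entry at (row {r + 1}, col {c + 1})")
        bad = (self.values < 0.0) | (self.values > 1.0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"probbase entry {self.values[r, c]} at (row {r + 1}, col {c + 1})"
                " is outside [0, 1]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PredictionSet:
    """Top-cause predictions (and optional posteriors) for a set of records."""

    record_ids: np.ndarray
    predicted_causes: np.ndarray
    cause_list: CauseList
    posteriors: np.ndarray | None = None  # (n, N), rows sum to 1
    flagged_ids: tuple = field(default_factory=tuple)  # e.g. all-missing records

    def __post_init__(self) -> None:
        self.record_ids = np.asarray(self.record_ids, dtype=object)
        self.predicted_causes = np.asarray(self.predicted_causes, dtype=object)
        if len(self.record_ids) != len(self.predicted_causes):
            raise ValueError("record_ids and predicted_causes lengths differ")
        known = set(self.cause_list.causes)
        for cause in self.predicted_causes:
            if cause not in known:
                raise ValueError(f"predicted cause {cause!r} is not in the cause list")
        if self.posteriors is not None:
            self.posteriors = np.asarray(self.posteriors, dtype=np.float64)
            if self.posteriors.shape != (len(self.record_ids), self.cause_list.N):
                raise ValueError("posterior matrix shape mismatch")
            if (self.posteriors < 0).any():
                raise ValueError("posterior weights must be non-negative")
            if not np.allclose(self.posteriors.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("posterior rows must sum to 1 within 1e-9")

    def predicted_indices(self) -> np.ndarray:
        return self.cause_list.indices_of(self.predicted_causes.tolist())


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_META_COLUMNS = ["record_id", "module", "site", "gold_cause"]


def read_dataset(path, cause_list: CauseList, symptom_dict: SymptomDictionary) -> VADataset:
    """Read a wide-format VA dataset CSV and validate it.

    Symptom cells must be ``1``, ``0`` or empty; empty cells become missing.
    Unknown gold causes and symptom-column mismatches raise ``ValueError``
    naming the offending row or column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"dataset CSV is missing required columns {missing_meta}")
    symptom_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if tuple(symptom_cols) != symptom_dict.ids:
        raise ValueError(
            "dataset symptom columns do not match the symptom dictionary: "
            f"file has {symptom_cols[:5]}..., dictionary has {list(symptom_dict.ids[:5])}..."
        )
    n = len(df)
    symptoms = np.full((n, symptom_dict.S), MISSING, dtype=np.int8)
    for j, col in enumerate(symptom_cols):
        vals = df[col].to_numpy()
        for i, v in enumerate(vals):
            v = v.strip()
            if v == "":
                continue
            if v == "1":
                symptoms[i, j] = YES
            elif v == "0":
                symptoms[i, j] = NO
            else:
                raise ValueError(
                    f"row {i + 1} (record {df['record_id'].iat[i]!r}): symptom"
                    f" {col!r} has value {v!r}; expected 1, 0 or empty"
                )
    known = set(cause_list.causes)
    for i, cause in enumerate(df["gold_cause"]):
        if cause not in known:
            raise ValueError(
                f"row {i + 1} (record {df['record_id'].iat[i]!r}): gold cause"
                f" {cause!r} is not in the cause list"
            )
    modules = df["module"].unique()
    if len(modules) != 1:
        raise ValueError(f"dataset mixes modules {sorted(modules)}; one module per file")
    return VADataset(
        record_ids=df["record_id"].to_numpy(dtype=object),
        module=str(modules[0]),
        sites=df["site"].to_numpy(dtype=object),
        gold_causes=df["gold_cause"].to_numpy(dtype=object),
        symptoms=symptoms,
        cause_list=cause_list,
        symptom_dict=symptom_dict,
    )


def write_dataset(dataset: VADataset, path) -> None:
    """Write a VA dataset in the wide CSV format (missing -> empty cell)."""
    cols = {
        "record_id": dataset.record_ids,
        "module": np.repeat(dataset.module, dataset.n_records),
        "site": dataset.sites,
        "gold_cause": dataset.gold_causes,
    }
    sym = dataset.symptoms
    for j, sid in enumerate(dataset.symptom_dict.ids):
        col = sym[:, j]
        cols[sid] = ["" if v == MISSING else str(int(v)) for v in col]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_probbase(path, cause_list: CauseList, symptom_dict: SymptomDictionary,
                  provenance: str = "fixed") -> Probbase:
    """Read a probbase CSV (rows = causes, columns = symptoms) and validate."""
    df = pd.read_csv(path, index_col=0)
    if tuple(df.index) != cause_list.causes:
        raise ValueError("probbase cause rows do not match the cause list (order matters)")
    if tuple(df.columns) != symptom_dict.ids:
        raise ValueError("probbase symptom columns do not match the symptom dictionary")
    return Probbase(df.to_numpy(dtype=np.float64), cause_list, symptom_dict,
                    provenance=provenance)


def write_probbase(probbase: Probbase, path) -> None:
    """Write a probbase CSV; entries round-trip to >= 12 significant digits."""
    df = pd.DataFrame(probbase.values,
                      index=list(probbase.cause_list.causes),
                      columns=list(probbase.symptom_dict.ids))
    df.to_csv(path, float_format="%.17g")


def read_symptom_dictionary(path) -> SymptomDictionary:
    df = pd.read_csv(path, dtype={"symptom_id": str})
    if "symptom_id" not in df.columns or "hce_flag" not in df.columns:
        raise ValueError("symptom dictionary CSV needs columns symptom_id,hce_flag")
    flags = df["hce_flag"].astype(str).str.strip().str.lower()
    mapped = flags.map({"1": True, "0": False, "true": True, "false": False})
    if mapped.isna().any():
        bad = flags[mapped.isna()].iloc[0]
        raise ValueError(f"hce_flag value {bad!r} is not 0/1/true/false")
    return SymptomDictionary(tuple(df["symptom_id"]), tuple(mapped))


def write_symptom_dictionary(symptom_dict: SymptomDictionary, path) -> None:
    pd.DataFrame({
        "symptom_id": list(symptom_dict.ids),
        "hce_flag": [int(f) for f in symptom_dict.hce_flags],
    }).to_csv(path, index=False)


def read_predictions(path, cause_list: CauseList) -> PredictionSet:
    """Read an external predictions CSV (``record_id,predicted_cause``).

    This is the plug-in contract: any classifier run outside this package can
    be scored by supplying its top-cause predictions in this format.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("record_id", "predicted_cause"):
        if col not in df.columns:
            raise ValueError(f"predictions CSV is missing column {col!r}")
    return PredictionSet(
        record_ids=df["record_id"].to_numpy(dtype=object),
        predicted_causes=df["predicted_cause"].to_numpy(dtype=object),
        cause_list=cause_list,
    )


def write_predictions(predictions: PredictionSet, path) -> None:
    pd.DataFrame({
        "record_id": predictions.record_ids,
        "predicted_cause": predictions.predicted_causes,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Health-care-experience masking
# ---------------------------------------------------------------------------

def apply_hce_mask(obj, include_hce: bool):
    """Drop health-care-experience symptom columns from a dataset or probbase.

    With ``include_hce=True`` this is the identity.  With ``False`` every
    HCE-flagged column is removed from the symptom matrix / probbase and the
    symptom dictionary consistently, preserving column order.  Removing all
    symptoms is an error (the dictionary invariant already forbids all-HCE
    dictionaries, so this can only arise from a corrupted object).
    """
    if include_hce:
        return obj
    if isinstance(obj, VADataset):
        keep = obj.symptom_dict.non_hce_indices()
        if keep.size == 0:
            raise ValueError("HCE masking would remove every symptom")
        new_dict = SymptomDictionary(
            tuple(obj.symptom_dict.ids[i] for i in keep),
            tuple(False for _ in keep),
        )
        return VADataset(
            record_ids=obj.record_ids,
            module=obj.module,
            sites=obj.sites,
            gold_causes=obj.gold_causes,
            symptoms=obj.symptoms[:, keep],
            cause_list=obj.cause_list,
            symptom_dict=new_dict,
        )
    if isinstance(obj, Probbase):
        keep = obj.symptom_dict.non_hce_indices()
        if keep.size == 0:
            raise ValueError("HCE masking would remove every symptom")
        new_dict = SymptomDictionary(
            tuple(obj.symptom_dict.ids[i] for i in keep),
            tuple(False for _ in keep),
        )
        return Probbase(obj.values[:, keep], obj.cause_list, new_dict,
                        provenance=obj.provenance,
                        zero_train_causes=obj.zero_train_causes)
    raise TypeError(f"apply_hce_mask does not support {type(obj).__name__}")


def default_cause_list(module: str, n_causes: int | None = None) -> CauseList:
    """Construct a generic cause list of the default size for ``module``."""
    if module not in MODULES:
        raise ValueError(f"unknown module {module!r}; expected one of {MODULES}")
    n = DEFAULT_CAUSE_COUNTS[module] if n_causes is None else int(n_causes)
    width = len(str(n))
    return CauseList(module, tuple(f"{module}_cause_{i + 1:0{width}d}" for i in range(n)))
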