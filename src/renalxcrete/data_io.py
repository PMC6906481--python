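"""Compound-table ingestion, serialization and dataset splitting.

The canonical tabular format is CSV with columns ``compound_id``, ``smiles``
and optional PK annotations (``fe``, ``clr``, ``fup_observed``,
``fup_predicted``, ``ionization_class``).  Structures may alternatively come
from an SDF file; SMILES wins on conflict.

Splitting follows the ceiling convention: the test partition holds
``ceil(n × test_fraction)`` records, which reproduces both printed dataset
splits used throughout (411 → 328/83 at 8:2 and 401 → 360/41 at 9:1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pk_core import (
    DEFAULT_CONSTANTS,
    CRType,
    PhysiologyConstants,
    classify_cr_type,
    compute_cr,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "SplitSpec",
    "read_compound_table",
    "write_compound_table",
    "read_structures",
    "split_dataset",
    "subset_by_cr_type",
    "records_to_frame",
    "write_split_manifest",
]

_IONIZATION_CLASSES = {"acid", "base", "neutral", "zwitterion"}
_NUMERIC_COLUMNS = ("fe", "clr", "fup_observed", "fup_predicted")


@dataclass
class CompoundRecord:
    """One compound's structure plus pharmacokinetic annotations.

    Absent annotations are ``None``.  ``cr_type`` is derived (see
    :func:`subset_by_cr_type`), never read from disk as authoritative.
    """

    compound_id: str
    smiles: str | None = None
    fe: float | None = None
    clr: float | None = None
    fup_observed: float | None = None
    fup_predicted: float | None = None
    ionization_class: str | None = None
    cr_type: CRType | None = None

    def validate(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if self.fe is not None and not (0 <= self.fe <= 1):
            raise ValueError(
                f"{self.compound_id}: fe must lie in [0, 1], got {self.fe!r}"
            )
        if self.clr is not None and not (self.clr >= 0):
            raise ValueError(
                f"{self.compound_id}: clr must be non-negative, got {self.clr!r}"
            )
        for name in ("fup_observed", "fup_predicted"):
            value = getattr(self, name)
            if value is not None and not (0 < value <= 1):
                raise ValueError(
                    f"{self.compound_id}: {name} must lie in (0, 1], got {value!r}"
                )
        if (
            self.ionization_class is not None
            and self.ionization_class not in _IONIZATION_CLASSES
        ):
            raise ValueError(
                f"{self.compound_id}: unknown ionization_class {self.ionization_class!r}"
            )


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split convention.

    ``test_fraction`` in (0, 1); the test set receives
    ``ceil(n × test_fraction)`` records.  ``stratify_on`` optionally names a
    record field whose level proportions are preserved across the partition.
    """

    test_fraction: float
    seed: int
    stratify_on: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError(
                f"test_fraction must lie in (0, 1), got {self.test_fraction!r}"
            )


def _parse_cell(value, row_idx: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row_idx}: could not parse column {column!r} value {value!r} as a number"
        ) from None


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound CSV into validated records.

    The header must contain ``compound_id`` and ``smiles``; other recognised
    columns are optional.  Blank cells become absent fields.  Duplicate
    compound ids and unparsable numeric cells are hard errors naming the
    offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"compound_id", "smiles"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: header lacks required column(s) {sorted(missing)}")
    dupes = frame["compound_id"][frame["compound_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate compound_id values: {sorted(dupes)}")

    records: list[CompoundRecord] = []
    for idx, row in frame.iterrows():
        kwargs: dict = {
            "compound_id": row["compound_id"],
            "smiles": row["smiles"].strip() or None,
        }
        for column in _NUMERIC_COLUMNS:
            if column in frame.columns:
                kwargs[column] = _parse_cell(row[column], int(idx) + 2, column)
        if "ionization_class" in frame.columns:
            kwargs["ionization_class"] = row["ionization_class"].strip() or None
        record = CompoundRecord(**kwargs)
        try:
            record.validate()
        except ValueError as exc:
            raise ValueError(f"{path} row {int(idx) + 2}: {exc}") from None
        records.append(record)
    return records


def write_compound_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Serialize records back to the canonical CSV schema."""
    records_to_frame(records).to_csv(path, index=False)


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Tabular view of records; ``cr_type`` rendered as its letter code."""
    rows = []
    for rec in records:
        rows.append(
            {
                "compound_id": rec.compound_id,
                "smiles": rec.smiles,
                "fe": rec.fe,
                "clr": rec.clr,
                "fup_observed": rec.fup_observed,
                "fup_predicted": rec.fup_predicted,
                "ionization_class": rec.ionization_class,
                "cr_type": rec.cr_type.value if rec.cr_type is not None else None,
            }
        )
    return pd.DataFrame(rows)


def read_structures(path: str | Path):
    """Read (compound_id, RDKit Mol) pairs from an SDF file.

    Order-preserving.  Unparsable molecule blocks are skipped with a logged
    warning; a file yielding zero parsable molecules is a hard error.  The
    identifier is the molecule title line, falling back to an ``ID`` /
    ``compound_id`` property, then to the positional index.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    except OSError as exc:
        raise ValueError(f"{path}: unreadable SDF ({exc})") from exc
    entries = []
    n_failed = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_failed += 1
            logger.warning("%s: molecule block %d failed to parse; skipped", path, i)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not name:
            for prop in ("compound_id", "ID", "id"):
                if mol.HasProp(prop):
                    name = mol.GetProp(prop)
                    break
        entries.append((name or f"mol_{i}", mol))
    if not entries:
        raise ValueError(f"{path}: no parsable molecules")
    if n_failed:
        logger.warning("%s: skipped %d unparsable molecule block(s)", path, n_failed)
    return entries


def split_dataset(
    records: Sequence[CompoundRecord], spec: SplitSpec
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Random disjoint train/test partition with a ceiling-rule test size.

    ``|test| = ceil(n × test_fraction)``; reproducible for a fixed seed.  With
    ``stratify_on`` set, test slots are allocated across the levels of that
    field by largest remainder so the total still follows the ceiling rule.
    """
    n = len(records)
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    n_test = math.ceil(n * spec.test_fraction)
    if n_test >= n:
        raise ValueError(
            f"test_fraction {spec.test_fraction} leaves an empty training set for n={n}"
        )
    rng = np.random.default_rng(spec.seed)

    if spec.stratify_on is None:
        order = rng.permutation(n)
        test_idx = set(order[:n_test].tolist())
    else:
        groups: dict[object, list[int]] = {}
        for i, rec in enumerate(records):
            groups.setdefault(getattr(rec, spec.stratify_on), []).append(i)
        # Largest-remainder allocation of test slots over strata.
        keys = sorted(groups, key=lambda k: str(k))
        quotas = {k: len(groups[k]) * n_test / n for k in keys}
        base = {k: math.floor(quotas[k]) for k in keys}
        short = n_test - sum(base.values())
        for k in sorted(keys, key=lambda k: quotas[k] - base[k], reverse=True)[:short]:
            base[k] += 1
        test_idx = set()
        for k in keys:
            idx = np.asarray(groups[k])
            take = min(base[k], len(idx))
            test_idx.update(idx[rng.permutation(len(idx))[:take]].tolist())
        # Top up if rounding against small strata left a shortfall.
        if len(test_idx) < n_test:
            rest = [i for i in range(n) if i not in test_idx]
            extra = rng.permutation(len(rest))[: n_test - len(test_idx)]
            test_idx.update(rest[j] for j in extra)

    train = [records[i] for i in range(n) if i not in test_idx]
    test = [records[i] for i in range(n) if i in test_idx]
    return train, test


def subset_by_cr_type(
    records: Iterable[CompoundRecord],
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> dict[CRType, list[CompoundRecord]]:
    """Annotate records with their observed CR type and partition by it.

    Requires ``clr`` and ``fup_observed`` on every record; the partition over
    {R, IM, S} is exhaustive and disjoint.
    """
    records = list(records)
    missing = [
        r.compound_id for r in records if r.clr is None or r.fup_observed is None
    ]
    if missing:
        raise ValueError(
            f"records missing clr or fup_observed: {missing}"
        )
    buckets: dict[CRType, list[CompoundRecord]] = {t: [] for t in CRType}
    for rec in records:
        cr = compute_cr(rec.clr, rec.fup_observed, constants)
        typed = replace(rec, cr_type=classify_cr_type(cr, constants))
        buckets[typed.cr_type].append(typed)
    return buckets


def write_split_manifest(
    train: Sequence[CompoundRecord],
    test: Sequence[CompoundRecord],
    path: str | Path,
) -> None:
    """Persist a partition as a two-column CSV (compound_id, partition)."""
    rows = [(r.compound_id, "train") for r in train] + [
        (r.compound_id, "test") for r in test
    ]
    pd.DataFrame(rows, columns=["compound_id", "partition"]).to_csv(path, index=False)
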