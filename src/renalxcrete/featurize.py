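"""Structure featurization: a 2D-descriptor block plus three binary
fingerprint families, with failed-descriptor exclusion and optional fu,p
column injection.

The feature table is organised in named blocks:

``descriptor_2d``
    Whole-molecule 2D descriptors (constitutional, topological,
    physico-chemical).
``fp_extended``
    Path-based (Daylight-style, "extended connectivity over linear paths")
    binary fingerprint bits.
``fp_klekota_roth``
    Substructure-key binary fingerprint bits.  In the bundled RDKit backend
    this family is backed by the MACCS structural keys.
``fp_atompairs_2d``
    Hashed 2D atom-pair binary fingerprint bits.
``fup``
    A single optional column carrying the fraction unbound in plasma
    (observed or predicted), attached after featurization.

Backends are pluggable: anything exposing ``feature_blocks(mol)`` returning
``{block: {name: value}}`` works.  The default backend is RDKit, whose
descriptor and fingerprint sets are deterministic for a fixed RDKit version.
Descriptor columns that fail to compute (NaN/±inf) for any compound are
excluded column-wise by :func:`drop_failed_features`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BLOCKS",
    "DescriptorMatrix",
    "RDKitBackend",
    "featurize",
    "drop_failed_features",
    "attach_fup_column",
    "save_matrix",
    "load_matrix",
]

BLOCKS = ("descriptor_2d", "fp_extended", "fp_klekota_roth", "fp_atompairs_2d", "fup")
_FP_BLOCKS = ("fp_extended", "fp_klekota_roth", "fp_atompairs_2d")


@dataclass
class DescriptorMatrix:
    """Compounds × named numeric features with block provenance.

    ``values`` is a dense numeric DataFrame indexed by compound_id;
    ``block_of`` maps every feature name to its block; ``missing_mask`` marks
    cells whose computation failed (non-finite).  After
    :func:`drop_failed_features` the mask is all-False.
    """

    values: pd.DataFrame
    block_of: dict[str, str]
    missing_mask: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        unknown = set(self.values.columns) - set(self.block_of)
        if unknown:
            raise ValueError(f"features with no block assignment: {sorted(unknown)}")
        bad_blocks = set(self.block_of.values()) - set(BLOCKS)
        if bad_blocks:
            raise ValueError(f"unknown block name(s): {sorted(bad_blocks)}")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(
                self.values.to_numpy(dtype=float)
            )
            self.missing_mask = pd.DataFrame(
                self.missing_mask, index=self.values.index, columns=self.values.columns
            )

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def features_in_block(self, block: str) -> list[str]:
        return [f for f in self.values.columns if self.block_of[f] == block]

    def select(self, features: Sequence[str]) -> "DescriptorMatrix":
        """Column subset by name, preserving block labels and provenance."""
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise KeyError(f"features not present: {missing}")
        return DescriptorMatrix(
            values=self.values[list(features)].copy(),
            block_of={f: self.block_of[f] for f in features},
            missing_mask=self.missing_mask[list(features)].copy(),
            provenance=dict(self.provenance),
        )

    def subset_rows(self, row_ids: Sequence[str]) -> "DescriptorMatrix":
        """Row subset by compound_id, order following ``row_ids``."""
        return DescriptorMatrix(
            values=self.values.loc[list(row_ids)].copy(),
            block_of=dict(self.block_of),
            missing_mask=self.missing_mask.loc[list(row_ids)].copy(),
            provenance=dict(self.provenance),
        )


class RDKitBackend:
    """Default featurization engine built on RDKit.

    2D descriptors come from ``Descriptors.CalcMolDescriptors``; the three
    fingerprint families are the RDKit path fingerprint (``fp_extended``),
    MACCS substructure keys (``fp_klekota_roth`` family) and hashed 2D atom
    pairs (``fp_atompairs_2d``).  Bit widths are configurable; outputs are
    deterministic for a fixed RDKit version.
    """

    name = "rdkit"

    def __init__(self, n_bits_extended: int = 1024, n_bits_atompairs: int = 1024):
        from rdkit.Chem import rdFingerprintGenerator

        self.n_bits_extended = n_bits_extended
        self.n_bits_atompairs = n_bits_atompairs
        self._gen_extended = rdFingerprintGenerator.GetRDKitFPGenerator(
            fpSize=n_bits_extended
        )
        self._gen_atompairs = rdFingerprintGenerator.GetAtomPairGenerator(
            fpSize=n_bits_atompairs
        )

    def parse(self, smiles: str):
        from rdkit import Chem

        return Chem.MolFromSmiles(smiles)

    def feature_blocks(self, mol) -> dict[str, dict[str, float]]:
        from rdkit.Chem import Descriptors, MACCSkeys

        desc = Descriptors.CalcMolDescriptors(mol)
        blocks: dict[str, dict[str, float]] = {
            "descriptor_2d": {k: float(v) for k, v in desc.items()}
        }
        ext = self._gen_extended.GetFingerprint(mol)
        blocks["fp_extended"] = {
            f"b{i:04d}": float(ext.GetBit(i)) for i in range(ext.GetNumBits())
        }
        maccs = MACCSkeys.GenMACCSKeys(mol)
        blocks["fp_klekota_roth"] = {
            f"k{i:03d}": float(maccs.GetBit(i)) for i in range(maccs.GetNumBits())
        }
        ap = self._gen_atompairs.GetFingerprint(mol)
        blocks["fp_atompairs_2d"] = {
            f"p{i:04d}": float(ap.GetBit(i)) for i in range(ap.GetNumBits())
        }
        return blocks


def featurize(structures, backend: RDKitBackend | None = None) -> DescriptorMatrix:
    """Compute the full descriptor matrix for a list of structures.

    ``structures`` is a sequence of ``(compound_id, smiles-or-Mol)`` pairs.
    Featurization is all-or-nothing per run: any structure that fails to
    parse aborts with an error listing the offending ids.  Feature names are
    prefixed with their block (``descriptor_2d.MolWt`` etc.); row order
    follows input order and values are independent of it.
    """
    backend = backend or RDKitBackend()
    mols = []
    failed = []
    for cid, struct in structures:
        mol = backend.parse(struct) if isinstance(struct, str) else struct
        if mol is None:
            failed.append(cid)
        else:
            mols.append((cid, mol))
    if failed:
        raise ValueError(f"structures failed to parse: {failed}")
    if not mols:
        raise ValueError("no structures to featurize")

    rows = []
    block_of: dict[str, str] = {}
    for cid, mol in mols:
        blocks = backend.feature_blocks(mol)
        row: dict[str, float] = {}
        for block, feats in blocks.items():
            for name, value in feats.items():
                qualified = f"{block}.{name}"
                row[qualified] = value
                block_of.setdefault(qualified, block)
        rows.append(pd.Series(row, name=cid))
    values = pd.DataFrame(rows)
    values.index.name = "compound_id"
    matrix = DescriptorMatrix(
        values=values,
        block_of=block_of,
        provenance={"backend": backend.name},
    )
    for block in _FP_BLOCKS:
        cols = matrix.features_in_block(block)
        if cols and not matrix.values[cols].isin([0.0, 1.0]).all().all():
            raise AssertionError(f"fingerprint block {block} produced non-binary values")
    return matrix


def drop_failed_features(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Exclude every feature column containing a failed (non-finite) value.

    Removal is column-wise only — rows are never dropped — and idempotent.
    Removal counts are logged per block; removing every column is an error.
    """
    finite = np.isfinite(matrix.values.to_numpy(dtype=float))
    ok = finite.all(axis=0) & ~matrix.missing_mask.to_numpy().any(axis=0)
    keep = [f for f, good in zip(matrix.feature_names, ok) if good]
    if not keep:
        raise ValueError("all feature columns failed; nothing survives exclusion")
    dropped = [f for f in matrix.feature_names if f not in set(keep)]
    if dropped:
        per_block: dict[str, int] = {}
        for f in dropped:
            per_block[matrix.block_of[f]] = per_block.get(matrix.block_of[f], 0) + 1
        logger.info(
            "excluded %d failed feature column(s): %s", len(dropped), per_block
        )
    out = matrix.select(keep)
    out.missing_mask.loc[:, :] = False
    out.provenance = {**matrix.provenance, "dropped_failed": len(dropped)}
    return out


def attach_fup_column(
    matrix: DescriptorMatrix, records, source: str
) -> DescriptorMatrix:
    """Append the fraction-unbound-in-plasma column from compound records.

    ``source`` is ``"observed"``, ``"predicted"`` or ``"none"`` (identity).
    Every matrix row must have the requested fu,p value on its record; the
    chosen source is recorded in the matrix provenance.
    """
    if source == "none":
        return matrix
    if source not in ("observed", "predicted"):
        raise ValueError(f"unknown fup source {source!r}")
    attr = f"fup_{source}"
    by_id = {r.compound_id: getattr(r, attr) for r in records}
    missing = [cid for cid in matrix.row_ids if by_id.get(cid) is None]
    if missing:
        raise ValueError(f"records missing {attr} for compounds: {missing}")
    values = matrix.values.copy()
    values["fup"] = [by_id[cid] for cid in matrix.row_ids]
    mask = matrix.missing_mask.copy()
    mask["fup"] = False
    return DescriptorMatrix(
        values=values,
        block_of={**matrix.block_of, "fup": "fup"},
        missing_mask=mask,
        provenance={**matrix.provenance, "fup_source": source},
    )


def save_matrix(matrix: DescriptorMatrix, csv_path: str | Path) -> None:
    """Persist as CSV (first column compound_id) + JSON block sidecar."""
    csv_path = Path(csv_path)
    matrix.values.to_csv(csv_path, index_label="compound_id")
    sidecar = csv_path.with_suffix(".blocks.json")
    sidecar.write_text(
        json.dumps(
            {"block_of": matrix.block_of, "provenance": matrix.provenance},
            indent=2,
            sort_keys=True,
        )
    )


def load_matrix(csv_path: str | Path) -> DescriptorMatrix:
    """Inverse of :func:`save_matrix`; round-trips values bit-exactly."""
    csv_path = Path(csv_path)
    values = pd.read_csv(csv_path, index_col="compound_id")
    meta = json.loads(csv_path.with_suffix(".blocks.json").read_text())
    return DescriptorMatrix(
        values=values,
        block_of=meta["block_of"],
        provenance=meta.get("provenance", {}),
    )
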