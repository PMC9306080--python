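"""Molecule/descriptor ingest, potency labeling, and the descriptor filter chain.

The chemical-space stage consumes a table of molecules with measured IC50
potencies and a precomputed molecular-descriptor matrix (one row per molecule,
one named numeric column per descriptor).  Before model fitting the descriptor
matrix is reduced by three filters applied in a fixed order:

1. sparsity   — drop columns whose fraction of exact zeros exceeds 0.85;
2. variance   — drop columns whose sample standard deviation is below 0.03;
3. redundancy — drop the later column of any pair with |Pearson rho| > 0.90,
                greedily left-to-right so a removed column cannot trigger
                further removals.

All thresholds are strict and configurable; defaults follow the published
protocol (85% zeros, 3% SD, 90% correlation).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Potency cutoff (µM) below which a molecule is labeled an inhibitor.
DEFAULT_IC50_CUTOFF_UM = 0.05
DEFAULT_MAX_ZERO_FRAC = 0.85
DEFAULT_MIN_SD = 0.03
DEFAULT_MAX_ABS_RHO = 0.90


class IngestError(ValueError):
    """Raised for unrecoverable problems in input files."""


@dataclass
class MoleculeRecord:
    """One molecule: identifier, structure, optional potency and class label.

    ``ic50`` is in µM; ``label`` is 1 (inhibitor) / 0 (non-inhibitor).
    """

    id: str
    smiles: str | None = None
    ic50: float | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("molecule id must be non-empty")
        if self.ic50 is not None and not self.ic50 > 0:
            raise ValueError(f"molecule {self.id!r}: ic50 must be > 0, got {self.ic50}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"molecule {self.id!r}: label must be 0 or 1")


@dataclass
class ParseFailure:
    """A record-level ingest failure (run continues)."""

    index: int
    id: str | None
    reason: str


@dataclass
class DescriptorMatrix:
    """Instances x named numeric features, optionally with binary labels."""

    ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count must equal number of ids")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count must equal number of feature names")
        if len(set(self.ids)) != len(self.ids):
            raise IngestError("duplicate molecule ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise IngestError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise IngestError("descriptor values must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.ids),):
                raise ValueError("labels length must equal number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def select_features(self, names: Sequence[str]) -> "DescriptorMatrix":
        idx = [self.feature_names.index(f) for f in names]
        return DescriptorMatrix(
            ids=list(self.ids),
            feature_names=list(names),
            values=self.values[:, idx],
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.feature_names)
        df.index.name = "id"
        if self.labels is not None:
            df["label"] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_column: str | None = None) -> "DescriptorMatrix":
        labels = None
        if label_column is not None and label_column in df.columns:
            labels = df[label_column].to_numpy()
            df = df.drop(columns=[label_column])
        return cls(
            ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            labels=labels,
        )


@dataclass
class FilterReport:
    """Bookkeeping for one filter stage."""

    stage: Literal["sparse", "low_sd", "correlated"]
    removed: list[str]
    threshold: float
    kept_count: int


def read_molecules(
    path: str | Path, format: Literal["smiles_table", "sdf"] = "smiles_table",
    ic50_property: str = "ic50_uM",
) -> tuple[list[MoleculeRecord], list[ParseFailure]]:
    """Read molecules from a SMILES table or an SDF file.

    The SMILES table is whitespace- or comma-delimited with a header row and
    columns ``id``, ``smiles``, optional ``ic50_uM`` and ``label``.  For SDF,
    the IC50 is read from the property tag named by ``ic50_property``.

    Returns ``(records, failures)``: unparsable structures are collected as
    :class:`ParseFailure` entries and the run continues.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    records: list[MoleculeRecord] = []
    failures: list[ParseFailure] = []

    if format == "smiles_table":
        df = pd.read_csv(path, sep=None, engine="python")
        if df.empty:
            raise IngestError(f"empty molecule table: {path}")
        df.columns = [c.strip().lower() for c in df.columns]
        if "id" not in df.columns or "smiles" not in df.columns:
            raise IngestError("SMILES table must have 'id' and 'smiles' columns")
        for i, row in df.iterrows():
            smiles = str(row["smiles"])
            if Chem.MolFromSmiles(smiles) is None:
                failures.append(ParseFailure(int(i), str(row["id"]), f"unparsable SMILES {smiles!r}"))
                continue
            ic50 = None
            if "ic50_um" in df.columns and pd.notna(row["ic50_um"]):
                ic50 = float(row["ic50_um"])
            label = None
            if "label" in df.columns and pd.notna(row["label"]):
                label = int(row["label"])
            records.append(MoleculeRecord(id=str(row["id"]), smiles=smiles, ic50=ic50, label=label))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        n_seen = 0
        for i, mol in enumerate(supplier):
            n_seen += 1
            if mol is None:
                failures.append(ParseFailure(i, None, "unparsable SDF block"))
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
            ic50 = float(mol.GetProp(ic50_property)) if mol.HasProp(ic50_property) else None
            records.append(MoleculeRecord(id=mol_id, smiles=Chem.MolToSmiles(mol), ic50=ic50))
        if n_seen == 0:
            raise IngestError(f"empty SDF file: {path}")
    else:
        raise IngestError(f"unsupported format: {format!r}")

    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise IngestError("duplicate molecule ids in input")
    for f in failures:
        logger.warning("parse failure at record %d (%s): %s", f.index, f.id, f.reason)
    return records, failures


def label_by_potency(
    records: Iterable[MoleculeRecord], cutoff: float = DEFAULT_IC50_CUTOFF_UM
) -> list[MoleculeRecord]:
    """Assign labels by the potency rule: inhibitor (1) iff IC50 < cutoff µM.

    The inequality is strict: a molecule at exactly the cutoff is a
    non-inhibitor.  If a record already carries a label it must agree with the
    derived one; a mismatch raises rather than silently preferring either.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    out = []
    for r in records:
        if r.ic50 is None:
            raise ValueError(f"molecule {r.id!r} has no IC50; cannot label by potency")
        derived = 1 if r.ic50 < cutoff else 0
        if r.label is not None and r.label != derived:
            raise IngestError(
                f"molecule {r.id!r}: input label {r.label} disagrees with "
                f"IC50-derived label {derived} (IC50={r.ic50} µM, cutoff={cutoff})"
            )
        out.append(dataclasses.replace(r, label=derived))
    return out


def read_descriptor_csv(path: str | Path, label_column: str | None = None) -> DescriptorMatrix:
    """Read a descriptor matrix CSV (header row; first column = molecule id).

    Non-numeric cells are an error naming the offending row and column; the
    label column, if named, is split out as the binary label vector.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise IngestError(f"duplicate feature names: {dupes}")
    if df.index.duplicated().any():
        raise IngestError(f"duplicate molecule ids: {df.index[df.index.duplicated()].tolist()}")
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise IngestError(f"label column {label_column!r} not in file")
        labels = df.pop(label_column).to_numpy()
    for col in df.columns:
        if df[col].isna().all():
            raise IngestError(f"column {col!r} is entirely empty")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist() + df.index[df[col].isna()].tolist()
        if bad:
            raise IngestError(f"non-numeric or missing cell(s) in column {col!r}, row(s) {bad[:5]}")
        df[col] = coerced
    return DescriptorMatrix(
        ids=[str(i) for i in df.index],
        feature_names=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        labels=labels,
    )


def write_descriptor_csv(m: DescriptorMatrix, path: str | Path, label_column: str = "label") -> None:
    """Write a descriptor matrix to CSV at full float precision (round-trip safe)."""
    df = pd.DataFrame(m.values, index=m.ids, columns=m.feature_names)
    df.index.name = "id"
    if m.labels is not None:
        df[label_column] = m.labels
    df.to_csv(path, float_format="%.17g")


def _drop(m: DescriptorMatrix, remove: list[str], stage: str, threshold: float):
    kept = [f for f in m.feature_names if f not in set(remove)]
    report = FilterReport(stage=stage, removed=remove, threshold=threshold, kept_count=len(kept))
    return m.select_features(kept), report


def filter_sparse(
    m: DescriptorMatrix, max_zero_frac: float = DEFAULT_MAX_ZERO_FRAC
) -> tuple[DescriptorMatrix, FilterReport]:
    """Remove columns whose fraction of exact zeros is strictly above the cutoff."""
    if not 0 <= max_zero_frac <= 1:
        raise ValueError("max_zero_frac must be in [0, 1]")
    zero_frac = (m.values == 0.0).mean(axis=0)
    removed = [f for f, z in zip(m.feature_names, zero_frac) if z > max_zero_frac]
    if len(removed) == m.d:
        logger.warning("sparsity filter removed every column")
    return _drop(m, removed, "sparse", max_zero_frac)


def filter_low_sd(
    m: DescriptorMatrix, min_sd: float = DEFAULT_MIN_SD, relative: bool = False
) -> tuple[DescriptorMatrix, FilterReport]:
    """Remove columns with sample SD (ddof=1) strictly below ``min_sd``.

    With ``relative=True`` the criterion is the coefficient of variation
    SD/|mean| instead of the absolute SD (columns with zero mean are kept
    unless their SD is zero).
    """
    if min_sd < 0:
        raise ValueError("min_sd must be >= 0")
    sd = m.values.std(axis=0, ddof=1) if m.n > 1 else np.zeros(m.d)
    if relative:
        mean = np.abs(m.values.mean(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            crit = np.where(mean > 0, sd / mean, np.where(sd > 0, np.inf, 0.0))
    else:
        crit = sd
    removed = [f for f, s in zip(m.feature_names, crit) if s < min_sd]
    return _drop(m, removed, "low_sd", min_sd)


def filter_correlated(
    m: DescriptorMatrix, max_abs_rho: float = DEFAULT_MAX_ABS_RHO
) -> tuple[DescriptorMatrix, FilterReport]:
    """Remove redundant columns with |Pearson rho| strictly above the cutoff.

    Greedy left-to-right: a column is removed iff it correlates above the
    cutoff with an *earlier kept* column, so the earlier column of any
    redundant pair survives and a removed column cannot cascade removals.
    """
    if not 0 <= max_abs_rho <= 1:
        raise ValueError("max_abs_rho must be in [0, 1]")
    if m.d == 0:
        return _drop(m, [], "correlated", max_abs_rho)
    sd = m.values.std(axis=0, ddof=0)
    if np.any(sd == 0):
        zero_cols = [f for f, s in zip(m.feature_names, sd) if s == 0]
        raise ValueError(
            f"zero-variance column(s) {zero_cols}: run filter_low_sd before filter_correlated"
        )
    corr = np.corrcoef(m.values, rowvar=False)
    kept_idx: list[int] = []
    removed: list[str] = []
    for j in range(m.d):
        if any(abs(corr[j, k]) > max_abs_rho for k in kept_idx):
            removed.append(m.feature_names[j])
        else:
            kept_idx.append(j)
    return _drop(m, removed, "correlated", max_abs_rho)


@dataclass
class FilterConfig:
    max_zero_frac: float = DEFAULT_MAX_ZERO_FRAC
    min_sd: float = DEFAULT_MIN_SD
    sd_relative: bool = False
    max_abs_rho: float = DEFAULT_MAX_ABS_RHO


def preprocess(
    m: DescriptorMatrix, cfg: FilterConfig | None = None
) -> tuple[DescriptorMatrix, list[FilterReport]]:
    """Apply the three-stage filter chain: sparsity, variance, redundancy.

    The order is fixed — the correlation filter requires variance to be
    positive everywhere, which the variance stage guarantees.  The chain is
    idempotent: a second application removes nothing.
    """
    if m.d == 0 or m.n == 0:
        raise ValueError("descriptor matrix is empty")
    cfg = cfg or FilterConfig()
    m1, r1 = filter_sparse(m, cfg.max_zero_frac)
    m2, r2 = filter_low_sd(m1, cfg.min_sd, relative=cfg.sd_relative)
    m3, r3 = filter_correlated(m2, cfg.max_abs_rho)
    return m3, [r1, r2, r3]
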