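"""Substructure-count fingerprints for ligands (protein-space features).

Each ligand is encoded as a length-4860 vector of substructure match counts
over a fixed SMARTS library (the Klekota–Roth dimensionality); the binary
view is the indicator ``count > 0``.  Match counting uses unique-match
semantics: symmetry-equivalent automorphic matches of a pattern on the same
atom set are collapsed (configurable via ``uniquify``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from ._substructure_library import LIBRARY_SIZE, LIBRARY_VERSION, generate_patterns
from .io_prep import MoleculeRecord


@dataclass(frozen=True)
class SubstructureLibrary:
    """Ordered SMARTS pattern library with stable indices 0..K-1."""

    patterns: tuple[str, ...]
    version: str = LIBRARY_VERSION
    _compiled: tuple = field(default=None, repr=False, compare=False)

    @property
    def size(self) -> int:
        return len(self.patterns)

    def compiled(self) -> tuple:
        """RDKit query molecules, compiled once and cached on the instance."""
        if self._compiled is None:
            from rdkit import Chem

            queries = tuple(Chem.MolFromSmarts(p) for p in self.patterns)
            for i, q in enumerate(queries):
                if q is None:
                    raise ValueError(f"pattern {i} ({self.patterns[i]!r}) failed to compile")
            object.__setattr__(self, "_compiled", queries)
        return self._compiled


@dataclass
class FingerprintVector:
    """Per-molecule substructure counts over a library."""

    molecule_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def binary(self) -> np.ndarray:
        return (self.counts > 0).astype(int)


def load_library() -> SubstructureLibrary:
    """Load the packaged 4860-pattern library in its canonical order.

    The library is generated deterministically in code (see
    ``_substructure_library``); two successive loads return identical
    pattern order.  Every pattern is validated to compile as a substructure
    query; an unparsable pattern raises naming its index.
    """
    lib = SubstructureLibrary(patterns=generate_patterns())
    if lib.size != LIBRARY_SIZE:
        raise ValueError(f"library has {lib.size} patterns, expected {LIBRARY_SIZE}")
    lib.compiled()
    return lib


def compute_fingerprint(
    mol: MoleculeRecord | str,
    lib: SubstructureLibrary,
    mode: Literal["count", "binary"] = "count",
    uniquify: bool = True,
) -> FingerprintVector:
    """Count substructure matches of every library pattern in one molecule.

    ``mol`` is a :class:`MoleculeRecord` or a bare SMILES string.  In
    ``count`` mode entry *i* is the number of distinct matches of pattern
    *i*; ``binary`` mode returns the indicator.  With ``uniquify`` (default)
    automorphic matches covering the same atom set count once.
    """
    from rdkit import Chem

    if isinstance(mol, MoleculeRecord):
        mol_id, smiles = mol.id, mol.smiles
    else:
        mol_id, smiles = str(mol), str(mol)
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparsable structure for molecule {mol_id!r}: {smiles!r}")
    counts = np.zeros(lib.size, dtype=int)
    for i, query in enumerate(lib.compiled()):
        matches = rdmol.GetSubstructMatches(query, uniquify=uniquify, maxMatches=100000)
        counts[i] = len(matches)
    if mode == "binary":
        counts = (counts > 0).astype(int)
    elif mode != "count":
        raise ValueError(f"unknown mode {mode!r}")
    return FingerprintVector(molecule_id=mol_id, counts=counts)


def fingerprint_matrix(
    molecules: Iterable[MoleculeRecord | str],
    lib: SubstructureLibrary | None = None,
    mode: Literal["count", "binary"] = "count",
) -> pd.DataFrame:
    """Fingerprint a collection of molecules into an N x K count DataFrame."""
    lib = lib or load_library()
    rows = [compute_fingerprint(m, lib, mode=mode) for m in molecules]
    df = pd.DataFrame(
        np.vstack([r.counts for r in rows]),
        index=[r.molecule_id for r in rows],
        columns=[f"p{i}" for i in range(lib.size)],
    )
    df.index.name = "id"
    return df


def write_fingerprints(df: pd.DataFrame, path: str | Path, sparse: bool = False) -> None:
    """Write fingerprints as dense CSV or sparse (id, pattern_index, count) triplets."""
    if sparse:
        rows = []
        cols = {c: j for j, c in enumerate(df.columns)}
        for mol_id, row in df.iterrows():
            nz = row[row > 0]
            for c, v in nz.items():
                rows.append((mol_id, cols[c], int(v)))
        pd.DataFrame(rows, columns=["id", "pattern_index", "count"]).to_csv(path, index=False)
    else:
        df.to_csv(path)


def read_fingerprints(path: str | Path, size: int = LIBRARY_SIZE) -> pd.DataFrame:
    """Read fingerprints written by :func:`write_fingerprints` (either layout)."""
    head = pd.read_csv(path, nrows=1)
    if list(head.columns) == ["id", "pattern_index", "count"]:
        trip = pd.read_csv(path)
        ids = list(dict.fromkeys(trip["id"]))
        mat = np.zeros((len(ids), size), dtype=int)
        pos = {m: i for i, m in enumerate(ids)}
        for _, r in trip.iterrows():
            mat[pos[r["id"]], int(r["pattern_index"])] = int(r["count"])
        df = pd.DataFrame(mat, index=ids, columns=[f"p{i}" for i in range(size)])
        df.index.name = "id"
        return df
    return pd.read_csv(path, index_col=0)
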