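"""Synthetic fixtures for every pipeline stage (no downloads, pure functions).

Generators emulate the statistical structure of the real inputs without
claiming chemical realism:

* :func:`gen_descriptor_matrix` — two-class descriptor matrices with planted
  sparse / constant / duplicated columns whose removal by the filter chain
  is known by construction;
* :func:`gen_fingerprint_dataset` — 4860-wide substructure-count matrices
  with class-informative columns;
* :func:`gen_complex` — syntactically valid PDB complexes whose geometry
  fires the packaged interaction profiler exactly per spec (planted sites
  are spaced 30 Å apart; decoy atoms sit far from every rule's reach);
* :func:`gen_potency_table` — molecule tables with a prescribed potency
  split around the 0.05 µM labeling cutoff;
* :func:`gen_study` — a coherent two-stage screening study with signal in
  both descriptor and fingerprint space and planted in-window interaction
  counts for the true actives.

Every generator is a pure function of its spec including the seed, and
returns a ground-truth manifest sufficient for downstream checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._substructure_library import LIBRARY_SIZE
from .interactions import InteractionProfile, InteractionRecord
from .io_prep import DescriptorMatrix


# --------------------------------------------------------------------------
# Descriptor matrices
# --------------------------------------------------------------------------

@dataclass
class DescriptorGenSpec:
    n: int = 100
    p: int = 20
    class_sep: float = 2.0
    n_informative: int = 5
    n_sparse: int = 0
    n_constant: int = 0
    n_duplicated: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("need n >= 4")
        planted = self.n_informative + self.n_sparse + self.n_constant + self.n_duplicated
        if planted > self.p:
            raise ValueError(f"planted columns ({planted}) exceed p ({self.p})")
        if self.n_duplicated > 0 and self.n_informative + (self.p - planted) == 0:
            raise ValueError("duplicated columns need at least one dense source column")


def gen_descriptor_matrix(spec: DescriptorGenSpec) -> tuple[DescriptorMatrix, dict]:
    """Two-class descriptor matrix with planted filter targets.

    Informative columns are class-shifted normals (shift = ``class_sep``);
    the remainder up to ``p`` is filled with uninformative noise.  Sparse
    columns carry > 85% exact zeros, constants a single value, duplicates
    are exact copies of earlier dense columns.  The manifest records every
    planted column by name.
    """
    rng = np.random.default_rng(spec.seed)
    n, half = spec.n, spec.n // 2
    y = np.array([0] * (n - half) + [1] * half)

    names, cols = [], []
    manifest: dict = {"seed": spec.seed, "informative": [], "sparse": [],
                      "constant": [], "duplicated": [], "noise": []}

    for i in range(spec.n_informative):
        name = f"inf{i}"
        col = rng.normal(0.0, 1.0, n) + spec.class_sep * y
        names.append(name); cols.append(col)
        manifest["informative"].append(name)

    n_noise = spec.p - spec.n_informative - spec.n_sparse - spec.n_constant - spec.n_duplicated
    for i in range(n_noise):
        name = f"noise{i}"
        names.append(name); cols.append(rng.normal(0.0, 1.0, n))
        manifest["noise"].append(name)

    for i in range(spec.n_sparse):
        name = f"sparse{i}"
        n_zero = math.floor(0.9 * n)  # zero fraction 0.9 > 0.85
        col = np.zeros(n)
        nz = rng.choice(n, size=n - n_zero, replace=False)
        col[nz] = rng.normal(5.0, 1.0, len(nz))
        names.append(name); cols.append(col)
        manifest["sparse"].append(name)

    for i in range(spec.n_constant):
        name = f"const{i}"
        names.append(name); cols.append(np.full(n, float(i + 1)))
        manifest["constant"].append(name)

    dense_sources = manifest["informative"] + manifest["noise"]
    for i in range(spec.n_duplicated):
        src = dense_sources[i % len(dense_sources)]
        name = f"dup{i}_of_{src}"
        names.append(name); cols.append(np.array(cols[names.index(src)]))
        manifest["duplicated"].append(name)

    order = rng.permutation(len(names))
    # keep each duplicate *after* its source so the redundancy filter,
    # which keeps the earlier column, removes exactly the planted copies
    order = _sources_first(order, names)
    names = [names[i] for i in order]
    cols = [cols[i] for i in order]

    m = DescriptorMatrix(
        ids=[f"mol{i:04d}" for i in range(n)],
        feature_names=names,
        values=np.column_stack(cols) if cols else np.zeros((n, 0)),
        labels=y,
    )
    manifest["planted_removed"] = (
        manifest["sparse"] + manifest["constant"] + manifest["duplicated"]
    )
    return m, manifest


def _sources_first(order: np.ndarray, names: list[str]) -> list[int]:
    pos = {names[i]: k for k, i in enumerate(order)}
    fixed = list(order)
    for i, name in enumerate(names):
        if name.startswith("dup"):
            src = name.split("_of_", 1)[1]
            if pos[name] < pos[src]:  # swap so the source comes first
                a, b = pos[name], pos[src]
                fixed[a], fixed[b] = fixed[b], fixed[a]
                pos[name], pos[src] = b, a
    return fixed


# --------------------------------------------------------------------------
# Fingerprint datasets
# --------------------------------------------------------------------------

def gen_fingerprint_dataset(
    n: int, k_informative: int, effect: float, seed: int,
    width: int = LIBRARY_SIZE, background_cols: int = 150,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Substructure-count matrix (n x 4860) with class-informative columns.

    Counts are Poisson draws; informative columns have their rate raised by
    ``effect`` for the positive class.  Returns (counts, labels, manifest).
    """
    if n < 20:
        raise ValueError("need n >= 20")
    if not 1 <= k_informative <= width:
        raise ValueError(f"need 1 <= k_informative <= {width}")
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n - n // 2) + [1] * (n // 2))
    X = np.zeros((n, width), dtype=int)
    active_cols = rng.choice(width, size=background_cols + k_informative, replace=False)
    informative = np.sort(active_cols[:k_informative])
    background = np.sort(active_cols[k_informative:])
    X[:, background] = rng.poisson(0.6, size=(n, len(background)))
    base = rng.poisson(0.5, size=(n, k_informative))
    boost = rng.poisson(effect, size=(n, k_informative)) * y[:, None]
    X[:, informative] = base + boost
    manifest = {"seed": seed, "informative_indices": informative.tolist(),
                "background_indices": background.tolist(), "effect": effect}
    return X, y, manifest


# --------------------------------------------------------------------------
# Complexes
# --------------------------------------------------------------------------

@dataclass
class ComplexGenSpec:
    planted: list[tuple[str, int]] = field(default_factory=list)
    decoy_atoms: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        known = {"hbond", "hydrophobic", "salt_bridge", "pi_stacking", "pi_cation"}
        for t, k in self.planted:
            if t not in known:
                raise ValueError(f"unknown interaction type {t!r}")
            if k < 0:
                raise ValueError("planted counts must be >= 0")


def _hexagon(radius: float, z: float, phase_deg: float = 0.0) -> list[tuple[float, float, float]]:
    out = []
    for k in range(6):
        a = math.radians(phase_deg + 60 * k)
        out.append((radius * math.cos(a), radius * math.sin(a), z))
    return out


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, xyz: tuple[float, float, float], element: str,
              charge: int = 0) -> str:
    x, y, z = xyz
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    charge_f = "  " if charge == 0 else f"{abs(charge)}{'+' if charge > 0 else '-'}"
    return (f"{record:<6s}{serial:>5d} {name_f}{'':1s}{resname:<3s} {chain}"
            f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}{charge_f}")


# Site templates: (protein residue atoms, ligand atoms). Coordinates are
# local to the site; each plants exactly one interaction of its type and,
# by margin, nothing else.
def _site(kind: str, tag: int):
    if kind == "salt_bridge":
        prot = ("ASP", [("CB", "C", (0, 0, -1.5)), ("CG", "C", (0, 0, 0)),
                        ("OD1", "O", (-1.1, 0, 0.6)), ("OD2", "O", (1.1, 0, 0.6))])
        lig = [(f"N{tag}", "N", (0, 0, 5.4), 1)]
    elif kind == "hbond":
        prot = ("SER", [("CB", "C", (0, 0, -1.5)), ("OG", "O", (0, 0, 0))])
        lig = [(f"O{tag}", "O", (0, 0, 3.0), 0)]
    elif kind == "hydrophobic":
        prot = ("ALA", [("CA", "C", (0, 0, -1.54)), ("CB", "C", (0, 0, 0))])
        lig = [(f"C{tag}", "C", (0, 0, 3.6), 0)]
    elif kind == "pi_stacking":
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        prot = ("PHE", [(nm, "C", p) for nm, p in zip(ring_names, _hexagon(1.39, 0.0))])
        lig = [(f"C{tag}{chr(ord('A') + k)}", "C", p, 0)
               for k, p in enumerate(_hexagon(1.39, 4.2, phase_deg=30.0))]
    elif kind == "pi_cation":
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        prot = ("PHE", [(nm, "C", p) for nm, p in zip(ring_names, _hexagon(1.39, 0.0))])
        lig = [(f"N{tag}", "N", (0, 0, 4.5), 1)]
    else:  # pragma: no cover
        raise ValueError(kind)
    return prot, lig


_EXPECTED_DISTANCE = {"salt_bridge": 4.8, "hbond": 3.0, "hydrophobic": 3.6,
                      "pi_stacking": 4.2, "pi_cation": 4.5}


def gen_complex(spec: ComplexGenSpec, complex_id: str = "synthetic") -> tuple[str, InteractionProfile]:
    """Write a synthetic PDB complex whose profile is known by construction.

    Each planted interaction occupies its own site 30 Å from every other
    site; ``decoy_atoms`` glycine atoms are placed 60 Å away from all
    ligand atoms.  Returns the PDB text and the expected profile.
    """
    rng = np.random.default_rng(spec.seed)
    lines = []
    serial, resseq, site_index = 1, 1, 0
    expected: list[InteractionRecord] = []
    lig_atoms_out = []

    for kind, count in spec.planted:
        for _ in range(count):
            offset = np.array([30.0 * site_index, 0.0, 0.0])
            prot_res, lig_atoms = _site(kind, site_index)
            resname, atoms = prot_res
            residue_label = f"{resname}{resseq}:A"
            for name, element, pos in atoms:
                xyz = tuple(np.asarray(pos, float) + offset)
                lines.append(_pdb_line("ATOM", serial, name, resname, "A", resseq, xyz, element))
                serial += 1
            for entry in lig_atoms:
                name, element, pos, charge = entry
                xyz = tuple(np.asarray(pos, float) + offset)
                lig_atoms_out.append((name, element, xyz, charge))
            lig_names = tuple(a[0] for a in lig_atoms)
            expected.append(InteractionRecord(
                type=kind, residue=residue_label,
                ligand_atoms=lig_names if len(lig_names) > 1 else (lig_names[0],),
                distance=_EXPECTED_DISTANCE[kind],
            ))
            resseq += 1
            site_index += 1

    for k in range(spec.decoy_atoms):
        xyz = (30.0 * (k % max(site_index, 1)) + float(rng.normal(0, 2)),
               60.0 + 8.0 * (k // max(site_index, 1)), float(rng.normal(0, 2)))
        lines.append(_pdb_line("ATOM", serial, "CA", "GLY", "B", 500 + k, xyz, "C"))
        serial += 1

    if not lig_atoms_out:
        # an empty-contact fixture still needs a ligand group (far from protein)
        lig_atoms_out.append(("C99", "C", (500.0, 500.0, 500.0), 0))
    for name, element, xyz, charge in lig_atoms_out:
        lines.append(_pdb_line("HETATM", serial, name, "LIG", "L", 900, xyz, element, charge))
        serial += 1
    lines.append("END")

    order = {"hbond": 0, "hydrophobic": 1, "salt_bridge": 2, "pi_stacking": 3, "pi_cation": 4}
    expected.sort(key=lambda r: (order[r.type], r.residue, r.ligand_atoms))
    return "\n".join(lines) + "\n", InteractionProfile(complex_id=complex_id, records=expected)


# --------------------------------------------------------------------------
# Potency tables
# --------------------------------------------------------------------------

_SMILES_POOL = ["CCO", "c1ccccc1", "CCN", "CC(=O)O", "c1ccncc1", "CCCC",
                "c1cnc[nH]1", "CC(C)O", "CCS", "c1ccc2[nH]ccc2c1"]


def gen_potency_table(
    n_active: int = 81, n_inactive: int = 94, cutoff: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Molecule table with a prescribed potency split around ``cutoff`` µM.

    A synthetic stand-in for a published training table: IC50s for actives
    are log-uniform strictly below the cutoff, inactives strictly above.
    Columns: id, smiles, ic50_uM.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_active):
        ic50 = float(np.exp(rng.uniform(np.log(cutoff / 100), np.log(cutoff * 0.98))))
        rows.append((f"ACT{i:04d}", _SMILES_POOL[i % len(_SMILES_POOL)], ic50))
    for i in range(n_inactive):
        ic50 = float(np.exp(rng.uniform(np.log(cutoff * 1.02), np.log(cutoff * 2000))))
        rows.append((f"INA{i:04d}", _SMILES_POOL[i % len(_SMILES_POOL)], ic50))
    return pd.DataFrame(rows, columns=["id", "smiles", "ic50_uM"])


# --------------------------------------------------------------------------
# End-to-end study
# --------------------------------------------------------------------------

@dataclass
class StudyData:
    """A complete synthetic two-stage screening study."""

    train_descriptors: DescriptorMatrix
    screen_descriptors: DescriptorMatrix
    train_fingerprints: np.ndarray
    screen_fingerprints: np.ndarray
    train_labels: np.ndarray
    screen_labels: np.ndarray
    screen_ids: list[str]
    complexes: dict[str, str]          # id -> PDB text
    expected_d_i: dict[str, int]
    window: tuple[int, int]
    manifest: dict


def gen_study(
    n_train: int = 120, n_screen: int = 40, class_sep: float = 3.0,
    fp_effect: float = 3.0, window: tuple[int, int] = (9, 12), seed: int = 0,
    fp_width: int = LIBRARY_SIZE,
) -> StudyData:
    """Generate a coherent study: descriptor + fingerprint signal, planted d_i.

    True actives receive interaction counts inside ``window`` (cycling over
    all five contact types); decoys receive 0..window_min-4 contacts.  The
    manifest records the planted actives, whose recovery at the top of the
    beta ranking is the end-to-end success criterion.
    """
    rng = np.random.default_rng(seed)
    n = n_train + n_screen
    spec = DescriptorGenSpec(n=n, p=24, class_sep=class_sep, n_informative=6,
                             n_sparse=3, n_constant=2, n_duplicated=2, seed=seed + 1)
    m_all, desc_manifest = gen_descriptor_matrix(spec)
    X_fp, y_fp, fp_manifest = gen_fingerprint_dataset(
        n, k_informative=12, effect=fp_effect, seed=seed + 2, width=fp_width)
    y = m_all.labels
    # align fingerprint labels with descriptor labels by permuting class blocks
    assert (np.sort(y) == np.sort(y_fp)).all()
    idx_fp = np.concatenate([np.flatnonzero(y_fp == 0), np.flatnonzero(y_fp == 1)])
    idx_y = np.concatenate([np.flatnonzero(y == 0), np.flatnonzero(y == 1)])
    X_fp_aligned = np.empty_like(X_fp)
    X_fp_aligned[idx_y] = X_fp[idx_fp]

    perm = rng.permutation(n)
    train_idx, screen_idx = perm[:n_train], perm[n_train:]

    def subset(idx):
        return DescriptorMatrix(
            ids=[m_all.ids[i] for i in idx],
            feature_names=list(m_all.feature_names),
            values=m_all.values[idx],
            labels=y[idx],
        )

    screen_ids = [m_all.ids[i] for i in screen_idx]
    screen_labels = y[screen_idx]

    kinds = ["salt_bridge", "hbond", "hydrophobic", "pi_stacking", "pi_cation"]
    complexes, expected_d = {}, {}
    lo, hi = window
    for k, (mol_id, label) in enumerate(zip(screen_ids, screen_labels)):
        if label == 1:
            d = int(rng.integers(lo, hi + 1))
        else:
            d = int(rng.integers(0, max(lo - 3, 1)))
        planted = [(kinds[(k + j) % len(kinds)], 1) for j in range(d)]
        merged: dict[str, int] = {}
        for t, c in planted:
            merged[t] = merged.get(t, 0) + c
        cspec = ComplexGenSpec(planted=sorted(merged.items()), decoy_atoms=4,
                               seed=seed + 100 + k)
        pdb_text, prof = gen_complex(cspec, complex_id=mol_id)
        complexes[mol_id] = pdb_text
        expected_d[mol_id] = prof.d_i

    manifest = {
        "seed": seed, "descriptors": desc_manifest, "fingerprints": fp_manifest,
        "window": list(window),
        "planted_actives": [m for m, l in zip(screen_ids, screen_labels) if l == 1],
        "expected_d_i": expected_d,
    }
    return StudyData(
        train_descriptors=subset(train_idx),
        screen_descriptors=subset(screen_idx),
        train_fingerprints=X_fp_aligned[train_idx],
        screen_fingerprints=X_fp_aligned[screen_idx],
        train_labels=y[train_idx],
        screen_labels=screen_labels,
        screen_ids=screen_ids,
        complexes=complexes,
        expected_d_i=expected_d,
        window=window,
        manifest=manifest,
    )
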