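"""Protein–ligand interaction profiling from docked PDB complexes.

Each docked complex is reduced to a typed contact list and its total count
d_i, the quantity the optimization score beta = f(alpha) + d_i consumes.
Two routes produce a profile:

* the packaged geometric profiler (:func:`detect_interactions`), which
  applies simplified distance/angle rules with defaults mirroring PLIP's
  published cutoffs; or
* :func:`ingest_plip_report`, which maps a real PLIP XML or text report
  onto the same record types.

Supported contact types: hydrogen bond, hydrophobic contact, salt bridge,
pi-stacking and pi-cation; report ingest additionally maps PLIP's water
bridges / halogen bonds / metal complexes to an ``other`` type (counted in
d_i by default, toggleable).

Geometry conventions: coordinates in Å; a contact is reported once per
(type, residue, ligand atom-or-ring); only the first model (MODEL 1) of a
multi-model file is profiled and only the first altloc of a disordered atom
is kept.  Hydrogens are optional — when absent, donor capability is
inferred from heavy-atom types, and hydrogen-bond angle criteria are
skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

InteractionType = Literal[
    "hbond", "hydrophobic", "salt_bridge", "pi_stacking", "pi_cation", "other"
]

#: Heavy-atom distance within which two atoms are considered covalently bonded.
BOND_CUTOFF = 1.9
WATER_NAMES = {"HOH", "WAT", "DOD"}

# Charged-group templates (residue name -> atom names, sign).
_NEGATIVE_GROUPS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_POSITIVE_GROUPS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "CZ"), "HIS": ("ND1", "NE2")}

# Aromatic-ring templates (residue name -> tuple of rings, each a tuple of atom names).
_AROMATIC_RINGS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
}


@dataclass
class InteractionRules:
    """Geometric cutoffs for the packaged profiler (Å and degrees)."""

    hbond_dist_max: float = 4.1
    hbond_dist_min: float = 2.0
    hbond_donor_angle_min: float = 100.0
    hydrophobic_dist_max: float = 4.0
    salt_bridge_dist_max: float = 5.5
    pi_stack_dist_max: float = 5.5
    pi_stack_parallel_angle_max: float = 30.0
    pi_stack_tshape_angle_min: float = 60.0
    pi_stack_offset_max: float = 2.5
    pi_cation_dist_max: float = 6.0
    enabled_types: tuple[str, ...] = (
        "hbond", "hydrophobic", "salt_bridge", "pi_stacking", "pi_cation"
    )


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    resname: str
    resseq: int
    chain: str
    pos: tuple[float, float, float]
    charge: int = 0

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos)

    @property
    def residue(self) -> str:
        return f"{self.resname}{self.resseq}:{self.chain}"


@dataclass
class ComplexStructure:
    """Parsed docked complex: protein atoms + one ligand HETATM group."""

    complex_id: str
    protein_atoms: list[Atom]
    ligand_atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError(f"complex {self.complex_id!r} has no ligand atoms")
        for a in self.protein_atoms + self.ligand_atoms:
            if not np.all(np.isfinite(a.xyz)):
                raise ValueError("non-finite coordinates")


@dataclass
class InteractionRecord:
    type: str
    residue: str
    ligand_atoms: tuple[str, ...]
    distance: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class InteractionProfile:
    complex_id: str
    records: list[InteractionRecord]

    @property
    def d_i(self) -> int:
        return len(self.records)

    def count_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.type] = out.get(r.type, 0) + 1
        return out


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

def parse_complex(
    path: str | Path, ligand_selector: str | None = None, complex_id: str | None = None
) -> ComplexStructure:
    """Parse a PDB complex: ATOM records = protein, selected HETATM group = ligand.

    ``ligand_selector`` is a HETATM residue name (e.g. ``"LIG"``); when
    omitted, the file must contain exactly one non-water HETATM residue
    name, otherwise the candidates are listed in the error.  Waters are
    always excluded; MODEL 1 only; first altloc kept.
    """
    import gemmi

    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    protein: list[Atom] = []
    het_groups: dict[str, list[Atom]] = {}
    for chain in model:
        for res in chain:
            seen_names: set[str] = set()
            atoms = []
            for a in res:
                if a.name in seen_names:  # keep first altloc only
                    continue
                seen_names.add(a.name)
                atoms.append(Atom(
                    name=a.name, element=a.element.name.upper(), resname=res.name,
                    resseq=res.seqid.num, chain=chain.name,
                    pos=(a.pos.x, a.pos.y, a.pos.z), charge=int(a.charge),
                ))
            if res.name in WATER_NAMES:
                continue
            if res.het_flag == "H":
                het_groups.setdefault(res.name, []).extend(atoms)
            else:
                protein.extend(atoms)

    if not het_groups:
        raise ValueError(f"{path}: no non-water HETATM ligand group found")
    if ligand_selector is not None:
        if ligand_selector not in het_groups:
            raise ValueError(
                f"{path}: no HETATM group named {ligand_selector!r}; "
                f"candidates: {sorted(het_groups)}"
            )
        ligand = het_groups[ligand_selector]
    elif len(het_groups) == 1:
        ligand = next(iter(het_groups.values()))
    else:
        raise ValueError(
            f"{path}: multiple ligand candidates {sorted(het_groups)}; "
            "pass ligand_selector to disambiguate"
        )
    return ComplexStructure(
        complex_id=complex_id or path.stem,
        protein_atoms=protein,
        ligand_atoms=ligand,
    )


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------

def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.xyz - b.xyz))


def _bond_graph(atoms: Sequence[Atom]) -> dict[int, set[int]]:
    """Infer covalent bonds among heavy atoms by interatomic distance."""
    adj: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    coords = np.array([a.xyz for a in atoms]) if atoms else np.zeros((0, 3))
    for i in range(len(atoms)):
        d = np.linalg.norm(coords - coords[i], axis=1)
        for j in np.flatnonzero((d > 0.1) & (d <= BOND_CUTOFF)):
            adj[i].add(int(j))
            adj[int(j)].add(i)
    return adj


def _apolar_carbons(atoms: Sequence[Atom], adj: dict[int, set[int]]) -> list[int]:
    """Carbons bonded to no N/O/S/P (classical hydrophobic contact partners)."""
    out = []
    for i, a in enumerate(atoms):
        if a.element != "C":
            continue
        if all(atoms[j].element not in ("N", "O", "S", "P") for j in adj[i]):
            out.append(i)
    return out


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid, unit normal and max planarity deviation of a ring."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    dev = float(np.abs(centered @ normal).max())
    return centroid, normal, dev


def _ligand_rings(atoms: Sequence[Atom], adj: dict[int, set[int]]) -> list[list[int]]:
    """5/6-membered, near-planar rings in the ligand bond graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    for i, nbrs in adj.items():
        for j in nbrs:
            g.add_edge(i, j)
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        coords = np.array([atoms[i].xyz for i in cycle])
        _, _, dev = _ring_plane(coords)
        if dev < 0.35:
            rings.append(cycle)
    return rings


def _protein_rings(atoms: Sequence[Atom]) -> list[tuple[str, list[int]]]:
    by_res: dict[tuple, dict[str, int]] = {}
    for i, a in enumerate(atoms):
        by_res.setdefault((a.resname, a.resseq, a.chain), {})[a.name] = i
    rings = []
    for (resname, _, _), name_map in by_res.items():
        for ring_names in _AROMATIC_RINGS.get(resname, ()):
            if all(n in name_map for n in ring_names):
                idx = [name_map[n] for n in ring_names]
                rings.append((atoms[idx[0]].residue, idx))
    return rings


def _charged_centers(
    atoms: Sequence[Atom], adj: dict[int, set[int]] | None, protein: bool
) -> list[tuple[int, np.ndarray, str, tuple[str, ...]]]:
    """(sign, centroid, residue, member atom names) for each charged group."""
    centers = []
    if protein:
        by_res: dict[tuple, dict[str, int]] = {}
        for i, a in enumerate(atoms):
            by_res.setdefault((a.resname, a.resseq, a.chain), {})[a.name] = i
        for (resname, _, _), name_map in by_res.items():
            for table, sign in ((_NEGATIVE_GROUPS, -1), (_POSITIVE_GROUPS, +1)):
                names = table.get(resname)
                if names and all(n in name_map for n in names):
                    idx = [name_map[n] for n in names]
                    centroid = np.mean([atoms[i].xyz for i in idx], axis=0)
                    centers.append((sign, centroid, atoms[idx[0]].residue,
                                    tuple(atoms[i].name for i in idx)))
    else:
        # Ligand: group contiguous formally charged atoms into one center.
        charged = [i for i, a in enumerate(atoms) if a.charge != 0]
        used: set[int] = set()
        for i in charged:
            if i in used:
                continue
            group = {i}
            frontier = [i]
            while frontier:
                k = frontier.pop()
                for j in (adj or {}).get(k, ()):  # grow through bonded charged atoms
                    if j in charged and j not in group:
                        group.add(j)
                        frontier.append(j)
            used |= group
            sign = int(np.sign(sum(atoms[j].charge for j in group))) or 1
            centroid = np.mean([atoms[j].xyz for j in group], axis=0)
            centers.append((sign, centroid, atoms[i].residue,
                            tuple(atoms[j].name for j in group)))
    return centers


def _hbond_capable(atom: Atom, adj: dict[int, set[int]], idx: int) -> tuple[bool, bool]:
    """(can_donate, can_accept) inferred from heavy-atom connectivity.

    Without explicit hydrogens: any N with < 4 heavy neighbours may carry a
    donatable H; an O with <= 1 heavy neighbour is hydroxyl/water-like
    (donor); every N/O accepts.
    """
    n_heavy = len(adj[idx])
    if atom.element == "N":
        return n_heavy < 4, True
    if atom.element == "O":
        return n_heavy <= 1, True
    return False, False


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

def detect_interactions(
    c: ComplexStructure, rules: InteractionRules | None = None
) -> list[InteractionRecord]:
    """Apply the geometric rule set to one complex; deterministic record list.

    Each contact is reported once per (type, residue, ligand atom/ring).
    Hydrophobic contacts between rings that also satisfy the pi-stacking
    rule are suppressed in favour of the stacking record.
    """
    rules = rules or InteractionRules()
    prot, lig = c.protein_atoms, c.ligand_atoms
    prot_adj = _bond_graph(prot)
    lig_adj = _bond_graph(lig)
    records: list[InteractionRecord] = []

    lig_rings = _ligand_rings(lig, lig_adj)
    prot_rings = _protein_rings(prot)

    # --- pi-stacking (first, so ring-ring hydrophobic contacts can be pruned)
    stacked_pairs: list[tuple[str, frozenset[int]]] = []
    if "pi_stacking" in rules.enabled_types:
        for residue, p_idx in prot_rings:
            p_coords = np.array([prot[i].xyz for i in p_idx])
            p_cen, p_norm, _ = _ring_plane(p_coords)
            for ring in lig_rings:
                l_coords = np.array([lig[i].xyz for i in ring])
                l_cen, l_norm, _ = _ring_plane(l_coords)
                d = float(np.linalg.norm(p_cen - l_cen))
                if d > rules.pi_stack_dist_max:
                    continue
                cosang = abs(float(np.dot(p_norm, l_norm)))
                angle = math.degrees(math.acos(min(1.0, cosang)))
                parallel = angle <= rules.pi_stack_parallel_angle_max
                tshape = angle >= rules.pi_stack_tshape_angle_min
                if not (parallel or tshape):
                    continue
                # in-plane offset of the ligand centroid over the protein ring
                v = l_cen - p_cen
                offset = float(np.linalg.norm(v - np.dot(v, p_norm) * p_norm))
                if parallel and offset > rules.pi_stack_offset_max:
                    continue
                records.append(InteractionRecord(
                    type="pi_stacking", residue=residue,
                    ligand_atoms=tuple(lig[i].name for i in ring),
                    distance=d, angle=angle,
                ))
                stacked_pairs.append((residue, frozenset(ring)))

    # --- hydrogen bonds
    if "hbond" in rules.enabled_types:
        seen = set()
        for pi, pa in enumerate(prot):
            if pa.element not in ("N", "O"):
                continue
            p_don, p_acc = _hbond_capable(pa, prot_adj, pi)
            for li, la in enumerate(lig):
                if la.element not in ("N", "O"):
                    continue
                l_don, l_acc = _hbond_capable(la, lig_adj, li)
                if not ((p_don and l_acc) or (l_don and p_acc)):
                    continue
                d = _dist(pa, la)
                if not rules.hbond_dist_min <= d <= rules.hbond_dist_max:
                    continue
                key = (pa.residue, la.name)
                if key in seen:
                    continue
                seen.add(key)
                records.append(InteractionRecord(
                    type="hbond", residue=pa.residue,
                    ligand_atoms=(la.name,), distance=d,
                ))

    # --- hydrophobic contacts
    if "hydrophobic" in rules.enabled_types:
        stacked_lig_atoms = {
            (res, lig[i].name) for res, ring in stacked_pairs for i in ring
        }
        best: dict[tuple[str, str], float] = {}
        for pi in _apolar_carbons(prot, prot_adj):
            for li in _apolar_carbons(lig, lig_adj):
                d = _dist(prot[pi], lig[li])
                if d > rules.hydrophobic_dist_max:
                    continue
                key = (prot[pi].residue, lig[li].name)
                if key in stacked_lig_atoms:
                    continue
                if key not in best or d < best[key]:
                    best[key] = d
        for (residue, lname), d in sorted(best.items()):
            records.append(InteractionRecord(
                type="hydrophobic", residue=residue, ligand_atoms=(lname,), distance=d,
            ))

    # --- salt bridges
    if "salt_bridge" in rules.enabled_types:
        p_centers = _charged_centers(prot, None, protein=True)
        l_centers = _charged_centers(lig, lig_adj, protein=False)
        for ps, p_cen, residue, _ in p_centers:
            for ls, l_cen, _, l_names in l_centers:
                if ps * ls >= 0:
                    continue
                d = float(np.linalg.norm(p_cen - l_cen))
                if d <= rules.salt_bridge_dist_max:
                    records.append(InteractionRecord(
                        type="salt_bridge", residue=residue,
                        ligand_atoms=l_names, distance=d,
                    ))

    # --- pi-cation
    if "pi_cation" in rules.enabled_types:
        l_centers = _charged_centers(lig, lig_adj, protein=False)
        for residue, p_idx in prot_rings:
            p_cen, _, _ = _ring_plane(np.array([prot[i].xyz for i in p_idx]))
            for ls, l_cen, _, l_names in l_centers:
                if ls <= 0:
                    continue
                d = float(np.linalg.norm(p_cen - l_cen))
                if d <= rules.pi_cation_dist_max:
                    records.append(InteractionRecord(
                        type="pi_cation", residue=residue,
                        ligand_atoms=l_names, distance=d,
                    ))
        p_centers = _charged_centers(prot, None, protein=True)
        for ring in lig_rings:
            l_cen, _, _ = _ring_plane(np.array([lig[i].xyz for i in ring]))
            for ps, p_cen, residue, _ in p_centers:
                if ps <= 0:
                    continue
                d = float(np.linalg.norm(p_cen - l_cen))
                if d <= rules.pi_cation_dist_max:
                    records.append(InteractionRecord(
                        type="pi_cation", residue=residue,
                        ligand_atoms=tuple(lig[i].name for i in ring), distance=d,
                    ))

    order = {"hbond": 0, "hydrophobic": 1, "salt_bridge": 2,
             "pi_stacking": 3, "pi_cation": 4, "other": 5}
    records.sort(key=lambda r: (order.get(r.type, 9), r.residue, r.ligand_atoms))
    return records


def profile(c: ComplexStructure, rules: InteractionRules | None = None) -> InteractionProfile:
    """Full interaction profile of one complex: records plus d_i = |records|."""
    return InteractionProfile(complex_id=c.complex_id, records=detect_interactions(c, rules))


# --------------------------------------------------------------------------
# PLIP report ingest
# --------------------------------------------------------------------------

_PLIP_XML_SECTIONS = {
    "hydrogen_bonds": "hbond",
    "hydrophobic_interactions": "hydrophobic",
    "salt_bridges": "salt_bridge",
    "pi_stacks": "pi_stacking",
    "pi_cation_interactions": "pi_cation",
    "water_bridges": "other",
    "halogen_bonds": "other",
    "metal_complexes": "other",
}

_PLIP_TXT_SECTIONS = {
    "hydrogen bonds": "hbond",
    "hydrophobic interactions": "hydrophobic",
    "salt bridges": "salt_bridge",
    "pi-stacking": "pi_stacking",
    "pi-cation interactions": "pi_cation",
    "water bridges": "other",
    "halogen bonds": "other",
    "metal complexes": "other",
}


def ingest_plip_report(
    path: str | Path, complex_id: str | None = None, include_other: bool = True
) -> InteractionProfile:
    """Map a PLIP report (XML or text) for one complex onto an InteractionProfile.

    Water bridges, halogen bonds and metal complexes are mapped to type
    ``other``; ``include_other=False`` drops them from d_i.
    """
    path = Path(path)
    text = path.read_text()
    records: list[InteractionRecord] = []
    if text.lstrip().startswith("<"):
        import xml.etree.ElementTree as ET

        root = ET.fromstring(text)
        for section, itype in _PLIP_XML_SECTIONS.items():
            for sec in root.iter(section):
                for child in sec:
                    resname = (child.findtext("restype") or "UNK").strip()
                    resseq = (child.findtext("resnr") or "0").strip()
                    chain = (child.findtext("reschain") or "?").strip()
                    dist = None
                    for tag in ("dist", "dist_d-a", "dist_h-a", "centdist"):
                        if child.findtext(tag):
                            dist = float(child.findtext(tag))
                            break
                    records.append(InteractionRecord(
                        type=itype, residue=f"{resname}{resseq}:{chain}",
                        ligand_atoms=(), distance=dist if dist else 1.0,
                    ))
    else:
        current: str | None = None
        header_seen = 0
        for line in text.splitlines():
            stripped = line.strip()
            low = stripped.lower().strip("*").strip()
            if stripped.startswith("**"):
                current = _PLIP_TXT_SECTIONS.get(low)
                header_seen = 0
                continue
            if current and stripped.startswith("|"):
                if set(stripped) <= {"|", "-", "+", "=", " "}:
                    continue
                header_seen += 1
                if header_seen == 1:  # column-header row
                    continue
                records.append(InteractionRecord(
                    type=current, residue="UNK0:?", ligand_atoms=(), distance=1.0,
                ))
        if current is None and "|" not in text and "<" not in text:
            raise ValueError(f"{path}: unrecognized PLIP report schema")
    if not include_other:
        records = [r for r in records if r.type != "other"]
    return InteractionProfile(complex_id=complex_id or path.stem, records=records)


def profiles_to_frame(profiles: Iterable[InteractionProfile]):
    """Flatten profiles to a tidy DataFrame (complex_id, type, residue, distance, d_i)."""
    import pandas as pd

    rows = []
    for p in profiles:
        if not p.records:
            rows.append({"complex_id": p.complex_id, "type": None,
                         "residue": None, "distance": None, "d_i": 0})
        for r in p.records:
            rows.append({"complex_id": p.complex_id, "type": r.type,
                         "residue": r.residue, "distance": r.distance, "d_i": p.d_i})
    return pd.DataFrame(rows)
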