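"""Molecular graph data model, edge construction/typing, and file I/O.

A molecule is a fixed bond graph — atomic numbers ``Z``, undirected bonds
with orders, optional 3D coordinates in Angstrom. Two directed edge sets
drive the encoders:

* *local* edges: covalent bonds typed by bond order, plus auxiliary edges
  joining atoms at covalent-graph distance 2 or 3 (each hop count its own
  edge type);
* *spatial* edges: all remaining atom pairs within a distance cutoff
  (inclusive at the boundary), sharing a single "spatial" type.

Edge-type vocabulary (fixed): 0 single, 1 double, 2 triple, 3 aromatic,
4 two-hop, 5 three-hop, 6 spatial.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOND_SINGLE", "BOND_DOUBLE", "BOND_TRIPLE", "BOND_AROMATIC",
    "EDGE_TWO_HOP", "EDGE_THREE_HOP", "EDGE_SPATIAL", "EDGE_TYPE_NAMES",
    "MoleculeGraph", "EdgeSet", "InvalidGraphError",
    "build_local_edges", "build_spatial_edges", "edge_lengths",
    "merge_edges", "read_molecules", "write_conformers",
]

BOND_SINGLE = 0
BOND_DOUBLE = 1
BOND_TRIPLE = 2
BOND_AROMATIC = 3
EDGE_TWO_HOP = 4
EDGE_THREE_HOP = 5
EDGE_SPATIAL = 6

EDGE_TYPE_NAMES = {
    BOND_SINGLE: "single", BOND_DOUBLE: "double", BOND_TRIPLE: "triple",
    BOND_AROMATIC: "aromatic", EDGE_TWO_HOP: "2-hop",
    EDGE_THREE_HOP: "3-hop", EDGE_SPATIAL: "spatial",
}

_BOND_ORDER_NAMES = {"single": BOND_SINGLE, "double": BOND_DOUBLE,
                     "triple": BOND_TRIPLE, "aromatic": BOND_AROMATIC}


class InvalidGraphError(ValueError):
    """Raised for malformed molecular graphs or edge inputs."""


@dataclass
class MoleculeGraph:
    """Atoms, typed undirected bonds and optional coordinates.

    Parameters
    ----------
    atom_numbers : array of int
        Atomic numbers Z, one per atom.
    bonds : list of (i, j, order)
        Each undirected bond once; `order` is one of the covalent codes
        0..3 or the strings single/double/triple/aromatic.
    coords : (n_atoms, 3) array, optional
        Positions in Angstrom.
    """

    atom_numbers: np.ndarray
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    coords: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.atom_numbers = np.asarray(self.atom_numbers, dtype=np.int64)
        n = self.n_atoms
        if n < 1:
            raise InvalidGraphError("molecule must have at least one atom")
        norm_bonds = []
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.bonds:
            if isinstance(order, str):
                order = _BOND_ORDER_NAMES[order]
            if not (0 <= i < n and 0 <= j < n):
                raise InvalidGraphError(
                    f"bond ({i},{j}) out of range for {n} atoms")
            if i == j:
                raise InvalidGraphError(f"self-bond on atom {i}")
            if order not in (BOND_SINGLE, BOND_DOUBLE, BOND_TRIPLE,
                             BOND_AROMATIC):
                raise InvalidGraphError(f"unknown bond order {order!r}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise InvalidGraphError(f"duplicate bond {key}")
            seen.add(key)
            norm_bonds.append((int(i), int(j), int(order)))
        self.bonds = norm_bonds
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.shape != (n, 3):
                raise InvalidGraphError(
                    f"coords shape {self.coords.shape} != ({n}, 3)")
            if not np.all(np.isfinite(self.coords)):
                raise InvalidGraphError("coords contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_numbers)

    def heavy_mask(self) -> np.ndarray:
        return self.atom_numbers != 1


@dataclass
class EdgeSet:
    """Directed typed edges; every (i, j) has its reverse (j, i) with equal type."""

    pairs: np.ndarray            # (n_edges, 2) int
    types: np.ndarray            # (n_edges,) int
    is_local: np.ndarray         # (n_edges,) bool
    lengths: np.ndarray | None = None

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.types = np.asarray(self.types, dtype=np.int64).reshape(-1)
        self.is_local = np.asarray(self.is_local, dtype=bool).reshape(-1)
        if not (len(self.pairs) == len(self.types) == len(self.is_local)):
            raise InvalidGraphError("edge field lengths disagree")
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths, dtype=np.float64).reshape(-1)
            if len(self.lengths) != len(self.pairs):
                raise InvalidGraphError("lengths do not match edge count")

    def __len__(self) -> int:
        return len(self.pairs)

    @staticmethod
    def empty() -> "EdgeSet":
        return EdgeSet(np.empty((0, 2), dtype=np.int64),
                       np.empty(0, dtype=np.int64),
                       np.empty(0, dtype=bool))

    def undirected_pairs(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j in self.pairs}


def _directed(und_pairs: list[tuple[int, int]], types: list[int],
              local: bool) -> EdgeSet:
    """Expand undirected pairs into both directions."""
    if not und_pairs:
        return EdgeSet.empty()
    pairs, ts = [], []
    for (i, j), t in zip(und_pairs, types):
        pairs.append((i, j))
        pairs.append((j, i))
        ts.extend((t, t))
    return EdgeSet(np.array(pairs), np.array(ts),
                   np.full(len(pairs), local))


def build_local_edges(mol: MoleculeGraph) -> EdgeSet:
    """Covalent edges typed by bond order, plus 2-hop and 3-hop edges.

    Hop edges are derived from the covalent graph only; a pair reachable
    at several hop counts gets the smallest, and covalent bonds are never
    re-typed as hop edges.
    """
    n = mol.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    bond_type: dict[tuple[int, int], int] = {}
    for i, j, order in mol.bonds:
        adj[i].append(j)
        adj[j].append(i)
        bond_type[(min(i, j), max(i, j))] = order

    und_pairs = [(min(i, j), max(i, j)) for i, j, _ in mol.bonds]
    und_types = [bond_type[p] for p in und_pairs]

    # BFS to depth 3 from each atom for hop edges
    hop_code = {2: EDGE_TWO_HOP, 3: EDGE_THREE_HOP}
    for src in range(n):
        dist = {src: 0}
        frontier = [src]
        for depth in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = depth
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if d in (2, 3) and src < v:
                key = (src, v)
                if key not in bond_type:  # covalent wins
                    und_pairs.append(key)
                    und_types.append(hop_code[d])
    return _directed(und_pairs, und_types, local=True)


def build_spatial_edges(coords: np.ndarray, cutoff: float = 10.0,
                        exclude: EdgeSet | None = None) -> EdgeSet:
    """All atom pairs within `cutoff` (inclusive) not present in `exclude`."""
    coords = np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise InvalidGraphError("non-finite coordinates")
    if cutoff <= 0:
        raise InvalidGraphError("cutoff must be positive")
    n = len(coords)
    excluded = exclude.undirected_pairs() if exclude is not None else set()
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    keep = dist[iu, ju] <= cutoff
    und_pairs = [(int(i), int(j)) for i, j, k in zip(iu, ju, keep)
                 if k and (int(i), int(j)) not in excluded]
    return _directed(und_pairs, [EDGE_SPATIAL] * len(und_pairs), local=False)


def edge_lengths(coords: np.ndarray, edges: EdgeSet) -> EdgeSet:
    """Return a copy of `edges` with Euclidean lengths attached."""
    coords = np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise InvalidGraphError("non-finite coordinates")
    if len(edges) == 0:
        return EdgeSet(edges.pairs, edges.types, edges.is_local,
                       np.empty(0))
    d = coords[edges.pairs[:, 0]] - coords[edges.pairs[:, 1]]
    return EdgeSet(edges.pairs, edges.types, edges.is_local,
                   np.linalg.norm(d, axis=1))


def merge_edges(*sets: EdgeSet) -> EdgeSet:
    """Concatenate edge sets (lengths kept only if all inputs carry them)."""
    sets = [s for s in sets if len(s) > 0]
    if not sets:
        return EdgeSet.empty()
    lengths = None
    if all(s.lengths is not None for s in sets):
        lengths = np.concatenate([s.lengths for s in sets])
    return EdgeSet(np.concatenate([s.pairs for s in sets]),
                   np.concatenate([s.types for s in sets]),
                   np.concatenate([s.is_local for s in sets]),
                   lengths)


# ---------------------------------------------------------------------------
# File I/O (RDKit-backed)

_RD_ORDER = {}


def _rdkit():
    from rdkit import Chem
    global _RD_ORDER
    if not _RD_ORDER:
        _RD_ORDER = {
            Chem.BondType.SINGLE: BOND_SINGLE,
            Chem.BondType.DOUBLE: BOND_DOUBLE,
            Chem.BondType.TRIPLE: BOND_TRIPLE,
            Chem.BondType.AROMATIC: BOND_AROMATIC,
        }
    return Chem


class FormatError(ValueError):
    """Raised when an input file fails to parse."""


def _mol_from_rdkit(rdmol, name: str, with_coords: bool) -> MoleculeGraph:
    Chem = _rdkit()
    atom_numbers = [a.GetAtomicNum() for a in rdmol.GetAtoms()]
    bonds = []
    for b in rdmol.GetBonds():
        order = _RD_ORDER.get(b.GetBondType())
        if order is None:
            raise FormatError(
                f"unsupported bond type {b.GetBondType()} in {name!r}")
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    coords = None
    if with_coords and rdmol.GetNumConformers() > 0:
        coords = np.array(rdmol.GetConformer().GetPositions(), dtype=np.float64)
    return MoleculeGraph(np.array(atom_numbers), bonds, coords, name=name)


def read_molecules(path: str, fmt: str | None = None) -> list[MoleculeGraph]:
    """Read molecules from SDF, SMILES (one per line) or XYZ.

    SMILES input yields topology-only graphs (no coords). An empty file
    yields an empty list.
    """
    Chem = _rdkit()
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower() or "sdf"
        if fmt in ("smi", "smiles"):
            fmt = "smiles"
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    mols: list[MoleculeGraph] = []
    if fmt == "sdf":
        if os.path.getsize(path) == 0:
            return []
        supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=True)
        for k, rdmol in enumerate(supplier):
            if rdmol is None:
                raise FormatError(f"record {k} of {path!r} failed to parse")
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"mol{k}"
            mols.append(_mol_from_rdkit(rdmol, name, with_coords=True))
    elif fmt == "smiles":
        with open(path) as fh:
            for k, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                smi = line.split()[0]
                rdmol = Chem.MolFromSmiles(smi)
                if rdmol is None:
                    raise FormatError(f"line {k + 1} of {path!r}: bad SMILES {smi!r}")
                rdmol = Chem.AddHs(rdmol)
                mols.append(_mol_from_rdkit(rdmol, smi, with_coords=False))
    elif fmt == "xyz":
        mols.extend(_read_xyz(path))
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return mols


def _read_xyz(path: str) -> list[MoleculeGraph]:
    from rdkit.Chem import GetPeriodicTable

    pt = GetPeriodicTable()
    mols = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    rec = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
            title = lines[pos + 1].strip() if pos + 1 < len(lines) else ""
            zs, xyz = [], []
            for ln in lines[pos + 2:pos + 2 + n]:
                sym, x, y, z = ln.split()[:4]
                zs.append(pt.GetAtomicNumber(sym))
                xyz.append((float(x), float(y), float(z)))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"record {rec} of {path!r}: {exc}") from exc
        mols.append(MoleculeGraph(np.array(zs), [], np.array(xyz),
                                  name=title or f"xyz{rec}"))
        pos += 2 + n
        rec += 1
    return mols


def _to_rdkit(mol: MoleculeGraph, coords: np.ndarray):
    Chem = _rdkit()
    from rdkit.Geometry import Point3D

    rev = {v: k for k, v in _RD_ORDER.items()}
    em = Chem.RWMol()
    for z in mol.atom_numbers:
        a = Chem.Atom(int(z))
        a.SetNoImplicit(True)
        em.AddAtom(a)
    for i, j, order in mol.bonds:
        em.AddBond(i, j, rev[order])
    rd = em.GetMol()
    Chem.SanitizeMol(rd, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                     | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY)
    conf = Chem.Conformer(mol.n_atoms)
    for k, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(k, Point3D(x, y, z))
    rd.AddConformer(conf)
    rd.SetProp("_Name", mol.name or "mol")
    return rd


def write_conformers(path: str, entries: list[tuple[MoleculeGraph, np.ndarray]]) -> None:
    """Write (molecule, coords) pairs as a multi-record V2000 SDF."""
    Chem = _rdkit()
    writer = Chem.SDWriter(path)
    writer.SetForceV3000(False)
    try:
        for mol, coords in entries:
            writer.write(_to_rdkit(mol, coords))
    finally:
        writer.close()


def write_xyz(path: str, frames: list[np.ndarray],
              atom_numbers: np.ndarray, comment: str = "") -> None:
    """Dump coordinate frames as a multi-record XYZ trajectory."""
    from rdkit.Chem import GetPeriodicTable

    pt = GetPeriodicTable()
    syms = [pt.GetElementSymbol(int(z)) for z in atom_numbers]
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            fh.write(f"{len(syms)}\n{comment or 'frame'} {k}\n")
            for sym, (x, y, z) in zip(syms, np.asarray(frame, dtype=float)):
                fh.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")
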