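"""Deterministic toy-molecule templates and reference ensembles.

Every other module is testable without downloads: these templates build
exact idealized geometries — a tetrahedral center, a straight chain, a
planar regular ring, and a zig-zag torsion chain with user-specified
dihedrals — together with matching bond graphs. Reference ensembles are
seeded Gaussian jitters of the ideal geometry.

The templates emulate rigid single-conformer molecules, not force-field
ensembles; they exercise graph/edge logic, equivariance and the
diffusion machinery, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molgraph import BOND_AROMATIC, BOND_SINGLE, MoleculeGraph

__all__ = ["ToySpec", "ToySpecError", "make_toy", "make_reference_ensemble",
           "ConformerSet"]

TEMPLATES = ("tetrahedral_center", "linear_chain", "ring", "torsion_chain")
TET_ANGLE = np.arccos(-1.0 / 3.0)  # 109.47 deg


class ToySpecError(ValueError):
    """Impossible toy-molecule specification."""


@dataclass
class ToySpec:
    """Template parameters for one toy molecule.

    n_atoms is the total atom count (ring size for `ring`; 1 + n-1
    substituents for `tetrahedral_center`, which requires exactly 5).
    `elements` assigns atomic numbers; default all-carbon.
    """

    template: str = "tetrahedral_center"
    n_atoms: int = 5
    bond_length: float = 1.54
    torsions: list[float] = field(default_factory=list)  # degrees
    elements: list[int] | None = None
    aromatic: bool = False
    name: str = ""

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ToySpecError(f"unknown template {self.template!r}")
        if self.bond_length <= 0:
            raise ToySpecError("bond_length must be positive")
        if self.template == "tetrahedral_center" and self.n_atoms != 5:
            raise ToySpecError("tetrahedral_center requires n_atoms=5")
        if self.template == "ring" and self.n_atoms < 3:
            raise ToySpecError("ring requires at least 3 atoms")
        if self.template in ("linear_chain", "torsion_chain") and self.n_atoms < 2:
            raise ToySpecError("chain requires at least 2 atoms")
        if self.aromatic and self.template != "ring":
            raise ToySpecError("aromatic bonds only apply to the ring template")


@dataclass
class ConformerSet:
    """A conformer ensemble: coordinate frames sharing one bond graph."""

    molecule: MoleculeGraph
    frames: list[np.ndarray]
    role: str = "reference"  # or "generated"

    def __post_init__(self):
        n = self.molecule.n_atoms
        self.frames = [np.asarray(f, dtype=np.float64) for f in self.frames]
        for f in self.frames:
            if f.shape != (n, 3):
                raise ValueError(f"frame shape {f.shape} != ({n}, 3)")

    def __len__(self) -> int:
        return len(self.frames)


def _tetrahedral(r: float) -> np.ndarray:
    # center at origin, four substituents at alternate cube vertices
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                    dtype=np.float64) / np.sqrt(3.0)
    return np.vstack([np.zeros(3), r * dirs])


def _chain_coords(n: int, r: float, torsions: list[float]) -> np.ndarray:
    """Zig-zag chain with tetrahedral bond angles placed by internal coordinates."""
    coords = [np.zeros(3), np.array([r, 0.0, 0.0])]
    if n > 2:
        coords.append(coords[1] + r * np.array([np.cos(np.pi - TET_ANGLE),
                                                np.sin(np.pi - TET_ANGLE), 0.0]))
    for k in range(3, n):
        tau = np.deg2rad(torsions[k - 3] if k - 3 < len(torsions) else 180.0)
        a, b, c = coords[k - 3], coords[k - 2], coords[k - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        n1 = np.cross(ab, bc)
        n1 /= np.linalg.norm(n1)
        m = np.cross(n1, bc)
        d = (-bc * np.cos(TET_ANGLE)
             + m * np.sin(TET_ANGLE) * np.cos(tau)
             - n1 * np.sin(TET_ANGLE) * np.sin(tau))
        coords.append(c + r * d)
    return np.array(coords)


def make_toy(spec: ToySpec) -> MoleculeGraph:
    """Build the exact idealized geometry and bond graph for `spec`."""
    n, r = spec.n_atoms, spec.bond_length
    if spec.template == "tetrahedral_center":
        coords = _tetrahedral(r)
        bonds = [(0, k, BOND_SINGLE) for k in range(1, 5)]
    elif spec.template == "linear_chain":
        coords = np.zeros((n, 3))
        coords[:, 0] = r * np.arange(n)
        bonds = [(k, k + 1, BOND_SINGLE) for k in range(n - 1)]
    elif spec.template == "ring":
        radius = r / (2.0 * np.sin(np.pi / n))
        ang = 2.0 * np.pi * np.arange(n) / n
        coords = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                           np.zeros(n)], axis=1)
        order = BOND_AROMATIC if spec.aromatic else BOND_SINGLE
        bonds = [(k, (k + 1) % n, order) for k in range(n)]
    else:  # torsion_chain
        coords = _chain_coords(n, r, spec.torsions)
        bonds = [(k, k + 1, BOND_SINGLE) for k in range(n - 1)]
    elements = spec.elements if spec.elements is not None else [6] * n
    if len(elements) != n:
        raise ToySpecError("elements length must equal n_atoms")
    return MoleculeGraph(np.array(elements), bonds, coords,
                         name=spec.name or spec.template)


def make_reference_ensemble(spec: ToySpec, n_frames: int, jitter_sd: float,
                            seed: int) -> ConformerSet:
    """n_frames seeded Gaussian jitters of the ideal geometry.

    jitter_sd is the per-coordinate standard deviation in Angstrom;
    jitter_sd=0 gives identical frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    mol = make_toy(spec)
    rng = np.random.default_rng(seed)
    frames = [mol.coords + jitter_sd * rng.standard_normal(mol.coords.shape)
              for _ in range(n_frames)]
    return ConformerSet(mol, frames, role="reference")
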