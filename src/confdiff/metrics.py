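"""Conformer-ensemble evaluation.

RMSD uses Kabsch superposition (proper rotations only) after centering;
with symmetry correction on, it is minimized over graph automorphisms of
the bond graph (capped enumeration, identity fallback). Ensemble quality
and diversity are summarized with the recall/precision coverage and
matching statistics:

    COV-R = % of reference conformers whose nearest generated RMSD <= delta
    MAT-R = mean over references of the nearest generated RMSD

with COV-P / MAT-P swapping the roles of the two sets. Torsion analysis
provides signed dihedrals and a periodic 2D kernel density over
(phi, psi) built from the 3x3 tiling of the samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde, pearsonr

from .molgraph import MoleculeGraph
from .toydata import ConformerSet

__all__ = [
    "MetricsReport", "min_rmsd", "kabsch_rmsd", "automorphisms", "cov_mat",
    "rmsd_matrix", "best_k", "property_correlations", "dihedral",
    "ramachandran_density", "trajectory_rmsd",
]

AUTOMORPHISM_CAP = 10_000


@dataclass
class MetricsReport:
    """Per-molecule COV/MAT summary; reproducible from the RMSD matrix."""

    delta: float
    cov_r: float
    mat_r: float
    cov_p: float
    mat_p: float
    rmsd: np.ndarray = field(repr=False)  # (|Sg|, |Sr|)
    automorphism_fallback: bool = False

    def to_dict(self) -> dict:
        return {"delta": self.delta, "COV-R": self.cov_r, "MAT-R": self.mat_r,
                "COV-P": self.cov_p, "MAT-P": self.mat_p}


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD (proper rotation + translation removed)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape} vs {b.shape}")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if len(a) == 1:
        return 0.0
    with warnings.catch_warnings():
        # planar/collinear point sets make the optimal rotation non-unique;
        # the residual (all we use) is still well-defined
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(a)))


def automorphisms(mol: MoleculeGraph, cap: int = AUTOMORPHISM_CAP
                  ) -> tuple[list[np.ndarray], bool]:
    """Bond-graph automorphisms (element- and order-preserving).

    Returns (mappings, fell_back); when more than `cap` mappings exist
    only the identity is returned and fell_back is True.
    """
    import networkx as nx
    from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match

    g = nx.Graph()
    for k, z in enumerate(mol.atom_numbers):
        g.add_node(k, z=int(z))
    for i, j, order in mol.bonds:
        g.add_edge(i, j, order=order)
    matcher = GraphMatcher(
        g, g, node_match=categorical_node_match("z", 0),
        edge_match=lambda e1, e2: e1["order"] == e2["order"])
    maps: list[np.ndarray] = []
    for mapping in matcher.isomorphisms_iter():
        maps.append(np.array([mapping[k] for k in range(mol.n_atoms)]))
        if len(maps) > cap:
            return [np.arange(mol.n_atoms)], True
    return maps, False


def min_rmsd(a: np.ndarray, b: np.ndarray, mol: MoleculeGraph | None = None,
             mode: str = "heavy", symmetry: bool = True) -> float:
    """Minimal RMSD between two frames.

    mode="heavy" drops hydrogens (requires `mol`); symmetry=True minimizes
    over bond-graph automorphisms (also requires `mol`). Without `mol`
    the plain all-atom Kabsch RMSD is returned.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape} vs {b.shape}")
    if mol is None:
        return kabsch_rmsd(a, b)
    mask = mol.heavy_mask() if mode == "heavy" else np.ones(mol.n_atoms, bool)
    if not symmetry:
        return kabsch_rmsd(a[mask], b[mask])
    maps, _ = automorphisms(mol)
    best = np.inf
    for perm in maps:
        # permuted atoms must stay within the selected subset
        if not np.array_equal(mask[perm], mask):
            continue
        best = min(best, kabsch_rmsd(a[mask], b[perm][mask]))
    return best


def rmsd_matrix(gen: ConformerSet, ref: ConformerSet, mode: str = "heavy",
                symmetry: bool = True) -> np.ndarray:
    """(|Sg|, |Sr|) matrix of minimal RMSDs."""
    mol = gen.molecule
    maps, _ = automorphisms(mol) if symmetry else ([np.arange(mol.n_atoms)], False)
    mask = mol.heavy_mask() if mode == "heavy" else np.ones(mol.n_atoms, bool)
    maps = [p for p in maps if np.array_equal(mask[p], mask)]
    out = np.empty((len(gen), len(ref)))
    for gi, gf in enumerate(gen.frames):
        for ri, rf in enumerate(ref.frames):
            out[gi, ri] = min(kabsch_rmsd(gf[mask], rf[perm][mask])
                              for perm in maps)
    return out


def cov_mat(gen: ConformerSet, ref: ConformerSet, delta: float,
            mode: str = "heavy", symmetry: bool = True,
            rmsd: np.ndarray | None = None) -> MetricsReport:
    """Coverage/matching recall and precision at threshold `delta` (Angstrom).

    COV values are percentages in [0, 100]. A precomputed RMSD matrix
    (generated rows x reference columns) may be supplied.
    """
    if len(gen) == 0 or len(ref) == 0:
        which = "generated" if len(gen) == 0 else "reference"
        raise ValueError(f"{which} conformer set is empty")
    if rmsd is None:
        rmsd = rmsd_matrix(gen, ref, mode=mode, symmetry=symmetry)
    nearest_gen = rmsd.min(axis=0)   # per reference
    nearest_ref = rmsd.min(axis=1)   # per generated
    _, fallback = automorphisms(gen.molecule) if symmetry else ([], False)
    return MetricsReport(
        delta=delta,
        cov_r=100.0 * float(np.mean(nearest_gen <= delta)),
        mat_r=float(nearest_gen.mean()),
        cov_p=100.0 * float(np.mean(nearest_ref <= delta)),
        mat_p=float(nearest_ref.mean()),
        rmsd=rmsd,
        automorphism_fallback=fallback,
    )


def best_k(gen: ConformerSet, ref: ConformerSet, k: int = 5,
           mode: str = "heavy", symmetry: bool = True,
           rmsd: np.ndarray | None = None) -> list[float]:
    """The k smallest per-generated-frame minima over references, ascending.

    Ties are broken by generated-frame index (stable sort).
    """
    if k > len(gen):
        raise ValueError(f"k={k} exceeds |generated|={len(gen)}")
    if rmsd is None:
        rmsd = rmsd_matrix(gen, ref, mode=mode, symmetry=symmetry)
    minima = rmsd.min(axis=1)
    order = np.argsort(minima, kind="stable")
    return [float(minima[i]) for i in order[:k]]


def property_correlations(rmsd_means: dict[str, float],
                          properties) -> dict[str, float | None]:
    """Pearson correlation of per-molecule mean RMSD with each property column.

    `properties` is a DataFrame indexed by molecule id (or convertible);
    a constant column has undefined correlation and is reported as None.
    """
    import pandas as pd

    props = pd.DataFrame(properties)
    ids = [i for i in props.index if i in rmsd_means]
    if len(ids) < 3:
        raise ValueError("need at least 3 molecules with aligned ids")
    y = np.array([rmsd_means[i] for i in ids], dtype=float)
    out: dict[str, float | None] = {}
    for col in props.columns:
        x = props.loc[ids, col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[col] = None
        else:
            out[col] = float(pearsonr(x, y)[0])
    return out


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, in (-180, 180].

    Standard atan2 construction; raises on collinear degeneracies.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("undefined dihedral: three consecutive points collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = float(np.degrees(np.arctan2(m @ n2, n1 @ n2)))
    return 180.0 if np.isclose(ang, -180.0) else ang


def ramachandran_density(phi_psi: np.ndarray, bandwidth: float | str = "scott",
                         grid: int = 180):
    """Periodic 2D KDE over (phi, psi) in degrees.

    The estimator is fitted on the 3x3 tiling of the samples (images
    shifted by -360/0/+360 on each axis) and evaluated on a `grid` x
    `grid` cell-center lattice over [-180, 180)^2, then normalized to
    integrate to 1 over the grid.

    Returns (phi_centers, psi_centers, density).
    """
    phi_psi = np.asarray(phi_psi, dtype=np.float64).reshape(-1, 2)
    if len(phi_psi) < 2:
        raise ValueError("need at least 2 (phi, psi) samples")
    shifts = np.array([-360.0, 0.0, 360.0])
    tiled = np.concatenate([phi_psi + np.array([a, b])
                            for a in shifts for b in shifts])
    kde = gaussian_kde(tiled.T, bw_method=bandwidth)
    step = 360.0 / grid
    centers = -180.0 + step * (np.arange(grid) + 0.5)
    pp, ss = np.meshgrid(centers, centers, indexing="ij")
    dens = kde(np.vstack([pp.ravel(), ss.ravel()])).reshape(grid, grid)
    dens /= dens.sum() * step * step
    return centers, centers, dens


def trajectory_rmsd(trajectories, reference: np.ndarray,
                    mol: MoleculeGraph | None = None, mode: str = "heavy",
                    symmetry: bool = False):
    """Per-frame minimal RMSD to `reference` for one or more trajectories.

    `trajectories` is a list of frames, or a list of such lists; returns
    (per-trajectory series array, mean curve).
    """
    first = trajectories[0]
    if isinstance(first, np.ndarray) and first.ndim == 2:
        trajectories = [trajectories]
    series = np.array([
        [min_rmsd(frame, reference, mol=mol, mode=mode, symmetry=symmetry)
         for frame in traj]
        for traj in trajectories])
    return series, series.mean(axis=0)
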