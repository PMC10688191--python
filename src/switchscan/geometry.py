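"""Residue atom selection, triplet enumeration, and trajectory geometry.

Each residue is treated as a rigid body described by a reduced set of
atoms (backbone plus side-chain branch points and terminal heteroatoms).
The local conformation of the residue is then captured by the planar
angles formed by every combination of three selected atoms: a selection
of k atoms yields C(k, 3) angles.  This module enumerates those angle
triplets and measures them — together with RMSD and residue-pair
distances — on MD trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ResidueSelection",
    "AtomTriplet",
    "AngleSeries",
    "TrajectorySet",
    "load_selection_table",
    "selected_atoms",
    "enumerate_triplets",
    "angle",
    "angle_series",
    "rmsd_series",
    "pair_distance_series",
]

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


# ---------------------------------------------------------------------------
# Selection table and triplet enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueSelection:
    """Ordered rigid-body atom selection for one residue type.

    Atoms are in topological order (N, CA, CB, side chain outward, C, O);
    the order defines the vertex convention for angle triplets.
    """

    residue_name: str
    atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(
                f"duplicate atom names in selection for {self.residue_name}: {self.atoms}"
            )
        if len(self.atoms) < 3:
            raise ValueError(
                f"selection for {self.residue_name} has {len(self.atoms)} atoms; "
                "at least 3 are required to form an angle"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_triplets(self) -> int:
        k = self.n_atoms
        return k * (k - 1) * (k - 2) // 6


@dataclass(frozen=True)
class AtomTriplet:
    """One unordered atom triplet, canonicalized.

    ``vertex`` is the middle atom under the selection's topological order;
    ``atom_a`` precedes ``atom_b`` in that order.  The measured quantity is
    the angle at ``vertex`` between the arms to ``atom_a`` and ``atom_b``.
    """

    residue_index: int
    atom_a: str
    vertex: str
    atom_b: str

    @property
    def atoms(self) -> tuple[str, str, str]:
        return (self.atom_a, self.vertex, self.atom_b)

    @property
    def label(self) -> str:
        return f"{self.atom_a}-{self.vertex}-{self.atom_b}"


@dataclass
class AngleSeries:
    """Per-frame values of one three-atom angle, pooled across trajectories.

    ``segments`` records the [start, end) frame range contributed by each
    source trajectory so that downstream transition counting never crosses
    a trajectory seam.
    """

    triplet: AtomTriplet
    values: np.ndarray
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("angle series must be one-dimensional")
        if not self.segments:
            self.segments = [(0, len(self.values))]
        if self.values.size and (
            self.values.min() < -1e-9 or self.values.max() > math.pi + 1e-9
        ):
            raise ValueError("angle values must lie in [0, pi]")
        covered = sorted(self.segments)
        if covered[0][0] != 0 or covered[-1][1] != len(self.values):
            raise ValueError("segments must partition the frame range")
        for (_, e0), (s1, _) in zip(covered, covered[1:]):
            if e0 != s1:
                raise ValueError("segments must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return len(self.values)


def load_selection_table(path: str | Path | None = None) -> dict[str, ResidueSelection]:
    """Load the rigid-body selection table (built-in YAML by default)."""
    if path is None:
        with resources.files("switchscan.data").joinpath("selection_table.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {
        name: ResidueSelection(name, tuple(atoms)) for name, atoms in raw.items()
    }


_BUILTIN_TABLE: dict[str, ResidueSelection] | None = None


def _builtin_table() -> dict[str, ResidueSelection]:
    global _BUILTIN_TABLE
    if _BUILTIN_TABLE is None:
        _BUILTIN_TABLE = load_selection_table()
    return _BUILTIN_TABLE


def selected_atoms(
    residue_name: str, table: dict[str, ResidueSelection] | None = None
) -> ResidueSelection:
    """Return the rigid-body atom selection for a 3-letter residue code."""
    name = residue_name.upper()
    table = table if table is not None else _builtin_table()
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"no atom selection for residue {residue_name!r}; "
            f"known residues: {sorted(table)}"
        ) from None


def enumerate_triplets(
    selection: ResidueSelection, residue_index: int = 0
) -> list[AtomTriplet]:
    """Enumerate all C(k,3) canonical angle triplets of a selection.

    Output order is lexicographic by topological atom indices; each triplet
    is canonicalized with the middle atom as vertex.
    """
    atoms = selection.atoms
    return [
        AtomTriplet(residue_index, atoms[i], atoms[j], atoms[k])
        for i, j, k in combinations(range(len(atoms)), 3)
    ]


# ---------------------------------------------------------------------------
# Angle computation
# ---------------------------------------------------------------------------

def angle(p_a: Sequence[float], p_vertex: Sequence[float], p_b: Sequence[float]) -> float:
    """Planar angle at ``p_vertex`` between the arms to ``p_a`` and ``p_b``.

    Returns arccos of the normalized dot product, clamped to [-1, 1];
    result in [0, pi] radians.
    """
    u = np.asarray(p_a, dtype=float) - np.asarray(p_vertex, dtype=float)
    v = np.asarray(p_b, dtype=float) - np.asarray(p_vertex, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: one arm has zero length")
    c = float(np.dot(u, v) / (nu * nv))
    return math.acos(max(-1.0, min(1.0, c)))


def _angles_vectorized(xyz_a: np.ndarray, xyz_v: np.ndarray, xyz_b: np.ndarray) -> np.ndarray:
    u = xyz_a - xyz_v
    v = xyz_b - xyz_v
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = (nu == 0) | (nv == 0)
    if bad.any():
        frame = int(np.nonzero(bad)[0][0])
        raise ValueError(f"degenerate angle at frame {frame}: zero-length arm")
    c = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.arccos(np.clip(c, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Trajectory handling (mdtraj-backed)
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySet:
    """Frames pooled from one or more trajectories sharing a topology.

    ``xyz`` has shape (n_frames, n_atoms, 3) in float64; ``segments`` holds
    one [start, end) range per source trajectory, in input order.
    """

    topology: "object"  # mdtraj.Topology
    xyz: np.ndarray
    segments: list[tuple[int, int]]
    sources: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @classmethod
    def from_files(
        cls, topology_path: str | Path, trajectory_paths: Iterable[str | Path]
    ) -> "TrajectorySet":
        """Load a PDB topology plus DCD/XTC trajectories, order preserved."""
        import mdtraj as md

        top = md.load_topology(str(topology_path))
        parts: list[np.ndarray] = []
        segments: list[tuple[int, int]] = []
        sources: list[str] = []
        offset = 0
        paths = list(trajectory_paths)
        if not paths:
            raise ValueError("at least one trajectory file is required")
        for p in paths:
            t = md.load(str(p), top=top)
            if t.n_frames == 0:
                raise ValueError(f"trajectory {p} contains no frames")
            parts.append(np.asarray(t.xyz, dtype=float))
            segments.append((offset, offset + t.n_frames))
            offset += t.n_frames
            sources.append(str(p))
        return cls(top, np.concatenate(parts, axis=0), segments, sources)

    def _find_residue(self, residue_index: int):
        for res in self.topology.residues:
            if res.resSeq == residue_index:
                return res
        raise KeyError(f"residue with sequence number {residue_index} not in topology")

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        res = self._find_residue(residue_index)
        for a in res.atoms:
            if a.name == atom_name:
                return a.index
        src = self.sources[0] if self.sources else "<in-memory>"
        raise KeyError(
            f"atom {atom_name!r} not found in residue {res.name}{residue_index} "
            f"(topology from {src})"
        )


def angle_series(
    trajectories: TrajectorySet, residue_index: int, triplet: AtomTriplet
) -> AngleSeries:
    """Measure one triplet's angle on every frame of the pooled trajectories."""
    ia = trajectories.atom_index(residue_index, triplet.atom_a)
    iv = trajectories.atom_index(residue_index, triplet.vertex)
    ib = trajectories.atom_index(residue_index, triplet.atom_b)
    values = _angles_vectorized(
        trajectories.xyz[:, ia], trajectories.xyz[:, iv], trajectories.xyz[:, ib]
    )
    trip = AtomTriplet(residue_index, triplet.atom_a, triplet.vertex, triplet.atom_b)
    return AngleSeries(trip, values, list(trajectories.segments))


# ---------------------------------------------------------------------------
# RMSD and distances
# ---------------------------------------------------------------------------

def rmsd_series(
    trajectories: TrajectorySet,
    reference_frame_index: int = 0,
    atom_indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference frame after optimal rigid superposition.

    Superposition (Kabsch) is solved in float64 over the given atom subset;
    the result is in the coordinate unit of the input (nm for mdtraj loads).
    """
    from scipy.spatial.transform import Rotation

    xyz = trajectories.xyz
    if not 0 <= reference_frame_index < xyz.shape[0]:
        raise IndexError(f"reference frame {reference_frame_index} out of range")
    idx = (
        np.arange(xyz.shape[1])
        if atom_indices is None
        else np.asarray(list(atom_indices), dtype=int)
    )
    if idx.size == 0:
        raise ValueError("atom subset for RMSD must be non-empty")
    if idx.size and (idx.min() < 0 or idx.max() >= xyz.shape[1]):
        raise IndexError("atom subset contains indices outside the topology")
    ref = xyz[reference_frame_index][idx]
    ref_c = ref - ref.mean(axis=0)
    n = idx.size
    out = np.empty(xyz.shape[0])
    for f in range(xyz.shape[0]):
        frm = xyz[f][idx]
        frm_c = frm - frm.mean(axis=0)
        # apply the optimal rotation and measure residuals directly: the
        # rssd reported by align_vectors loses ~1e-8 to cancellation
        rot, _ = Rotation.align_vectors(ref_c, frm_c)
        resid = rot.apply(frm_c) - ref_c
        out[f] = math.sqrt(np.sum(resid**2) / n)
    return out


def pair_distance_series(
    trajectories: TrajectorySet,
    residue_i: int,
    residue_j: int,
    atom_name: str = "CA",
) -> np.ndarray:
    """Per-frame Euclidean distance between the named atom of two residues."""
    ii = trajectories.atom_index(residue_i, atom_name)
    jj = trajectories.atom_index(residue_j, atom_name)
    d = trajectories.xyz[:, ii] - trajectories.xyz[:, jj]
    return np.linalg.norm(d, axis=1)
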