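"""Ensemble descriptors: local gyration profiles, Rg, Dmax, RMSD.

A conformational ensemble of a disordered protein is compared here
through low-resolution geometric descriptors rather than raw
coordinates.  The central one is the local gyration profile: for each
residue n, the rms deviation of the backbone atoms (N, CA, C, O) of
residues within a +/- ``n_win`` window around n from their centroid.
Low values flag locally compact stretches, high values extended ones,
and profiles of different conformations are compared by Euclidean
distance.  Global size is summarized by the radius of gyration (rms
distance of atoms from the centroid, unit masses) and the maximum
interatomic distance; a population-weighted ensemble-level Rg combines
per-conformation radii with mixture populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "BACKBONE_ATOMS",
    "Conformation",
    "GyrationProfile",
    "read_ensemble",
    "write_ensemble",
    "backbone_dihedrals",
    "local_gyration_profile",
    "profile_distance",
    "radius_of_gyration",
    "max_diameter",
    "rmsd",
    "min_cross_distances",
    "ensemble_rg",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Conformation:
    """Atomic coordinates of one candidate conformation.

    ``residue_index`` is 1-based and parallel to ``atom_name`` and
    ``coords`` (Angstrom).
    """

    label: str
    residue_index: np.ndarray
    atom_name: np.ndarray
    coords: np.ndarray
    residue_name: np.ndarray = None

    def __post_init__(self):
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residue_index), 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.residue_name is None:
            self.residue_name = np.full(len(self.residue_index), "GLY", dtype=object)

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue indices present."""
        return np.unique(self.residue_index)

    def backbone_mask(self) -> np.ndarray:
        return np.isin(self.atom_name.astype(str), BACKBONE_ATOMS)


@dataclass
class GyrationProfile:
    """Per-residue local gyration radii (Angstrom); NaN marks undefined."""

    values: np.ndarray
    window: int = 5
    residue_ids: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, len(self.values) + 1)


def _from_atom_array(array, label: str) -> Conformation:
    return Conformation(
        label=label,
        residue_index=array.res_id,
        atom_name=array.atom_name.astype(object),
        coords=array.coord,
        residue_name=array.res_name.astype(object),
    )


def _to_atom_array(c: Conformation):
    n = len(c.residue_index)
    array = struc.AtomArray(n)
    array.res_id = c.residue_index
    array.atom_name = c.atom_name.astype("U6")
    array.res_name = c.residue_name.astype("U5")
    array.chain_id = np.full(n, "A")
    array.element = np.array([str(a)[0] for a in c.atom_name], dtype="U2")
    array.coord = c.coords
    return array


def read_ensemble(path) -> list[Conformation]:
    """Read a multi-model PDB file or a directory of single-model PDBs.

    Returns one :class:`Conformation` per model; labels come from model
    numbers or filenames.  A residue missing any of the four backbone
    atoms triggers a warning (its dihedrals and profile entries come out
    undefined)."""
    path = Path(path)
    confs: list[Conformation] = []
    if path.is_dir():
        files = sorted(path.glob("*.pdb"))
        if not files:
            raise ValueError(f"no .pdb files in {path}")
        for f in files:
            pdb = PDBFile.read(str(f))
            array = pdb.get_structure(model=1)
            confs.append(_from_atom_array(array, f.stem))
    else:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        if n_models == 0:
            raise ValueError(f"no models in {path}")
        for m in range(1, n_models + 1):
            array = pdb.get_structure(model=m)
            confs.append(_from_atom_array(array, f"model_{m}"))
    for c in confs:
        bb = c.backbone_mask()
        for rid in c.residue_ids:
            names = set(c.atom_name[(c.residue_index == rid) & bb].astype(str))
            if not names.issuperset(BACKBONE_ATOMS):
                warnings.warn(
                    f"{c.label}: residue {rid} is missing backbone atoms", stacklevel=2
                )
    return confs


def write_ensemble(confs, path) -> None:
    """Write conformations as a multi-model PDB (all models must share the
    same atom annotation)."""
    arrays = [_to_atom_array(c) for c in confs]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _dihedral(p0, p1, p2, p3):
    # IUPAC sign convention (matches biotite.structure.dihedral)
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w))


def backbone_dihedrals(c: Conformation) -> np.ndarray:
    """(phi, psi) in degrees per residue, shape (n_residues, 2).

    phi(n) uses C(n-1)-N(n)-CA(n)-C(n); psi(n) uses N(n)-CA(n)-C(n)-N(n+1);
    angles are wrapped to (-180, 180].  Chain termini and residues with
    missing backbone atoms come out NaN."""
    rids = c.residue_ids
    pos: dict[tuple[int, str], np.ndarray] = {}
    for rid in rids:
        sel = c.residue_index == rid
        for name in ("N", "CA", "C"):
            match = np.nonzero(sel & (c.atom_name.astype(str) == name))[0]
            if match.size:
                pos[(rid, name)] = c.coords[match[0]]
    out = np.full((len(rids), 2), np.nan)
    for i, rid in enumerate(rids):
        try:
            out[i, 0] = _dihedral(
                pos[(rid - 1, "C")], pos[(rid, "N")], pos[(rid, "CA")], pos[(rid, "C")]
            )
        except KeyError:
            pass
        try:
            out[i, 1] = _dihedral(
                pos[(rid, "N")], pos[(rid, "CA")], pos[(rid, "C")], pos[(rid + 1, "N")]
            )
        except KeyError:
            pass
    return out


def local_gyration_profile(c: Conformation, n_win: int = 5) -> GyrationProfile:
    """Local gyration radius profile P(n) over a +/- ``n_win`` residue window.

    P(n) = sqrt( mean_i ||X_i - X_bar||^2 ) over the backbone atoms of
    residues in [n - n_win, n + n_win] clamped to the chain, X_bar being
    their centroid."""
    bb = c.backbone_mask()
    rids = c.residue_ids
    values = np.full(len(rids), np.nan)
    for i, rid in enumerate(rids):
        sel = bb & (c.residue_index >= rid - n_win) & (c.residue_index <= rid + n_win)
        xyz = c.coords[sel]
        if xyz.shape[0] == 0:
            continue
        centered = xyz - xyz.mean(axis=0)
        values[i] = np.sqrt(np.mean(np.sum(centered**2, axis=1)))
    return GyrationProfile(values=values, window=n_win, residue_ids=rids)


def profile_distance(a: GyrationProfile, b: GyrationProfile) -> float:
    """Euclidean distance between two equal-length profiles; positions
    undefined in either profile are excluded pairwise."""
    if len(a.values) != len(b.values):
        raise ValueError("profiles must have equal length")
    ok = np.isfinite(a.values) & np.isfinite(b.values)
    return float(np.linalg.norm(a.values[ok] - b.values[ok]))


def radius_of_gyration(c: Conformation, backbone_only: bool = False) -> float:
    """Rg: rms distance of atoms from their centroid, unit masses."""
    xyz = c.coords[c.backbone_mask()] if backbone_only else c.coords
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def max_diameter(c: Conformation, backbone_only: bool = False) -> float:
    """Dmax: maximum pairwise interatomic distance."""
    xyz = c.coords[c.backbone_mask()] if backbone_only else c.coords
    if xyz.shape[0] < 2:
        raise ValueError("Dmax needs at least 2 atoms")
    return float(pdist(xyz).max())


def _matched_backbone(a: Conformation, b: Conformation):
    keys_a = {(int(r), str(n)): i for i, (r, n) in
              enumerate(zip(a.residue_index, a.atom_name)) if str(n) in BACKBONE_ATOMS}
    keys_b = {(int(r), str(n)): i for i, (r, n) in
              enumerate(zip(b.residue_index, b.atom_name)) if str(n) in BACKBONE_ATOMS}
    common = sorted(keys_a.keys() & keys_b.keys())
    if set(keys_a) != set(keys_b):
        raise ValueError("backbone atom sets do not match")
    if not common:
        raise ValueError("no common backbone atoms")
    ia = [keys_a[k] for k in common]
    ib = [keys_b[k] for k in common]
    return a.coords[ia], b.coords[ib]


def rmsd(a: Conformation, b: Conformation) -> float:
    """Minimum backbone RMSD over rigid rototranslations (proper rotations
    only, Kabsch superposition)."""
    xa, xb = _matched_backbone(a, b)
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    _, rssd = Rotation.align_vectors(xa, xb)
    return float(rssd / np.sqrt(xa.shape[0]))


def min_cross_distances(set_a, set_b, metric: str = "rmsd"):
    """For each member of one set, the minimum distance to the other set.

    ``metric`` is ``"rmsd"`` (conformations) or ``"profile"``
    (gyration profiles).  Returns ``(min_a_to_b, min_b_to_a)``."""
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    dist = rmsd if metric == "rmsd" else profile_distance
    if metric not in ("rmsd", "profile"):
        raise ValueError(f"unknown metric {metric!r}")
    matrix = np.array([[dist(a, b) for b in set_b] for a in set_a])
    return matrix.min(axis=1), matrix.min(axis=0)


def ensemble_rg(gamma, rgs, mode: str = "linear") -> float:
    """Resulting ensemble-level gyration radius from per-conformation radii.

    ``linear``: sum_q gamma_q * Rg_q; ``rms``: sqrt(sum_q gamma_q * Rg_q^2).
    """
    gamma = np.asarray(gamma, dtype=float)
    rgs = np.asarray(rgs, dtype=float)
    if gamma.shape != rgs.shape:
        raise ValueError("gamma and rgs must have the same length")
    if np.any(gamma < 0) or abs(gamma.sum() - 1.0) > 1e-9:
        raise ValueError("gamma must lie on the simplex")
    if mode == "linear":
        return float(gamma @ rgs)
    if mode == "rms":
        return float(np.sqrt(gamma @ rgs**2))
    raise ValueError(f"unknown mode {mode!r}")
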