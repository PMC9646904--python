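"""Per-residue Ramachandran likelihood grids: reading, normalization, boxes.

A Ramachandran map is discretized on an 18x18 grid of 20 x 20 degree
voxels; voxel centers sit at odd multiples of 10 degrees, from -170 to
+170, in both phi and psi.  Grids arrive either as a TALOS-N-style
whitespace table (one row per residue: id, name, then 324 likelihoods in
row-major order with phi as the outer loop) or as a long-format CSV with
columns residue_id, residue_name, phi_center, psi_center, likelihood.

High-likelihood regions can be summarized as rectangular angular boxes:
voxels at or above a probability threshold are grouped into 4-connected
components and each component is reported as its bounding rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GRID_SIZE",
    "N_VOXELS",
    "VOXEL_WIDTH_DEG",
    "CENTERS_DEG",
    "GENERIC_BOXES",
    "RamachandranGrid",
    "AngularBox",
    "read_rama_table",
    "write_rama_table",
    "normalize_grid",
    "extract_boxes",
    "grid_to_weights",
]

GRID_SIZE = 18
N_VOXELS = GRID_SIZE * GRID_SIZE
VOXEL_WIDTH_DEG = 20.0
#: Voxel-center angles in degrees, identical for phi and psi.
CENTERS_DEG = np.arange(-170.0, 171.0, VOXEL_WIDTH_DEG)


@dataclass
class RamachandranGrid:
    """One residue's discretized (phi, psi) likelihood or probability map.

    ``values[i, j]`` is the likelihood of phi = CENTERS_DEG[i],
    psi = CENTERS_DEG[j].
    """

    residue_id: int
    residue_name: str
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(
                f"grid must be {GRID_SIZE}x{GRID_SIZE} ({N_VOXELS} voxels), "
                f"got shape {self.values.shape}"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite and nonnegative")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("grid flagged normalized but does not sum to 1")


@dataclass(frozen=True)
class AngularBox:
    """Rectangle of (phi, psi) values, degrees, edges on the 20-degree lattice."""

    phi_lo: float
    phi_hi: float
    psi_lo: float
    psi_hi: float

    def __post_init__(self):
        for lo, hi in ((self.phi_lo, self.phi_hi), (self.psi_lo, self.psi_hi)):
            if not (-180 <= lo < hi <= 180):
                raise ValueError("box edges must satisfy -180 <= lo < hi <= 180")
            if lo % 20 or hi % 20:
                raise ValueError("box edges must be multiples of 20 degrees")


#: Broad fallback boxes covering the beta, alpha-R and alpha-L basins, used
#: when no per-residue prediction is available (e.g. phosphorylated
#: residues); basin rectangles snapped outward to the voxel lattice.
GENERIC_BOXES = (
    AngularBox(-180, -40, 80, 180),  # beta
    AngularBox(-160, -20, -120, 40),  # alpha-R
    AngularBox(20, 100, -20, 100),  # alpha-L
)


def _grid_from_long(resid, resname, sub: pd.DataFrame) -> RamachandranGrid:
    if len(sub) != N_VOXELS:
        raise ValueError(
            f"residue {resid}: expected {N_VOXELS} voxels, got {len(sub)}"
        )
    values = np.zeros((GRID_SIZE, GRID_SIZE))
    phi_idx = np.searchsorted(CENTERS_DEG, sub["phi_center"].to_numpy())
    psi_idx = np.searchsorted(CENTERS_DEG, sub["psi_center"].to_numpy())
    if not (
        np.allclose(CENTERS_DEG[np.clip(phi_idx, 0, GRID_SIZE - 1)], sub["phi_center"])
        and np.allclose(CENTERS_DEG[np.clip(psi_idx, 0, GRID_SIZE - 1)], sub["psi_center"])
    ):
        raise ValueError(f"residue {resid}: voxel centers off the 20-degree lattice")
    values[phi_idx, psi_idx] = sub["likelihood"].to_numpy()
    return RamachandranGrid(int(resid), str(resname), values)


def read_rama_table(path, dialect: str = "csv") -> list[RamachandranGrid]:
    """Read per-residue Ramachandran grids; one grid per residue, in
    sequence order.  Residues absent from the file are simply not returned
    (gaps allowed)."""
    grids: list[RamachandranGrid] = []
    if dialect == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"residue_id", "residue_name", "phi_center", "psi_center", "likelihood"}
        if not required.issubset(df.columns):
            raise ValueError(f"csv dialect requires columns {sorted(required)}")
        if (df["likelihood"] < 0).any():
            raise ValueError("negative likelihood value")
        for resid in df["residue_id"].drop_duplicates():
            sub = df[df["residue_id"] == resid]
            grids.append(_grid_from_long(resid, sub["residue_name"].iloc[0], sub))
    elif dialect == "talosn":
        with open(path) as fh:
            for line in fh:
                fields = line.split()
                if not fields or fields[0].startswith("#"):
                    continue
                if len(fields) != 2 + N_VOXELS:
                    raise ValueError(
                        f"talosn row for residue {fields[0]}: expected "
                        f"{N_VOXELS} values, got {len(fields) - 2}"
                    )
                values = np.array(fields[2:], dtype=float).reshape(GRID_SIZE, GRID_SIZE)
                if np.any(values < 0):
                    raise ValueError("negative likelihood value")
                grids.append(RamachandranGrid(int(fields[0]), fields[1], values))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    grids.sort(key=lambda g: g.residue_id)
    return grids


def write_rama_table(grids, path, dialect: str = "csv") -> None:
    """Write grids back to disk; round trips losslessly through
    :func:`read_rama_table` (floats written with shortest round-trip repr)."""
    if dialect == "csv":
        rows = []
        for g in grids:
            for i, phi in enumerate(CENTERS_DEG):
                for j, psi in enumerate(CENTERS_DEG):
                    rows.append(
                        (g.residue_id, g.residue_name, phi, psi, repr(float(g.values[i, j])))
                    )
        pd.DataFrame(
            rows,
            columns=["residue_id", "residue_name", "phi_center", "psi_center", "likelihood"],
        ).to_csv(path, index=False)
    elif dialect == "talosn":
        with open(path, "w") as fh:
            for g in grids:
                vals = " ".join(repr(float(v)) for v in g.values.ravel())
                fh.write(f"{g.residue_id} {g.residue_name} {vals}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def normalize_grid(g: RamachandranGrid) -> RamachandranGrid:
    """Scale a likelihood grid into a probability grid summing to 1."""
    total = g.values.sum()
    if total <= 0:
        raise ValueError(f"residue {g.residue_id}: all-zero grid cannot be normalized")
    return replace(g, values=g.values / total, normalized=True)


def extract_boxes(g: RamachandranGrid, threshold: float) -> list[AngularBox]:
    """Bounding boxes of 4-connected components of voxels >= threshold.

    Applied to a normalized probability grid; no periodic wrap, so a basin
    crossing +/-180 yields two boxes.  Boxes are sorted by descending
    summed probability.
    """
    if not g.normalized:
        raise ValueError("extract_boxes expects a normalized grid")
    mask = g.values >= threshold
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    boxes = []
    for k in range(1, n + 1):
        rows, cols = np.nonzero(labels == k)
        box = AngularBox(
            phi_lo=CENTERS_DEG[rows.min()] - VOXEL_WIDTH_DEG / 2,
            phi_hi=CENTERS_DEG[rows.max()] + VOXEL_WIDTH_DEG / 2,
            psi_lo=CENTERS_DEG[cols.min()] - VOXEL_WIDTH_DEG / 2,
            psi_hi=CENTERS_DEG[cols.max()] + VOXEL_WIDTH_DEG / 2,
        )
        boxes.append((g.values[rows, cols].sum(), box))
    boxes.sort(key=lambda t: -t[0])
    return [b for _, b in boxes]


def grid_to_weights(g: RamachandranGrid):
    """Flatten a normalized grid into (phi, psi, weight) voxel triples.

    Returns arrays ``(phi_rad, psi_rad, w)`` of length 324 with the voxel
    centers in radians and weights summing to 1; this is the discrete form
    consumed by the mixture likelihood.
    """
    if not g.normalized:
        raise ValueError("grid_to_weights expects a normalized grid")
    centers_rad = np.deg2rad(CENTERS_DEG)
    phi, psi = np.meshgrid(centers_rad, centers_rad, indexing="ij")
    return phi.ravel(), psi.ravel(), g.values.ravel()
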