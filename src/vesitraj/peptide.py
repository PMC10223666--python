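"""Helix tilt angle against the local bilayer normal, and its classification.

The peptide axis is the unit vector from the first residue's C-alpha to
the last residue's, and the local bilayer normal is the average outward
radial direction of the amphiphile monomers found within a cutoff
(default 8 angstrom) of any peptide atom — a patch normal that tracks
the curved vesicle surface instead of a global axis.  The tilt is the
angle between the two: near 0 deg the helix is inserted C-terminus
first, near 90 deg it lies on the bilayer surface, near 180 deg it is
inserted N-terminus first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import VesitrajError
from .topology import MoleculeMap
from .trajectory import Frame, Trajectory
from . import geometry as _geometry

DEFAULT_NORMAL_CUTOFF = 8.0   # angstrom
DEFAULT_MIN_SUPPORT = 5       # monomers required to define the patch normal

#: reporting windows (degrees): inclusive [lo, hi) except the last edge
DEFAULT_CLASS_WINDOWS = (
    (0.0, 30.0, "inserted C->N"),
    (60.0, 120.0, "surface"),
    (150.0, 180.0, "inserted N->C"),
)


@dataclass
class TiltSeries:
    times: np.ndarray          # ns
    tilt_deg: np.ndarray       # NaN where the normal was undefined
    tilt_class: list
    support: np.ndarray        # monomers behind each frame's normal
    missing: np.ndarray        # bool


def peptide_axis(frame: Frame, mmap: MoleculeMap) -> np.ndarray:
    """Unit vector from the first residue's C-alpha to the last residue's."""
    ca = mmap.peptide_calphas
    if len(ca) < 2:
        raise VesitrajError("peptide axis undefined: fewer than two C-alpha atoms")
    v = frame.coords[ca[-1]] - frame.coords[ca[0]]
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise VesitrajError("peptide axis undefined: end C-alphas coincide")
    return v / n


def local_bilayer_normal(
    frame: Frame,
    mmap: MoleculeMap,
    center: np.ndarray,
    cutoff: float = DEFAULT_NORMAL_CUTOFF,
    min_support: int = DEFAULT_MIN_SUPPORT,
):
    """Patch normal from the monomers near the peptide.

    A monomer qualifies when any of its atoms lies within ``cutoff`` of
    any peptide atom.  The normal is a weighted mean of the qualifying
    monomers' outward radial units (vesicle center to headgroup
    midpoint); weights follow a Gaussian kernel of the headgroup's
    distance to the peptide centroid (sigma = 0.75 * cutoff), which keeps
    the averaging footprint symmetric about the helix midpoint — a raw
    mean over the elongated any-atom footprint tilts the normal along the
    helix direction by several degrees.  Returns ``(normal | None,
    support_count)``; the normal is None when support falls below
    ``min_support``.
    """
    pep_atoms = mmap.atoms_by_species("peptide")
    if len(pep_atoms) == 0:
        raise VesitrajError("no peptide atoms in the molecule map")
    amat = mmap.amphiphile_atom_matrix
    pep_xyz = frame.coords[pep_atoms]
    tree = cKDTree(pep_xyz)
    d, _ = tree.query(frame.coords[amat.reshape(-1)], k=1, distance_upper_bound=cutoff)
    near_atom = np.isfinite(d.reshape(amat.shape))
    near_mol = near_atom.any(axis=1)
    support = int(near_mol.sum())
    if support < min_support:
        return None, support
    omid = 0.5 * (
        frame.coords[mmap.headgroup_o1[near_mol]] + frame.coords[mmap.headgroup_o2[near_mol]]
    )
    u = omid - np.asarray(center)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    sigma = 0.75 * cutoff
    w = np.exp(-np.sum((omid - pep_xyz.mean(axis=0)) ** 2, axis=1) / (2.0 * sigma**2))
    n = (u * w[:, None]).sum(axis=0)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        return None, support
    return n / norm, support


def classify_tilt(angle_deg: float, windows=DEFAULT_CLASS_WINDOWS) -> str:
    for lo, hi, name in windows:
        if lo <= angle_deg <= hi:
            return name
    return "intermediate"


def tilt_angle(axis: np.ndarray, normal: np.ndarray, windows=DEFAULT_CLASS_WINDOWS):
    """Angle (degrees, [0, 180]) between helix axis and bilayer normal, plus class."""
    na, nn = np.linalg.norm(axis), np.linalg.norm(normal)
    if na < 1e-9 or nn < 1e-9:
        raise VesitrajError("tilt undefined for zero-length vectors")
    c = float(np.dot(axis, normal) / (na * nn))
    angle = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    return angle, classify_tilt(angle, windows)


def tilt_series(
    traj: Trajectory,
    mmap: MoleculeMap,
    cutoff: float = DEFAULT_NORMAL_CUTOFF,
    min_support: int = DEFAULT_MIN_SUPPORT,
    windows=DEFAULT_CLASS_WINDOWS,
) -> TiltSeries:
    """Per-frame tilt angle and class; frames with undefined normals are missing."""
    n = traj.n_frames
    tilt = np.full(n, np.nan)
    support = np.zeros(n, dtype=int)
    missing = np.zeros(n, dtype=bool)
    classes: list = []
    for i in range(n):
        fr = traj.frame(i)
        center = _geometry.vesicle_center(fr, mmap, traj.elements)
        normal, sup = local_bilayer_normal(fr, mmap, center, cutoff, min_support)
        support[i] = sup
        if normal is None:
            missing[i] = True
            classes.append("missing")
            continue
        ang, cls = tilt_angle(peptide_axis(fr, mmap), normal, windows)
        tilt[i] = ang
        classes.append(cls)
    return TiltSeries(
        times=traj.times, tilt_deg=tilt, tilt_class=classes, support=support, missing=missing
    )
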