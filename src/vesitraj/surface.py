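"""Surface and ordering observables.

* Shrake-Rupley solvent-accessible surface area with a quasi-uniform
  sphere lattice and cell-listed neighbor search.
* Chain order parameters ``S = <3 cos^2 theta - 1> / 2`` on a curved
  bilayer: each monomer is referenced to its own outward radial normal,
  which is exactly equivalent to reorienting every molecule so that its
  local normal maps to +z before measuring against the z axis.
* Equal-area (cos theta, phi) 2-D density maps of the headgroups of one
  leaflet.
* Radial distribution function between two atom groups, shell-volume
  normalized with an optional finite-sphere edge correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import VesitrajError
from .labels import INNER, OUTER, UNASSIGNED
from .radii import AtomRadiusTable
from .topology import MoleculeMap
from .trajectory import Frame, Trajectory
from .units import NM_PER_ANG
from . import geometry as _geometry

DEFAULT_SASA_POINTS = 960


@dataclass
class SASAResult:
    per_atom: np.ndarray     # nm^2, aligned with `selection`
    selection: np.ndarray    # global atom indices scored
    probe_radius: float      # angstrom
    n_points: int

    @property
    def total(self) -> float:
        """Total SASA in nm^2."""
        return float(self.per_atom.sum())


@dataclass
class OrderProfile:
    carbon_index: np.ndarray   # 1-based tail positions with a defined segment (2..9)
    s: np.ndarray              # order parameter per carbon
    n_samples: np.ndarray      # (molecule, frame) samples per carbon


@dataclass
class DensityMap2D:
    counts: np.ndarray          # (n_lat, n_lon)
    density: np.ndarray         # counts normalized so a uniform shell -> 1
    cos_theta_edges: np.ndarray
    phi_edges: np.ndarray
    leaflet: str
    projection: str = "equal-area (cos theta, phi) about the vesicle center"

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


@dataclass
class RDFCurve:
    r: np.ndarray            # bin centers, angstrom
    g: np.ndarray
    counts: np.ndarray       # raw pair counts per bin, summed over frames
    reference_density: float  # mean group-b density used for normalization (A^-3)


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------

def sasa(
    frame: Frame,
    elements,
    radii: AtomRadiusTable | None = None,
    n_points: int = DEFAULT_SASA_POINTS,
    selection: np.ndarray | None = None,
) -> SASAResult:
    """Shrake-Rupley SASA of the selected atoms (nm^2).

    For every atom, ``n_points`` quasi-uniform test points on its expanded
    sphere (vdW radius + probe) are classified against the expanded
    spheres of neighboring selected atoms; the accessible fraction times
    the expanded-sphere area is that atom's contribution.  Burial is
    evaluated against the selection only, so the result is the SASA of
    the selected assembly in isolation.
    """
    if radii is None:
        radii = AtomRadiusTable()
    if n_points < 100:
        raise VesitrajError("n_points must be >= 100 for a meaningful lattice")
    if selection is None:
        selection = np.arange(frame.n_atoms)
    selection = np.asarray(selection, dtype=int)
    xyz = frame.coords[selection]
    from .synthetic import fibonacci_sphere  # quasi-uniform unit lattice

    r = radii.radii_for([elements[i] for i in selection]) + radii.probe_radius
    sphere = fibonacci_sphere(n_points)
    r_max = r.max()
    tree = cKDTree(xyz)
    neighbor_lists = tree.query_ball_point(xyz, 2.0 * r_max)

    areas = np.empty(len(selection))
    for i in range(len(selection)):
        nbr = [j for j in neighbor_lists[i] if j != i]
        if nbr:
            nbr = np.asarray(nbr)
            # keep only true overlaps of the expanded spheres
            d = np.linalg.norm(xyz[nbr] - xyz[i], axis=1)
            keep = d < r[i] + r[nbr]
            nbr, d = nbr[keep], d[keep]
        if len(nbr):
            # orient the point lattice in a frame derived from the nearest
            # neighbors: the lattice then co-rotates with the structure,
            # making the result invariant under rigid motion up to roundoff
            order = np.argsort(d, kind="stable")
            e1 = (xyz[nbr[order[0]]] - xyz[i]) / d[order[0]]
            e2 = None
            for j in order[1:]:
                v = xyz[nbr[j]] - xyz[i]
                v = v - np.dot(v, e1) * e1
                nv = np.linalg.norm(v)
                if nv > 1e-8:
                    e2 = v / nv
                    break
            if e2 is None:
                from .synthetic import perpendicular_unit

                e2 = perpendicular_unit(e1)
            frame_m = np.vstack([e1, e2, np.cross(e1, e2)])
            pts = xyz[i] + r[i] * (sphere @ frame_m)
            d2 = np.sum((pts[:, None, :] - xyz[nbr][None, :, :]) ** 2, axis=2)
            buried = (d2 < (r[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r[i] ** 2
    return SASAResult(
        per_atom=areas * NM_PER_ANG**2,
        selection=selection,
        probe_radius=radii.probe_radius,
        n_points=n_points,
    )


# --------------------------------------------------------------------------
# order parameters
# --------------------------------------------------------------------------

def order_parameter_from_cosines(cos_theta: np.ndarray) -> float:
    """S = <3 cos^2 theta - 1> / 2 over a sample of orientation cosines."""
    c = np.asarray(cos_theta, dtype=float)
    return float(np.mean(1.5 * c**2 - 0.5))


def order_parameters(
    traj: Trajectory,
    mmap: MoleculeMap,
    labels: np.ndarray | None = None,
    frames: np.ndarray | None = None,
    center: np.ndarray | None = None,
) -> OrderProfile:
    """Curvature-corrected chain order profile, averaged over molecules and frames.

    For tail carbon ``C_i`` (i = 2..9 of C1..C10) the chain segment is
    ``C_{i-1} -> C_{i+1}``; the CH direction is reconstructed without
    hydrogens as the in-plane perpendicular to that segment (the
    component of ``C_i`` minus the segment midpoint orthogonal to the
    segment).  theta is measured against the monomer's own outward radial
    normal, removing the vesicle curvature.  Monomers left unassigned by
    the leaflet step, and degenerate collinear segments, are skipped;
    ``labels`` may be per-frame ``(n_frames, n_mol)`` or a single row.
    ``center`` overrides the per-frame centroid estimate when the true
    vesicle center is known (e.g. from a generator sidecar).
    """
    n_tail = mmap.tail_carbons.shape[1]
    carbon_idx = np.arange(1, n_tail - 1)  # 0-based positions with both neighbors
    if frames is None:
        frames = np.arange(traj.n_frames)
    sums = np.zeros(len(carbon_idx))
    counts = np.zeros(len(carbon_idx), dtype=int)

    for fi in frames:
        fr = traj.frame(int(fi))
        ctr = (
            np.asarray(center, dtype=float)
            if center is not None
            else _geometry.vesicle_center(fr, mmap, traj.elements)
        )
        if labels is None:
            lab = _geometry.assign_leaflets(fr, mmap, ctr)
        else:
            lab = labels[int(fi)] if np.ndim(labels) == 2 else labels
        keep = np.asarray(lab) != UNASSIGNED
        if not keep.any():
            continue
        omid = 0.5 * (fr.coords[mmap.headgroup_o1[keep]] + fr.coords[mmap.headgroup_o2[keep]])
        normal = omid - ctr
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        tails = fr.coords[mmap.tail_carbons[keep]]  # (n_sel, n_tail, 3)

        for k, ci in enumerate(carbon_idx):
            seg = tails[:, ci + 1] - tails[:, ci - 1]
            seg_n = np.linalg.norm(seg, axis=1, keepdims=True)
            good = seg_n[:, 0] > 1e-9
            seg = seg / np.where(seg_n > 0, seg_n, 1.0)
            p = tails[:, ci] - 0.5 * (tails[:, ci + 1] + tails[:, ci - 1])
            p = p - np.einsum("ij,ij->i", p, seg)[:, None] * seg
            p_n = np.linalg.norm(p, axis=1, keepdims=True)
            good &= p_n[:, 0] > 1e-9
            if not good.any():
                continue
            ch = p[good] / p_n[good]
            cosang = np.einsum("ij,ij->i", ch, normal[good])
            sums[k] += np.sum(1.5 * cosang**2 - 0.5)
            counts[k] += good.sum()

    with np.errstate(invalid="ignore"):
        s = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return OrderProfile(carbon_index=carbon_idx + 1, s=s, n_samples=counts)


# --------------------------------------------------------------------------
# 2-D headgroup density maps
# --------------------------------------------------------------------------

def density_map(
    traj: Trajectory,
    mmap: MoleculeMap,
    labels: np.ndarray,
    leaflet: str = "outer",
    n_lat: int = 12,
    n_lon: int = 24,
    frames: np.ndarray | None = None,
) -> DensityMap2D:
    """Equal-area projected headgroup density of one leaflet.

    Headgroup midpoints are projected to ``(cos theta, phi)`` about the
    per-frame vesicle center; all cells subtend equal solid angle, so the
    normalized density of a uniform shell is 1 in every cell.
    """
    code = {"inner": INNER, "outer": OUTER}.get(leaflet)
    if code is None:
        raise VesitrajError("leaflet must be 'inner' or 'outer'")
    if frames is None:
        frames = np.arange(traj.n_frames)
    cos_edges = np.linspace(-1.0, 1.0, n_lat + 1)
    phi_edges = np.linspace(-np.pi, np.pi, n_lon + 1)
    counts = np.zeros((n_lat, n_lon))

    total = 0
    for fi in frames:
        fr = traj.frame(int(fi))
        lab = labels[int(fi)] if np.ndim(labels) == 2 else labels
        sel = np.asarray(lab) == code
        if not sel.any():
            continue
        center = _geometry.vesicle_center(fr, mmap, traj.elements)
        omid = 0.5 * (fr.coords[mmap.headgroup_o1[sel]] + fr.coords[mmap.headgroup_o2[sel]]) - center
        rr = np.linalg.norm(omid, axis=1)
        cost = np.clip(omid[:, 2] / rr, -1.0, 1.0)
        phi = np.arctan2(omid[:, 1], omid[:, 0])
        h, _, _ = np.histogram2d(cost, phi, bins=[cos_edges, phi_edges])
        counts += h
        total += int(sel.sum())
    if total == 0:
        warnings.warn("empty leaflet selection; density map has no counts")
        density = counts.copy()
    else:
        density = counts / (counts.sum() / counts.size)
    return DensityMap2D(
        counts=counts,
        density=density,
        cos_theta_edges=cos_edges,
        phi_edges=phi_edges,
        leaflet=leaflet,
    )


# --------------------------------------------------------------------------
# radial distribution function
# --------------------------------------------------------------------------

def _uniform_sphere_pair_cdf(r: np.ndarray, radius: float) -> np.ndarray:
    """CDF of the distance between two independent uniform points in a sphere."""
    x = np.clip(r / (2.0 * radius), 0.0, 1.0)
    # pdf in x = r/2R is 24x^2 - 36x^3 + 12x^5 (two uniform points in a ball)
    return 8.0 * x**3 - 9.0 * x**4 + 2.0 * x**6


def rdf(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    r_max: float,
    bin_width: float,
    frames: np.ndarray | None = None,
    reference_density: float | None = None,
    edge_correction: bool = True,
) -> RDFCurve:
    """Pair distribution g(r) between two atom groups (distances in angstrom).

    The histogram of a-b distances is shell-volume normalized and scaled
    by the mean group-b number density in the bounding analysis sphere.
    For box-free finite systems the ideal-gas reference is a uniform
    sphere, so by default the normalization uses the exact uniform-sphere
    pair-distance law (``edge_correction``), making g -> 1 for a
    homogeneous reference at all r.  Self-pairs are excluded when the
    groups overlap.
    """
    if not (r_max > bin_width > 0):
        raise VesitrajError("require r_max > bin_width > 0")
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise VesitrajError("RDF groups must be non-empty")
    if frames is None:
        frames = np.arange(traj.n_frames)

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-9]
    counts = np.zeros(len(edges) - 1)
    n_self = len(np.intersect1d(group_a, group_b))

    radius_acc, dens_acc = 0.0, 0.0
    for fi in frames:
        x = traj.coords[int(fi)]
        a, b = x[group_a], x[group_b]
        centroid = np.concatenate([a, b]).mean(axis=0)
        r_sys = float(np.linalg.norm(np.concatenate([a, b]) - centroid, axis=1).max())
        r_sys = max(r_sys, r_max / 2.0, 1e-6)
        radius_acc += r_sys
        dens_acc += len(group_b) / (4.0 / 3.0 * np.pi * r_sys**3)
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2).ravel()
        d = d[d > 1e-9]  # drops self-pairs (identical atoms at zero distance)
        h, _ = np.histogram(d, bins=edges)
        counts += h

    n_frames_used = len(frames)
    r_sys = radius_acc / n_frames_used
    rho_b = reference_density if reference_density is not None else dens_acc / n_frames_used
    n_pairs = len(group_a) * len(group_b) - n_self

    if edge_correction:
        cdf = _uniform_sphere_pair_cdf(edges, r_sys)
        expected = n_frames_used * n_pairs * np.diff(cdf)
    else:
        shell = 4.0 / 3.0 * np.pi * np.diff(edges**3)
        expected = n_frames_used * len(group_a) * rho_b * shell * (n_pairs / (len(group_a) * len(group_b)))
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFCurve(r=centers, g=g, counts=counts, reference_density=float(rho_b))
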