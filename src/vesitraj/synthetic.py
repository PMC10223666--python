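"""Synthetic vesicle trajectories with known ground truth.

Every analyzer in this package is validated by parameter recovery: the
generator plants a two-leaflet spherical vesicle of single-chain
ten-carbon amphiphiles (headgroup oxygens O1/O2 plus tail carbons
C1..C10), optional interior water beads, Brownian or anomalous monomer
motion, scripted leaflet flip-flops, gel (all-trans) or fluid
(random-dihedral) tails, and an ideal alpha-helix at an exact planted
tilt — and records all of it in a :class:`GroundTruth` sidecar.

Monomers are rigid bodies during dynamics: only their centers diffuse,
and scripted flips rotate the whole monomer about a local tangent axis
while its radial position crosses the bilayer.  Internal vibrations are
deliberately absent; the fixtures isolate each estimator's correctness,
not force-field realism.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import PackingError, SpecError
from .labels import INNER, OUTER, CODE_TO_NAME, NAME_TO_CODE
from .topology import Molecule, MoleculeMap
from .trajectory import Trajectory
from .units import ANG_PER_NM

# --- monomer internal geometry (angstrom / degrees) -----------------------
CC_BOND = 1.53
CCC_ANGLE = 111.0
CO_BOND = 1.40          # headgroup-midpoint to C1 offset
O_HALF_SEP = 1.10       # half the O1-O2 separation
N_TAIL_CARBONS = 10
ATOMS_PER_MONOMER = 2 + N_TAIL_CARBONS
MONOMER_ELEMENTS = ["O", "O"] + ["C"] * N_TAIL_CARBONS

GEL_DIHEDRAL = 180.0
FLUID_DIHEDRALS = (-60.0, 60.0, 180.0)

# Ideal alpha-helix C-alpha trace parameters.
HELIX_RISE = 1.5        # angstrom per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # angstrom


# --------------------------------------------------------------------------
# specs and ground truth
# --------------------------------------------------------------------------

@dataclass
class VesicleSpec:
    """Static vesicle composition; radii in nm, jitter is radial Gaussian sigma."""

    r_inner: float = 2.0
    r_outer: float = 3.5
    n_inner: int = 210
    n_outer: int = 790
    tail_state: str | list = "gel"       # gel | fluid | mixed, or per-monomer list
    fluid_fraction: float = 0.5          # used by tail_state="mixed"
    water_fill: int = 0
    jitter: float = 0.05                 # nm
    min_spacing: float = 0.45            # nm, headgroup-diameter scale
    seed: int = 0

    def validate(self):
        errs = []
        if not 0 < self.r_inner < self.r_outer:
            errs.append("require 0 < r_inner < r_outer")
        if self.n_inner <= 0 or self.n_outer <= 0:
            raise PackingError("both leaflets need at least one monomer (a vesicle has two leaflets)")
        if self.water_fill < 0 or self.jitter < 0:
            errs.append("water_fill and jitter must be non-negative")
        if errs:
            raise SpecError("; ".join(errs))


@dataclass
class MotionSpec:
    """Dynamics parameters: D in nm^2/ns, timestep in ns, alpha=1 is Brownian."""

    d_true: float = 0.0
    alpha: float = 1.0
    n_frames: int = 100
    timestep: float = 0.01
    flip_events: list = field(default_factory=list)  # (molecule_id, frame, direction?) tuples
    transit_frames: int = 10
    seed: int = 0

    def validate(self, n_amphiphiles: int):
        if self.d_true < 0:
            raise SpecError("d_true must be >= 0")
        if not 0 < self.alpha < 2:
            raise SpecError("alpha must lie in (0, 2)")
        if self.n_frames < 1 or self.timestep <= 0:
            raise SpecError("need n_frames >= 1 and timestep > 0")
        if self.transit_frames < 1:
            raise SpecError("transit_frames must be >= 1")
        for ev in self.flip_events:
            mol, frame = ev[0], ev[1]
            if not 0 <= mol < n_amphiphiles:
                raise SpecError(f"flip event references unknown molecule {mol}")
            if not 0 <= frame < self.n_frames:
                raise SpecError(f"flip event frame {frame} outside trajectory")


@dataclass
class PeptideSpec:
    """Ideal helix plant: tilt vs the local outward radial normal, in degrees."""

    n_residues: int = 16
    planted_tilt: float = 0.0
    insertion_depth: float = 0.0  # nm, radial offset of helix midpoint from bilayer midplane
    seed: int = 0

    def validate(self):
        if self.n_residues < 2:
            raise SpecError("peptide needs at least two residues")
        if not 0 <= self.planted_tilt <= 180:
            raise SpecError("planted_tilt must lie in [0, 180] degrees")


@dataclass
class GroundTruth:
    """Planted parameters emitted alongside every fixture."""

    r_inner_nm: float
    r_outer_nm: float
    n_inner: int
    n_outer: int
    center: list = field(default_factory=lambda: [0.0, 0.0, 0.0])  # angstrom
    leaflet_labels: list = field(default_factory=list)             # per amphiphile, "inner"/"outer"
    tail_states: list = field(default_factory=list)
    d_true_nm2_ns: float | None = None
    alpha: float | None = None
    timestep_ns: float | None = None
    flip_events: list = field(default_factory=list)  # dicts: molecule_id, frame_start, frame_end, direction
    planted_tilt_deg: float | None = None
    peptide_normal: list | None = None               # outward radial at the helix midpoint
    seed: int = 0

    @property
    def thickness_nm(self) -> float:
        return self.r_outer_nm - self.r_inner_nm

    @property
    def inner_fraction_pct(self) -> float:
        return 100.0 * self.n_inner / (self.n_inner + self.n_outer)

    @property
    def label_codes(self) -> np.ndarray:
        return np.array([NAME_TO_CODE[s] for s in self.leaflet_labels], dtype=np.int8)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# small geometry helpers
# --------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def perpendicular_unit(u: np.ndarray) -> np.ndarray:
    """Deterministic unit vector orthogonal to u."""
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, a)
    return v / np.linalg.norm(v)


def rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return rotation_about(perpendicular_unit(a), np.pi)
    axis = np.cross(a, b)
    return rotation_about(axis, np.arccos(np.clip(c, -1, 1)))


def build_chain(dihedrals_deg, bond: float = CC_BOND, angle_deg: float = CCC_ANGLE) -> np.ndarray:
    """Carbon chain from internal coordinates (natural-extension reference frame).

    ``len(dihedrals_deg) + 3`` atoms; all bond lengths and C-C-C angles fixed.
    An empty dihedral list gives the three-atom seed.
    """
    ang = np.radians(angle_deg)
    atoms = [np.zeros(3), np.array([bond, 0.0, 0.0])]
    atoms.append(atoms[1] + bond * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0]))
    for dih in dihedrals_deg:
        a, b_, c = atoms[-3], atoms[-2], atoms[-1]
        bc = c - b_
        bc /= np.linalg.norm(bc)
        n1 = np.cross(b_ - a, bc)
        n1 /= np.linalg.norm(n1)
        m = np.cross(n1, bc)
        d_rad = np.radians(dih)
        d2 = np.array(
            [
                -bond * np.cos(ang),
                bond * np.sin(ang) * np.cos(d_rad),
                bond * np.sin(ang) * np.sin(d_rad),
            ]
        )
        atoms.append(c + d2[0] * bc + d2[1] * m + d2[2] * n1)
    return np.array(atoms)


def place_monomer(
    rhat: np.ndarray,
    head_radius: float,
    tail_dir: np.ndarray,
    dihedrals_deg,
    spin: float = 0.0,
    align: str = "e2e",
) -> np.ndarray:
    """Assemble one amphiphile: [O1, O2, C1..C10] in angstrom.

    Both headgroup oxygens sit exactly on the sphere of ``head_radius``
    about the origin (their midpoint lies marginally inside, by the chord
    correction).  ``align`` controls which chain vector is made exactly
    parallel to ``tail_dir``: ``"e2e"`` uses C1->C10 (robust for kinked
    fluid chains), ``"axis"`` uses the zigzag axis C1->C3 so that every
    all-trans segment vector is exactly parallel to the tail direction.
    """
    rhat = rhat / np.linalg.norm(rhat)
    t = rotation_about(rhat, spin) @ perpendicular_unit(rhat)
    phi = np.arcsin(min(1.0, O_HALF_SEP / head_radius))
    o1 = head_radius * (np.cos(phi) * rhat + np.sin(phi) * t)
    o2 = head_radius * (np.cos(phi) * rhat - np.sin(phi) * t)
    omid = 0.5 * (o1 + o2)

    chain = build_chain(dihedrals_deg)
    e = chain[2] - chain[0] if align == "axis" else chain[-1] - chain[0]
    rot = rotation_between(e / np.linalg.norm(e), tail_dir)
    chain = (chain - chain[0]) @ rot.T + omid + CO_BOND * np.asarray(tail_dir)
    return np.vstack([o1, o2, chain])


# --------------------------------------------------------------------------
# vesicle assembly
# --------------------------------------------------------------------------

def _resolve_tail_states(spec: VesicleSpec, n: int, rng) -> list[str]:
    if isinstance(spec.tail_state, (list, tuple, np.ndarray)):
        states = [str(s) for s in spec.tail_state]
        if len(states) != n:
            raise SpecError("per-monomer tail_state list has wrong length")
    elif spec.tail_state == "mixed":
        states = np.where(rng.random(n) < spec.fluid_fraction, "fluid", "gel").tolist()
    elif spec.tail_state in ("gel", "fluid"):
        states = [spec.tail_state] * n
    else:
        raise SpecError(f"unknown tail_state {spec.tail_state!r}")
    bad = set(states) - {"gel", "fluid"}
    if bad:
        raise SpecError(f"unknown tail state(s) {sorted(bad)}")
    return states


def _dihedrals_for(state: str, rng) -> np.ndarray:
    n_dih = N_TAIL_CARBONS - 3
    if state == "gel":
        return np.full(n_dih, GEL_DIHEDRAL)
    return rng.choice(FLUID_DIHEDRALS, size=n_dih)


def make_vesicle(spec: VesicleSpec):
    """Build a single-frame assembled vesicle.

    Returns ``(trajectory, molecule_map, ground_truth)``.  Outer-leaflet
    tails point inward, inner-leaflet tails outward, meeting at the
    midplane.  Placement uses a golden-spiral lattice per shell; a shell
    whose lattice spacing falls below ``min_spacing`` raises
    :class:`PackingError`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_inner + spec.n_outer
    states = _resolve_tail_states(spec, n_total, rng)

    coords = []
    labels = []
    mono = 0
    for leaflet, (r_nm, n) in (
        (INNER, (spec.r_inner, spec.n_inner)),
        (OUTER, (spec.r_outer, spec.n_outer)),
    ):
        radius = r_nm * ANG_PER_NM
        pts = fibonacci_sphere(n)
        # density feasibility: each headgroup needs the hexagonal-packing
        # footprint of a disc of diameter min_spacing
        s = spec.min_spacing * ANG_PER_NM
        if 4.0 * np.pi * radius**2 / n < (np.sqrt(3.0) / 2.0) * s**2:
            raise PackingError(
                f"{n} monomers exceed the capacity of a {r_nm} nm shell at the "
                f"{spec.min_spacing} nm minimum headgroup spacing"
            )
        for m in range(n):
            rhat = pts[m]
            head_r = radius + rng.normal(0.0, spec.jitter * ANG_PER_NM)
            tail_dir = rhat if leaflet == INNER else -rhat
            coords.append(
                place_monomer(
                    rhat,
                    head_r,
                    tail_dir,
                    _dihedrals_for(states[mono], rng),
                    spin=rng.uniform(0, 2 * np.pi),
                    align="axis" if states[mono] == "gel" else "e2e",
                )
            )
            labels.append(leaflet)
            mono += 1

    atoms = np.concatenate(coords, axis=0)
    elements = MONOMER_ELEMENTS * n_total

    if spec.water_fill:
        r_w = max(1.0, spec.r_inner * ANG_PER_NM - 4.0)
        w = rng.normal(size=(spec.water_fill, 3))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        w *= r_w * rng.random(spec.water_fill)[:, None] ** (1.0 / 3.0)
        atoms = np.concatenate([atoms, w], axis=0)
        elements = elements + ["O"] * spec.water_fill

    molecules = []
    o1, o2, tails = [], [], []
    for m in range(n_total):
        base = m * ATOMS_PER_MONOMER
        molecules.append(Molecule(m, "amphiphile", np.arange(base, base + ATOMS_PER_MONOMER)))
        o1.append(base)
        o2.append(base + 1)
        tails.append(np.arange(base + 2, base + ATOMS_PER_MONOMER))
    for wi in range(spec.water_fill):
        base = n_total * ATOMS_PER_MONOMER + wi
        molecules.append(Molecule(n_total + wi, "water", np.array([base])))

    mmap = MoleculeMap(
        molecules=molecules,
        headgroup_o1=np.asarray(o1, dtype=int),
        headgroup_o2=np.asarray(o2, dtype=int),
        tail_carbons=np.stack(tails),
    )
    traj = Trajectory(atoms[None, :, :], timestep=0.01, elements=elements)
    truth = GroundTruth(
        r_inner_nm=spec.r_inner,
        r_outer_nm=spec.r_outer,
        n_inner=spec.n_inner,
        n_outer=spec.n_outer,
        leaflet_labels=[CODE_TO_NAME[c] for c in labels],
        tail_states=states,
        seed=spec.seed,
    )
    return traj, mmap, truth


# --------------------------------------------------------------------------
# peptide plant
# --------------------------------------------------------------------------

def make_peptide(pspec: PeptideSpec, traj: Trajectory, mmap: MoleculeMap, truth: GroundTruth):
    """Append an ideal alpha-helix C-alpha trace at an exact planted tilt.

    The helix end-to-end vector (first residue -> last residue) makes
    exactly ``planted_tilt`` degrees with the outward radial direction at
    the helix midpoint, which sits at the bilayer midplane radius plus
    ``insertion_depth``.  Returns new ``(trajectory, molecule_map,
    ground_truth)``; inputs are not mutated.
    """
    pspec.validate()
    if traj.n_frames != 1:
        raise SpecError("plant the peptide on the single-frame base vesicle, before dynamics")
    rng = np.random.default_rng(pspec.seed)

    i = np.arange(pspec.n_residues, dtype=float)
    helix = np.column_stack(
        [
            HELIX_RADIUS * np.cos(np.radians(HELIX_TWIST) * i),
            HELIX_RADIUS * np.sin(np.radians(HELIX_TWIST) * i),
            HELIX_RISE * i,
        ]
    )
    e0 = helix[-1] - helix[0]
    e0 /= np.linalg.norm(e0)

    w = rng.normal(size=3)
    w /= np.linalg.norm(w)
    t = rotation_about(w, rng.uniform(0, 2 * np.pi)) @ perpendicular_unit(w)
    tilt = np.radians(pspec.planted_tilt)
    target = np.cos(tilt) * w + np.sin(tilt) * t

    r_mid = 0.5 * (truth.r_inner_nm + truth.r_outer_nm) + pspec.insertion_depth
    thickness = truth.thickness_nm * ANG_PER_NM
    if np.linalg.norm(helix[-1] - helix[0]) > thickness and pspec.planted_tilt in (0.0, 180.0):
        warnings.warn("helix end-to-end length exceeds the bilayer thickness at transmembrane tilt")

    rot = rotation_between(e0, target)
    mid = helix.mean(axis=0)
    placed = (helix - mid) @ rot.T + r_mid * ANG_PER_NM * w

    base = traj.n_atoms
    coords = np.concatenate([traj.coords[0], placed], axis=0)
    elements = list(traj.elements) + ["C"] * pspec.n_residues
    new_traj = Trajectory(coords[None, :, :], timestep=traj.timestep, elements=elements)

    idx = np.arange(base, base + pspec.n_residues)
    molecules = list(mmap.molecules) + [Molecule(len(mmap.molecules), "peptide", idx)]
    new_map = MoleculeMap(
        molecules=molecules,
        headgroup_o1=mmap.headgroup_o1,
        headgroup_o2=mmap.headgroup_o2,
        tail_carbons=mmap.tail_carbons,
        peptide_calphas=idx,
    )
    new_truth = GroundTruth(**{**asdict(truth)})
    new_truth.planted_tilt_deg = float(pspec.planted_tilt)
    new_truth.peptide_normal = w.tolist()
    return new_traj, new_map, new_truth


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _fgn_cholesky(n_steps: int, alpha: float) -> np.ndarray:
    """Cholesky factor of the unit fractional-Gaussian-noise covariance.

    Increment sums then satisfy Var(S_k) = k**alpha exactly, so the
    ensemble MSD follows the planted power law at every lag with
    stationary increments (all-origin averaging stays unbiased).
    """
    h2 = alpha  # 2H
    k = np.arange(n_steps, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)
    idx = np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps)))
    cov = gamma[idx]
    cov[np.diag_indices_from(cov)] += 1e-12  # numerical guard
    return np.linalg.cholesky(cov)


def fgn_increments(n_steps: int, alpha: float, n_series: int, rng) -> np.ndarray:
    """(n_steps, n_series) unit fGn increments; iid normal when alpha == 1."""
    z = rng.standard_normal((n_steps, n_series))
    if abs(alpha - 1.0) < 1e-12:
        return z
    return _fgn_cholesky(n_steps, round(float(alpha), 9)) @ z


def make_dynamic_trajectory(
    traj: Trajectory, mmap: MoleculeMap, truth: GroundTruth, motion: MotionSpec
):
    """Propagate the base vesicle: rigid-monomer diffusion plus scripted flips.

    Per-monomer center displacements follow fractional Gaussian motion
    with ensemble MSD ``6 * d_true * (t)**alpha`` (3-D); scripted flip
    events rotate the monomer through the bilayer across a transit window
    while every other monomer stays leaflet-stable.  Waters and peptide
    atoms are static.  Returns ``(trajectory, ground_truth)``.
    """
    motion.validate(mmap.n_amphiphiles)
    rng = np.random.default_rng(motion.seed)
    n_frames, dt = motion.n_frames, motion.timestep
    base = traj.coords[0]
    frames = np.repeat(base[None, :, :], n_frames, axis=0)

    label_codes = truth.label_codes
    amph_matrix = mmap.amphiphile_atom_matrix
    r_shell = {INNER: truth.r_inner_nm * ANG_PER_NM, OUTER: truth.r_outer_nm * ANG_PER_NM}

    flip_records = []
    for ev in motion.flip_events:
        mol, f0 = int(ev[0]), int(ev[1])
        start_leaflet = int(label_codes[mol])
        direction = f"{CODE_TO_NAME[start_leaflet]}->" + CODE_TO_NAME[
            INNER if start_leaflet == OUTER else OUTER
        ]
        if len(ev) > 2 and ev[2] and str(ev[2]) != direction:
            raise SpecError(
                f"flip event for molecule {mol} declares {ev[2]!r} but the monomer is "
                f"{CODE_TO_NAME[start_leaflet]}"
            )
        atoms = amph_matrix[mol]
        x0 = base[atoms]
        pivot = 0.5 * (base[mmap.headgroup_o1[mol]] + base[mmap.headgroup_o2[mol]])
        u = pivot / np.linalg.norm(pivot)
        axis = perpendicular_unit(u)
        r_from = r_shell[start_leaflet]
        r_to = r_shell[INNER if start_leaflet == OUTER else OUTER]
        f_end = min(f0 + motion.transit_frames, n_frames)
        for k in range(f0, n_frames):
            p = min(1.0, (k - f0 + 1) / motion.transit_frames)
            rot = rotation_about(axis, np.pi * p)
            frames[k, atoms] = (x0 - pivot) @ rot.T + pivot + p * (r_to - r_from) * u
            if p >= 1.0:
                frames[k + 1 :, atoms] = frames[k, atoms]
                break
        flip_records.append(
            {
                "molecule_id": mol,
                "frame_start": f0,
                "frame_end": f_end - 1,
                "direction": direction,
            }
        )

    n_mol = mmap.n_amphiphiles
    if motion.d_true > 0 and n_frames > 1:
        d_ang2 = motion.d_true * ANG_PER_NM**2  # A^2 / ns^alpha
        sigma = np.sqrt(2.0 * d_ang2 * dt**motion.alpha)
        inc = fgn_increments(n_frames - 1, motion.alpha, n_mol * 3, rng) * sigma
        disp = np.zeros((n_frames, n_mol, 3))
        disp[1:] = np.cumsum(inc, axis=0).reshape(n_frames - 1, n_mol, 3)
        flat_atoms = amph_matrix.reshape(-1)
        mol_of_atom = np.repeat(np.arange(n_mol), amph_matrix.shape[1])
        frames[:, flat_atoms, :] += disp[:, mol_of_atom, :]

    out = Trajectory(frames, timestep=dt, elements=list(traj.elements))
    new_truth = GroundTruth(**{**asdict(truth)})
    new_truth.d_true_nm2_ns = float(motion.d_true)
    new_truth.alpha = float(motion.alpha)
    new_truth.timestep_ns = float(dt)
    new_truth.flip_events = flip_records
    return out, new_truth


# --------------------------------------------------------------------------
# named presets
# --------------------------------------------------------------------------

# Compositions emulating a ~1000-monomer decanoic-acid vesicle across the
# temperature series: outer-shell radius, bilayer thickness, inner-leaflet
# percentage, and the dominant tail phase at that temperature.
_PRESET_ROWS = {
    "DA-0": (3.55, 1.44, 20.9, "gel"),
    "DA-10": (3.51, 1.51, 22.3, "gel"),
    "DA-20": (3.53, 1.51, 21.4, "mixed"),
    "DA-25": (3.50, 1.50, 21.0, "mixed"),
    "DA-30": (3.56, 1.55, 22.5, "mixed"),
    "DA-40": (3.61, 1.52, 22.4, "mixed"),
    "DA-50": (3.51, 1.42, 25.6, "fluid"),
    "DA-60": (3.67, 1.54, 21.9, "fluid"),
    "DA-70": (3.59, 1.45, 23.4, "fluid"),
    "DA-80": (3.61, 1.47, 24.2, "fluid"),
    "DA-90": (3.59, 1.45, 23.4, "fluid"),
    "DA-100": (3.61, 1.47, 23.0, "fluid"),
    "DA-110": (3.64, 1.51, 21.4, "fluid"),
}


def preset_spec(name: str, seed: int = 0, n_monomers: int = 1000, **overrides) -> VesicleSpec:
    """VesicleSpec for a named temperature-series composition (e.g. "DA-25")."""
    if name not in _PRESET_ROWS:
        raise SpecError(f"unknown preset {name!r}; known: {sorted(_PRESET_ROWS)}")
    radius, thickness, inner_pct, phase = _PRESET_ROWS[name]
    n_inner = int(round(n_monomers * inner_pct / 100.0))
    spec = VesicleSpec(
        r_inner=round(radius - thickness, 3),
        r_outer=radius,
        n_inner=n_inner,
        n_outer=n_monomers - n_inner,
        tail_state=phase,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


PRESETS = tuple(_PRESET_ROWS)
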