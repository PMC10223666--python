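"""Trajectory container and multi-model PDB / XYZ readers and writers.

The in-memory model is deliberately small: a dense ``(n_frames, n_atoms, 3)``
coordinate array in angstrom, one element symbol per atom, a constant
sampling interval in nanoseconds, and an optional orthorhombic box per
frame.  Atom ordering is a stable contract across frames, so analyzers can
cache per-atom role lookups once.

File I/O goes through MDAnalysis; the two portable dialects are multi-model
PDB (MODEL/ENDMDL records) and XYZ (count, comment, element x y z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MalformedTrajectoryError, UnsupportedFormatError, VesitrajError

_FORMATS = {"pdb", "xyz"}


@dataclass
class Frame:
    """Coordinates (angstrom) and optional orthorhombic box of one snapshot."""

    coords: np.ndarray  # (n_atoms, 3)
    box: np.ndarray | None = None  # (3,) edge lengths, angstrom

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise VesitrajError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise VesitrajError("frame coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise VesitrajError("box edge lengths must be three positive values")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Fixed-roster multi-frame trajectory.

    Parameters
    ----------
    coords
        ``(n_frames, n_atoms, 3)`` array in angstrom.
    timestep
        Sampling interval between stored frames, in nanoseconds.  Frame
        times are ``t_i = i * timestep``.
    elements
        One chemical element symbol per atom.
    box
        Optional ``(n_frames, 3)`` orthorhombic edge lengths in angstrom.
    """

    coords: np.ndarray
    timestep: float
    elements: list[str] = field(default_factory=list)
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise VesitrajError("trajectory coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] == 0:
            raise VesitrajError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise MalformedTrajectoryError("non-finite coordinates in trajectory")
        if self.timestep <= 0:
            raise VesitrajError("timestep must be positive (ns)")
        if not self.elements:
            self.elements = ["C"] * self.coords.shape[1]
        if len(self.elements) != self.coords.shape[1]:
            raise VesitrajError("one element symbol required per atom")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3) or np.any(self.box <= 0):
                raise VesitrajError("box must be (n_frames, 3) positive edge lengths")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in nanoseconds."""
        return np.arange(self.n_frames) * self.timestep

    def frame(self, i: int) -> Frame:
        box = None if self.box is None else self.box[i]
        return Frame(self.coords[i], box)

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise UnsupportedFormatError(
            f"unsupported trajectory format {fmt!r}; supported: {sorted(_FORMATS)}"
        )
    return fmt


def _validate_pdb_models(path: Path) -> None:
    """Cheap pre-scan: every MODEL block must carry the same atom count."""
    counts, current, in_model, any_model = [], 0, False, False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                in_model, any_model, current = True, True, 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current += 1
    if not any_model:
        return  # single implicit model
    if in_model:
        counts.append(current)
    if len(set(counts)) > 1:
        raise MalformedTrajectoryError(
            f"{path}: atom counts differ between MODEL blocks: {sorted(set(counts))}"
        )


def _validate_xyz_frames(path: Path) -> None:
    """XYZ frames each declare their own atom count; require them equal."""
    counts = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            try:
                n = int(header.split()[0])
            except ValueError as exc:
                raise MalformedTrajectoryError(f"{path}: bad XYZ frame header {header!r}") from exc
            counts.append(n)
            fh.readline()  # comment
            for _ in range(n):
                if not fh.readline():
                    raise MalformedTrajectoryError(f"{path}: truncated XYZ frame")
    if len(set(counts)) > 1:
        raise MalformedTrajectoryError(
            f"{path}: atom counts differ between XYZ frames: {sorted(set(counts))}"
        )


def _element_from_name(name: str) -> str:
    sym = "".join(ch for ch in name if ch.isalpha())
    if not sym:
        return "C"
    sym = sym.capitalize()
    # two-letter symbols we care about; everything else collapses to its first letter
    return sym if sym.upper() in ("NA", "CL") else sym[0]


def read_trajectory(path, format: str | None = None, timestep: float = 0.01) -> Trajectory:
    """Read a multi-model PDB or XYZ file into a :class:`Trajectory`.

    ``timestep`` is the sampling interval in ns between stored frames
    (default 0.01 ns, the conventional analysis interval for these systems).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise VesitrajError(f"trajectory file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _validate_pdb_models(path)
    else:
        _validate_xyz_frames(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt.upper())
        except Exception as exc:  # pragma: no cover - dialect-specific parse errors
            raise MalformedTrajectoryError(f"cannot parse {path}: {exc}") from exc

        if hasattr(u.atoms, "elements") and all(u.atoms.elements):
            elements = [str(e).capitalize() for e in u.atoms.elements]
        else:
            elements = [_element_from_name(n) for n in u.atoms.names]

        frames, boxes = [], []
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float).copy())
            dims = ts.dimensions
            if dims is not None and np.all(dims[:3] > 1.0) and np.allclose(dims[3:], 90.0):
                boxes.append(dims[:3].astype(float).copy())
            else:
                boxes.append(None)

    box = None
    if all(b is not None for b in boxes):
        box = np.stack(boxes)
    return Trajectory(np.stack(frames), timestep=timestep, elements=elements, box=box)


def write_trajectory(trajectory: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or XYZ.

    Round trip through :func:`read_trajectory` preserves frame count exactly
    and coordinates to the dialect's printed precision (0.001 angstrom for
    PDB).
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    fmt = _infer_format(path, format)
    if trajectory.n_frames == 0:
        raise VesitrajError("refusing to write an empty trajectory")

    n = trajectory.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=1, atom_resindex=np.zeros(n, dtype=int), trajectory=True)
        u.add_TopologyAttr("names", [e.upper() for e in trajectory.elements])
        u.add_TopologyAttr("elements", [e.capitalize() for e in trajectory.elements])
        u.add_TopologyAttr("resnames", ["SYS"])
        u.load_new(trajectory.coords.astype(np.float32), format=MemoryReader)
        try:
            with mda.Writer(str(path), n_atoms=n, multiframe=True, format=fmt.upper()) as w:
                for i, ts in enumerate(u.trajectory):
                    if trajectory.box is not None:
                        ts.dimensions = [*trajectory.box[i], 90.0, 90.0, 90.0]
                    w.write(u.atoms)
        except OSError as exc:
            raise VesitrajError(f"cannot write {path}: {exc}") from exc
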