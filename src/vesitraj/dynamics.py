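"""Time-dependent observables: MSD, Einstein diffusion, flip-flop events.

The mean squared displacement is the all-time-origin, all-particle
average ``M(tau) = <|r(t + tau) - r(t)|^2>`` on a lag grid equal to the
trajectory sampling interval.  The diffusion coefficient follows the
Einstein relation ``D = slope(M vs tau) / (2 E)`` with ``E`` the fitted
dimensionality; the same window also yields the anomalous exponent from
the log-log slope, and a trajectory flagged anomalous reports no D —
a sub- or super-linear MSD has no single Einstein constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FitError, VesitrajError
from .labels import INNER, OUTER, UNASSIGNED, CODE_TO_NAME
from .topology import MoleculeMap
from .trajectory import Trajectory
from .units import NM_PER_ANG, masses_for

#: |alpha - 1| beyond which a fit is flagged anomalous
DEFAULT_ANOMALOUS_THRESHOLD = 0.2
#: frames a new leaflet label must persist before a flip-flop is counted
DEFAULT_MIN_DWELL = 20


@dataclass
class MSDCurve:
    lags: np.ndarray     # ns, starting at 0
    msd: np.ndarray      # nm^2
    n_pairs: np.ndarray  # (origin, particle) pairs averaged per lag


@dataclass
class DiffusionResult:
    d: float | None          # nm^2/ns; None when the regime is anomalous
    e_dim: int
    alpha_hat: float
    fit_window: tuple        # (tau_lo, tau_hi) ns
    anomalous: bool
    d_fit: float             # raw Einstein slope / 2E, regardless of flag


@dataclass
class FlipFlopReport:
    events: list             # dicts: molecule_id, frame_start, frame_end, direction

    @property
    def count(self) -> int:
        return len(self.events)


def monomer_centers(traj: Trajectory, mmap: MoleculeMap) -> np.ndarray:
    """(n_frames, n_amphiphiles, 3) mass-weighted monomer centers, angstrom."""
    amat = mmap.amphiphile_atom_matrix
    m = masses_for([traj.elements[i] for i in amat[0]])
    w = m / m.sum()
    return np.einsum("fmak,a->fmk", traj.coords[:, amat, :], w)


def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic jumps so displacements are continuous (boxed input only)."""
    if traj.box is None:
        return traj
    coords = traj.coords.copy()
    for i in range(1, traj.n_frames):
        box = traj.box[i]
        delta = coords[i] - coords[i - 1]
        coords[i] -= np.round(delta / box) * box
    return Trajectory(coords, timestep=traj.timestep, elements=list(traj.elements), box=traj.box)


def _msd_fft(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-origin MSD of (n_frames, n_series, 3) positions via FFT autocorrelation."""
    f, n, _ = pos.shape
    x = pos.reshape(f, n * 3)
    nfft = 1 << int(np.ceil(np.log2(2 * f)))
    fx = np.fft.rfft(x, n=nfft, axis=0)
    s2 = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:f].real

    d = x**2
    ss = 2.0 * d.sum(axis=0)
    s1 = np.empty_like(s2)
    s1[0] = ss
    for m in range(1, f):
        ss = ss - d[m - 1] - d[f - m]
        s1[m] = ss

    counts = (f - np.arange(f)).astype(float)
    per_series = (s1 - 2.0 * s2) / counts[:, None]
    msd = per_series.reshape(f, n, 3).sum(axis=2).mean(axis=1)
    msd[0] = 0.0
    return msd, counts * n


def msd(
    traj: Trajectory,
    mmap: MoleculeMap,
    species: str = "amphiphile",
    max_lag: float | None = None,
) -> MSDCurve:
    """Mean squared displacement of monomer centers of mass, in nm^2 vs ns.

    ``max_lag`` (ns) truncates the lag grid; lags beyond the trajectory
    length are dropped with a warning.  Boxed trajectories must be
    unwrapped (:func:`unwrap`) first.
    """
    if traj.n_frames < 2:
        raise VesitrajError("MSD needs at least two frames")
    if species == "amphiphile":
        pos = monomer_centers(traj, mmap)
    elif species == "peptide":
        if not mmap.has_peptide:
            raise VesitrajError("no peptide in the molecule map")
        pos = traj.coords[:, mmap.peptide_calphas, :].mean(axis=1, keepdims=True)
    else:
        raise VesitrajError(f"unknown species selection {species!r}")
    if pos.shape[1] == 0:
        raise VesitrajError("empty selection for MSD")

    full, n_pairs = _msd_fft(pos * NM_PER_ANG)
    lags = np.arange(traj.n_frames) * traj.timestep
    if max_lag is not None:
        n_keep = int(np.floor(max_lag / traj.timestep)) + 1
        if n_keep > traj.n_frames:
            warnings.warn("max_lag exceeds trajectory length; truncating to available lags")
            n_keep = traj.n_frames
        full, lags, n_pairs = full[:n_keep], lags[:n_keep], n_pairs[:n_keep]
    return MSDCurve(lags=lags, msd=full, n_pairs=n_pairs)


def diffusion_coefficient(
    curve: MSDCurve,
    e_dim: int = 3,
    fit_window: tuple | None = None,
    anomalous_threshold: float = DEFAULT_ANOMALOUS_THRESHOLD,
) -> DiffusionResult:
    """Einstein-relation D with anomalous-regime detection.

    The default window spans 10%-50% of the maximum lag, excluding the
    short-time ballistic/caging regime and the poorly averaged tail.  The
    anomalous exponent is the log-log slope over the same window; when
    ``|alpha_hat - 1|`` exceeds the threshold the result is flagged and
    ``d`` is None (the raw slope stays available as ``d_fit``).
    """
    if e_dim not in (1, 2, 3):
        raise FitError("dimensionality E must be 1, 2 or 3")
    tau_max = curve.lags[-1]
    if fit_window is None:
        fit_window = (0.1 * tau_max, 0.5 * tau_max)
    lo, hi = fit_window
    sel = (curve.lags >= lo) & (curve.lags <= hi) & (curve.lags > 0)
    if sel.sum() < 5:
        raise FitError("fit window must contain at least 5 positive lags")
    tau, m = curve.lags[sel], curve.msd[sel]
    if np.any(m <= 0):
        raise FitError("non-positive MSD values in the fit window")

    slope, _ = np.polyfit(tau, m, 1)
    alpha_hat, _ = np.polyfit(np.log(tau), np.log(m), 1)
    d_fit = float(slope / (2.0 * e_dim))
    anomalous = bool(abs(alpha_hat - 1.0) > anomalous_threshold)
    return DiffusionResult(
        d=None if anomalous else d_fit,
        e_dim=e_dim,
        alpha_hat=float(alpha_hat),
        fit_window=(float(lo), float(hi)),
        anomalous=anomalous,
        d_fit=d_fit,
    )


def detect_flip_flops(
    label_ts: np.ndarray,
    min_dwell: int = DEFAULT_MIN_DWELL,
    molecule_ids: np.ndarray | None = None,
) -> FlipFlopReport:
    """Count leaflet translocations with dwell-time hysteresis.

    ``label_ts`` is ``(n_frames, n_monomers)`` of leaflet codes.  An event
    is recorded when a monomer's label switches to the opposite leaflet
    and that new label persists for ``min_dwell`` consecutive frames;
    shorter excursions — including flickers through ``unassigned`` — do
    not count.  ``frame_start`` is the first frame of the confirming run
    and ``frame_end`` its ``min_dwell``-th frame.
    """
    label_ts = np.asarray(label_ts)
    n_frames, n_mol = label_ts.shape
    if molecule_ids is None:
        molecule_ids = np.arange(n_mol)
    events = []
    for m in range(n_mol):
        seq = label_ts[:, m]
        confirmed = 0
        run_label, run_start, run_len = 0, 0, 0
        for t in range(n_frames):
            lab = seq[t]
            if confirmed == UNASSIGNED:
                if lab in (INNER, OUTER):
                    confirmed = lab
                continue
            if lab == run_label:
                run_len += 1
            else:
                run_label, run_start, run_len = lab, t, 1
            if (
                run_label in (INNER, OUTER)
                and run_label != confirmed
                and run_len == min_dwell
            ):
                events.append(
                    {
                        "molecule_id": int(molecule_ids[m]),
                        "frame_start": int(run_start),
                        "frame_end": int(run_start + min_dwell - 1),
                        "direction": f"{CODE_TO_NAME[confirmed]}->{CODE_TO_NAME[run_label]}",
                    }
                )
                confirmed = run_label
    events.sort(key=lambda e: (e["frame_start"], e["molecule_id"]))
    return FlipFlopReport(events=events)
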