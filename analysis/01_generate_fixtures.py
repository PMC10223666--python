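"""Generate the synthetic vesicle fixtures used by the downstream analyses.

Builds a temperature-series of vesicle compositions (gel, ripple-like mixed,
and fluid tail phases at their reference radii/leaflet splits), gives each a
short Brownian trajectory, plants six flip-flop transits in one of them and a
surface-lying helix in another, and writes everything under
results/fixtures/ as multi-model PDB + topology spec + ground-truth sidecar.
"""

from pathlib import Path

import numpy as np

import vesitraj as vt
from vesitraj.topology import topology_spec_from_map

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"
SEED = 1
N_MONOMERS = 400   # down-scaled composition keeps every driver fast
N_FRAMES = 60

FIXTURES = {
    "DA-0": {},                                  # gel phase
    "DA-25": {"flips": 6},                       # ripple-like, planted flip-flops
    "DA-50": {},                                 # fluid phase
    "DA-110": {"alpha": 0.5},                    # fluid + anomalous motion
    "DAP-25": {"peptide_tilt": 90.0},            # peptide on the bilayer surface
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    for name, opts in FIXTURES.items():
        preset = name.replace("DAP", "DA")
        spec = vt.preset_spec(preset, seed=SEED, n_monomers=N_MONOMERS)
        traj, mmap, truth = vt.make_vesicle(spec)
        if "peptide_tilt" in opts:
            traj, mmap, truth = vt.make_peptide(
                vt.PeptideSpec(planted_tilt=opts["peptide_tilt"], seed=SEED + 1),
                traj, mmap, truth,
            )
        flips = []
        if opts.get("flips"):
            mols = rng.choice(mmap.n_amphiphiles, size=opts["flips"], replace=False)
            frames = np.sort(rng.choice(np.arange(5, N_FRAMES - 25), size=opts["flips"], replace=False))
            flips = list(zip(mols.tolist(), frames.tolist()))
        motion = vt.MotionSpec(
            d_true=0.05,
            alpha=opts.get("alpha", 1.0),
            n_frames=N_FRAMES,
            flip_events=flips,
            seed=SEED + 2,
        )
        traj, truth = vt.make_dynamic_trajectory(traj, mmap, truth, motion)

        base = OUT / name
        vt.write_trajectory(traj, base.with_suffix(".pdb"))
        vt.write_topology_spec(topology_spec_from_map(mmap), base.with_suffix(".topology.yaml"))
        truth.to_json(base.with_suffix(".truth.json"))
        print(
            f"{name}: {traj.n_frames} frames, {traj.n_atoms} atoms, "
            f"thickness {truth.thickness_nm:.2f} nm, inner {truth.inner_fraction_pct:.1f}%"
            + (f", {len(flips)} planted flips" if flips else "")
            + (f", alpha={motion.alpha}" if motion.alpha != 1.0 else "")
        )


if __name__ == "__main__":
    main()
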