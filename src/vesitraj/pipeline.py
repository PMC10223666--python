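"""Batch driver: run every analyzer over a trajectory, emit a summary row.

The pipeline executes aggregate detection -> leaflet assignment ->
headgroup geometry -> MSD/diffusion and flip-flops -> SASA / order
parameters / density map / RDF -> peptide tilt (when a peptide is
declared), time-averaging per-frame values over the equilibrated window,
and writes per-analysis CSV artifacts plus a manifest recording the
resolved configuration, its hash, and the seed.  Identical config +
inputs + seed give byte-identical outputs: iteration order and float
formatting are fixed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics as _dyn
from . import geometry as _geo
from . import peptide as _pep
from . import surface as _surf
from .errors import ConfigurationError, VesitrajError
from .labels import CODE_TO_NAME
from .radii import AtomRadiusTable
from .topology import build_molecule_map
from .trajectory import read_trajectory

DEFAULT_CONFIG = {
    "input": {
        "trajectory": None,
        "format": None,
        "timestep_ns": 0.01,
        "topology": None,
    },
    "label": "run",
    "seed": 0,
    "output_dir": "vesitraj_out",
    "equilibration_fraction": 0.1,
    "geometry": {
        "contact_cutoff_A": 6.0,
        "dead_zone_cos": 0.2,
        "radius_convention": "outer",
    },
    "dynamics": {
        "enabled": True,
        "fit_window_fractions": [0.1, 0.5],
        "anomalous_threshold": 0.2,
        "min_dwell_frames": 20,
        "e_dim": 3,
    },
    "surface": {
        "sasa": True,
        "probe_radius_A": 1.4,
        "n_sphere_points": 960,
        "order_parameters": True,
        "density_map": True,
        "density_leaflet": "outer",
        "density_n_lat": 12,
        "density_n_lon": 24,
        "rdf": False,
        "rdf_r_max_A": 20.0,
        "rdf_bin_width_A": 0.5,
        "analysis_frames": 5,
    },
    "peptide": {
        "normal_cutoff_A": 8.0,
        "min_support": 5,
    },
}

_VALIDATORS = {
    ("input", "timestep_ns"): lambda v: v > 0 or "must be positive",
    ("equilibration_fraction",): lambda v: 0 <= v < 1 or "must lie in [0, 1)",
    ("geometry", "contact_cutoff_A"): lambda v: v > 0 or "must be positive",
    ("geometry", "dead_zone_cos"): lambda v: 0 <= v < 1 or "must lie in [0, 1)",
    ("geometry", "radius_convention"): lambda v: v in ("outer", "inner", "mid") or "must be outer|inner|mid",
    ("dynamics", "anomalous_threshold"): lambda v: v > 0 or "must be positive",
    ("dynamics", "fit_window_fractions"): lambda v: (
        isinstance(v, (list, tuple)) and len(v) == 2 and 0 <= v[0] < v[1] <= 1
    )
    or "must be [lo, hi] fractions with 0 <= lo < hi <= 1",
    ("dynamics", "min_dwell_frames"): lambda v: v >= 1 or "must be >= 1",
    ("dynamics", "e_dim"): lambda v: v in (1, 2, 3) or "must be 1, 2 or 3",
    ("surface", "probe_radius_A"): lambda v: v >= 0 or "must be non-negative",
    ("surface", "n_sphere_points"): lambda v: v >= 100 or "must be >= 100",
    ("surface", "rdf_r_max_A"): lambda v: v > 0 or "must be positive",
    ("surface", "rdf_bin_width_A"): lambda v: v > 0 or "must be positive",
    ("surface", "analysis_frames"): lambda v: v >= 1 or "must be >= 1",
    ("peptide", "normal_cutoff_A"): lambda v: v > 0 or "must be positive",
    ("peptide", "min_support"): lambda v: v >= 1 or "must be >= 1",
}


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration (defaults filled, keys verified)."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SummaryRow:
    """One Table-style report line; None diffusion means anomalous regime."""

    label: str
    radius_nm: float
    thickness_nm: float
    inner_leaflet_pct: float
    diffusion_nm2_ns: float | None
    anomalous: bool
    sasa_nm2: float | None
    flip_flops: int
    tilt_mean_deg: float | None = None

    def as_record(self) -> dict:
        return {
            "label": self.label,
            "radius_nm": f"{self.radius_nm:.2f}",
            "thickness_nm": f"{self.thickness_nm:.2f}",
            "inner_leaflet_pct": f"{self.inner_leaflet_pct:.1f}",
            "diffusion_nm2_ns": "" if self.diffusion_nm2_ns is None else f"{self.diffusion_nm2_ns:.2f}",
            "anomalous": "yes" if self.anomalous else "no",
            "sasa_nm2": "" if self.sasa_nm2 is None else f"{self.sasa_nm2:.0f}",
            "flip_flops": str(self.flip_flops),
            "tilt_mean_deg": "" if self.tilt_mean_deg is None else f"{self.tilt_mean_deg:.1f}",
        }


def _check_keys(user: dict, defaults: dict, path=()) -> list:
    errs = []
    for k, v in user.items():
        if k not in defaults:
            errs.append(f"unknown key {'.'.join(path + (k,))!r}")
        elif isinstance(defaults[k], dict) and defaults[k] and isinstance(v, dict):
            errs.extend(_check_keys(v, defaults[k], path + (k,)))
    return errs


def _merge(defaults: dict, user: dict) -> dict:
    out = copy.deepcopy(defaults)
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(source) -> RunConfig:
    """Load + validate a config (path, YAML string, or dict).

    Every unknown key and every out-of-range value is reported at once in
    a single :class:`ConfigurationError`.
    """
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, dict):
        user = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(["config must be a mapping"])

    errs = _check_keys(user, DEFAULT_CONFIG)
    merged = _merge(DEFAULT_CONFIG, user)
    for keys, check in _VALIDATORS.items():
        node = merged
        for k in keys:
            node = node[k]
        try:
            verdict = check(node)
        except TypeError:
            verdict = "has the wrong type"
        if verdict is not True:
            errs.append(f"{'.'.join(keys)}: {verdict} (got {node!r})")
    if merged["input"]["trajectory"] is not None and not Path(merged["input"]["trajectory"]).exists():
        errs.append(f"input.trajectory: file not found: {merged['input']['trajectory']}")
    if merged["input"]["topology"] is not None and not Path(merged["input"]["topology"]).exists():
        errs.append(f"input.topology: file not found: {merged['input']['topology']}")
    if errs:
        raise ConfigurationError(errs)
    return RunConfig(data=merged)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def run_pipeline(config, trajectory=None, molecule_map=None) -> SummaryRow:
    """Execute all enabled analyses and write artifacts to ``output_dir``.

    ``trajectory``/``molecule_map`` may be passed directly (already in
    memory); otherwise they are read from the paths in the config.
    """
    cfg = validate_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    stage = "setup"

    try:
        t0 = time.perf_counter()
        if trajectory is None:
            if cfg["input"]["trajectory"] is None or cfg["input"]["topology"] is None:
                raise ConfigurationError(["input.trajectory and input.topology are required"])
            trajectory = read_trajectory(
                cfg["input"]["trajectory"],
                format=cfg["input"]["format"],
                timestep=cfg["input"]["timestep_ns"],
            )
            molecule_map = build_molecule_map(trajectory, cfg["input"]["topology"])
        if molecule_map is None:
            raise ConfigurationError(["molecule_map must accompany an in-memory trajectory"])
        stage_times[stage] = time.perf_counter() - t0

        n_frames = trajectory.n_frames
        first_eq = int(np.floor(cfg["equilibration_fraction"] * n_frames))
        eq_frames = np.arange(first_eq, n_frames)
        geo_cfg = cfg["geometry"]

        # --- leaflets + geometry ------------------------------------------
        stage = "geometry"
        t0 = time.perf_counter()
        labels_ts = _geo.label_timeseries(trajectory, molecule_map, geo_cfg["dead_zone_cos"])
        rows = []
        for i in eq_frames:
            fr = trajectory.frame(int(i))
            g = _geo.vesicle_geometry(
                fr, molecule_map, labels_ts[i], trajectory.elements, geo_cfg["radius_convention"]
            )
            rows.append(
                {
                    "frame": int(i),
                    "time_ns": i * trajectory.timestep,
                    "radius_nm": g.radius,
                    "thickness_nm": g.thickness,
                    "inner_fraction_pct": g.inner_fraction,
                    "n_unassigned": int(round(g.unassigned_fraction * len(labels_ts[i]) / 100.0)),
                }
            )
        geo_df = pd.DataFrame(rows)
        _write_csv(geo_df, out / "geometry.csv")
        agg = _geo.detect_aggregates(
            trajectory.frame(n_frames - 1), molecule_map, geo_cfg["contact_cutoff_A"]
        )
        stage_times[stage] = time.perf_counter() - t0

        # --- dynamics ------------------------------------------------------
        stage = "dynamics"
        t0 = time.perf_counter()
        diff = None
        flips = _dyn.detect_flip_flops(
            labels_ts,
            min_dwell=cfg["dynamics"]["min_dwell_frames"],
            molecule_ids=molecule_map.amphiphile_ids,
        )
        flip_df = pd.DataFrame(
            flips.events or [],
            columns=["molecule_id", "frame_start", "frame_end", "direction"],
        )
        flip_df.insert(1, "t_start_ns", flip_df["frame_start"] * trajectory.timestep)
        flip_df.insert(2, "t_end_ns", flip_df["frame_end"] * trajectory.timestep)
        _write_csv(flip_df, out / "flip_flops.csv")
        if cfg["dynamics"]["enabled"] and n_frames >= 20:
            curve = _dyn.msd(trajectory, molecule_map)
            _write_csv(
                pd.DataFrame({"lag_ns": curve.lags, "msd_nm2": curve.msd, "n_pairs": curve.n_pairs}),
                out / "msd.csv",
            )
            lo, hi = cfg["dynamics"]["fit_window_fractions"]
            diff = _dyn.diffusion_coefficient(
                curve,
                e_dim=cfg["dynamics"]["e_dim"],
                fit_window=(lo * curve.lags[-1], hi * curve.lags[-1]),
                anomalous_threshold=cfg["dynamics"]["anomalous_threshold"],
            )
        stage_times[stage] = time.perf_counter() - t0

        # --- surface -------------------------------------------------------
        stage = "surface"
        t0 = time.perf_counter()
        surf_cfg = cfg["surface"]
        pick = eq_frames[
            np.unique(np.linspace(0, len(eq_frames) - 1, min(surf_cfg["analysis_frames"], len(eq_frames))).astype(int))
        ]
        sasa_total = None
        if surf_cfg["sasa"]:
            table = AtomRadiusTable(probe_radius=surf_cfg["probe_radius_A"])
            res = _surf.sasa(
                trajectory.frame(int(pick[-1])),
                trajectory.elements,
                radii=table,
                n_points=surf_cfg["n_sphere_points"],
                selection=molecule_map.amphiphile_atoms,
            )
            sasa_total = res.total
            _write_csv(
                pd.DataFrame({"frame": [int(pick[-1])], "sasa_nm2": [res.total]}),
                out / "sasa.csv",
            )
        if surf_cfg["order_parameters"]:
            prof = _surf.order_parameters(trajectory, molecule_map, labels_ts, frames=pick)
            _write_csv(
                pd.DataFrame(
                    {"carbon_index": prof.carbon_index, "s": prof.s, "n_samples": prof.n_samples}
                ),
                out / "order_parameters.csv",
            )
        if surf_cfg["density_map"]:
            dm = _surf.density_map(
                trajectory,
                molecule_map,
                labels_ts,
                leaflet=surf_cfg["density_leaflet"],
                n_lat=surf_cfg["density_n_lat"],
                n_lon=surf_cfg["density_n_lon"],
                frames=pick,
            )
            np.savetxt(out / "density_map.txt", dm.density, fmt="%.6f", header=dm.projection)
        if surf_cfg["rdf"] and molecule_map.has_peptide:
            heads = np.concatenate([molecule_map.headgroup_o1, molecule_map.headgroup_o2])
            curve_r = _surf.rdf(
                trajectory,
                molecule_map.peptide_calphas,
                heads,
                r_max=surf_cfg["rdf_r_max_A"],
                bin_width=surf_cfg["rdf_bin_width_A"],
                frames=pick,
            )
            _write_csv(pd.DataFrame({"r_A": curve_r.r, "g": curve_r.g}), out / "rdf.csv")
        stage_times[stage] = time.perf_counter() - t0

        # --- peptide -------------------------------------------------------
        stage = "peptide"
        t0 = time.perf_counter()
        tilt_mean = None
        if molecule_map.has_peptide:
            ts = _pep.tilt_series(
                trajectory,
                molecule_map,
                cutoff=cfg["peptide"]["normal_cutoff_A"],
                min_support=cfg["peptide"]["min_support"],
            )
            _write_csv(
                pd.DataFrame(
                    {
                        "time_ns": ts.times,
                        "tilt_deg": ts.tilt_deg,
                        "class": ts.tilt_class,
                        "support_count": ts.support,
                        "missing": ts.missing.astype(int),
                    }
                ),
                out / "tilt.csv",
            )
            if np.isfinite(ts.tilt_deg).any():
                tilt_mean = float(np.nanmean(ts.tilt_deg))
        stage_times[stage] = time.perf_counter() - t0

        # --- summary -------------------------------------------------------
        summary = SummaryRow(
            label=cfg["label"],
            radius_nm=float(geo_df["radius_nm"].mean()),
            thickness_nm=float(geo_df["thickness_nm"].mean()),
            inner_leaflet_pct=float(geo_df["inner_fraction_pct"].mean()),
            diffusion_nm2_ns=None if diff is None else diff.d,
            anomalous=bool(diff.anomalous) if diff is not None else False,
            sasa_nm2=sasa_total,
            flip_flops=flips.count,
            tilt_mean_deg=tilt_mean,
        )
        _write_csv(pd.DataFrame([summary.as_record()]), out / "summary.csv")
        manifest = {
            "label": cfg["label"],
            "seed": cfg.seed,
            "config_hash": cfg.config_hash,
            "config": cfg.data,
            "n_frames": int(n_frames),
            "equilibrated_from_frame": int(first_eq),
            "n_aggregates": int(agg.n_clusters),
            "largest_aggregate": int(agg.largest_size),
            "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, VesitrajError):
            raise
        raise VesitrajError(f"pipeline stage {stage!r} failed: {exc}") from exc


def merge_summaries(paths) -> pd.DataFrame:
    """Stack per-run summary.csv files into one report table."""
    frames = [pd.read_csv(p, dtype=str, keep_default_na=False) for p in paths]
    return pd.concat(frames, ignore_index=True)
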