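"""Pipeline orchestration, configuration and report export.

``run_pipeline`` chains the stages shell -> order parameters -> residue
descriptors -> relaxation -> coupling for one or more replicate
trajectories and writes a standard output bundle:

* ``residue_summary.csv``   - one row per protein residue
* ``headline_stats.json``   - correlations, slopes, class stats, groups
* ``zeta_series.csv`` / ``rmsd_series.csv`` - per-residue time series
* ``descriptors.csv``, ``relaxation.csv``   - per-stage tables
* ``run_log.json``          - every parameter used and every record dropped

All defaults follow the conventional analysis constants: 5.0 A hydration
shell, 3.5 A / 40 deg hydrogen-bond criterion, 0.1 ACF crossing, the
10%-of-segment validity filter, velocity intervals {0.1, 1.0} ps and a
1.4 A SASA probe.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling, descriptors, order, relaxation, shell
from .exceptions import (
    ConfigurationError,
    EmptyTrajectoryError,
    UndefinedCorrelationError,
)
from .series import GappedSeries
from .trajectory import Frame, FrameSet, Topology, load_system


@dataclass
class RunConfig:
    """Flat key-value configuration; CLI flags override file values."""

    topology: str | None = None
    trajectories: list[str] = field(default_factory=list)
    window_start: float | None = None  # ps
    window_end: float | None = None  # ps
    shell_cutoff: float = shell.DEFAULT_SHELL_CUTOFF
    contact_water_site: str = "oxygen"
    contact_residue_atoms: str = "heavy"
    hb_oo_cutoff: float = order.HB_OO_CUTOFF
    hb_angle_deviation_max: float = order.HB_ANGLE_DEVIATION_MAX
    q_neighbor_count: int = order.Q_NEIGHBOR_COUNT
    probe_radius: float = descriptors.DEFAULT_PROBE_RADIUS
    sasa_points: int = descriptors.DEFAULT_SASA_POINTS
    sasa_stride: int = 0  # 0 = auto (~40 frames)
    rmsf_selection: str = "heavy"
    rmsd_reference: str = "first"
    histidine_class: str = "charged"
    acf_max_lag_fraction: float = relaxation.ACF_MAX_LAG_FRACTION
    tau_validity_fraction: float = relaxation.TAU_VALIDITY_FRACTION
    crossing_threshold: float = relaxation.CROSSING_THRESHOLD
    min_segment_frames: int = relaxation.MIN_SEGMENT_FRAMES
    vzeta_deltas: tuple[float, ...] = (0.1, 1.0)
    halfwidth_bin: float = 0.1
    replicate_mode: str = "pool"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "vzeta_deltas" in data:
            data["vzeta_deltas"] = tuple(data["vzeta_deltas"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vzeta_deltas"] = list(self.vzeta_deltas)
        return d


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    headline: dict
    zeta_series: dict[int, GappedSeries]
    rmsd_series: dict[int, GappedSeries]
    descriptor_table: pd.DataFrame
    relaxation_table: pd.DataFrame
    counts: dict


def _auto_stride(n_frames: int, target: int = 40) -> int:
    return max(1, n_frames // target)


def _pool_series(per_replicate: list[dict[int, GappedSeries]]):
    """Concatenate replicate series per residue, never bridging replicates.

    A single NaN separator between replicates guarantees that no
    autocorrelation segment spans a replicate boundary.
    """
    residues = sorted({r for d in per_replicate for r in d})
    pooled: dict[int, GappedSeries] = {}
    for r in residues:
        parts: list[np.ndarray] = []
        dt = None
        quantity = "zeta"
        for d in per_replicate:
            if r not in d:
                continue
            s = d[r]
            dt = s.dt if dt is None else dt
            quantity = s.quantity
            if parts:
                parts.append(np.asarray([np.nan]))
            parts.append(s.values)
        pooled[r] = GappedSeries(r, np.concatenate(parts), dt, quantity)
    return pooled


def analyze(
    framesets: FrameSet | list[FrameSet],
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on one or more in-memory replicates."""
    cfg = config or RunConfig()
    if isinstance(framesets, FrameSet):
        framesets = [framesets]
    if not framesets:
        raise EmptyTrajectoryError("no replicate trajectories given")

    zeta_per_rep: list[dict[int, GappedSeries]] = []
    rmsd_per_rep: list[dict[int, GappedSeries]] = []
    desc_tables: list[pd.DataFrame] = []
    counts = {
        "undefined_zeta_records": 0,
        "segments_dropped_short": 0,
        "segments_dropped_validity": 0,
        "segments_no_crossing": 0,
        "segments_degenerate": 0,
        "residue_frames_without_contact": 0,
    }

    for fs in framesets:
        if cfg.window_start is not None or cfg.window_end is not None:
            fs = fs.slice_time(cfg.window_start, cfg.window_end)
        assignments = shell.assign_all(
            fs, cfg.shell_cutoff, cfg.contact_water_site,
            cfg.contact_residue_atoms,
        )
        zres = order.residue_zeta_series(
            fs, assignments, cfg.hb_oo_cutoff, cfg.hb_angle_deviation_max
        )
        counts["undefined_zeta_records"] += zres.n_undefined_records
        counts["residue_frames_without_contact"] += sum(
            zres.n_frames_without_contact.values()
        )
        zeta_per_rep.append(zres.series)
        rmsd_per_rep.append(
            descriptors.residue_rmsd_series(fs, reference_index=0,
                                            fit_selection=cfg.rmsf_selection)
        )
        stride = cfg.sasa_stride or _auto_stride(fs.n_frames)
        desc_tables.append(
            descriptors.descriptor_table(
                fs,
                rmsf_selection=cfg.rmsf_selection,
                probe=cfg.probe_radius,
                n_points=cfg.sasa_points,
                sasa_stride=stride,
                histidine=cfg.histidine_class,
            )
        )

    if cfg.replicate_mode not in ("pool", "average"):
        raise ConfigurationError(f"unknown replicate_mode {cfg.replicate_mode!r}")
    zeta_series = _pool_series(zeta_per_rep)
    rmsd_series = _pool_series(rmsd_per_rep)

    desc = desc_tables[0][["name", "class"]].copy()
    desc["rmsf"] = np.mean([t["rmsf"] for t in desc_tables], axis=0)
    desc["sasa"] = np.mean([t["sasa"] for t in desc_tables], axis=0)

    relax_rows = []
    tau_zeta, tau_rmsd = {}, {}
    sigma_zeta, sigma_rmsd, mean_zeta = {}, {}, {}
    for quantity, series_map, sink in (
        ("zeta", zeta_series, tau_zeta),
        ("rmsd", rmsd_series, tau_rmsd),
    ):
        for r, s in series_map.items():
            res = relaxation.residue_relaxation(
                s,
                min_length=cfg.min_segment_frames,
                threshold=cfg.crossing_threshold,
                validity_fraction=cfg.tau_validity_fraction,
                max_lag_fraction=cfg.acf_max_lag_fraction,
            )
            counts["segments_dropped_short"] += res.n_dropped_short
            counts["segments_dropped_validity"] += res.n_filtered
            counts["segments_no_crossing"] += res.n_no_crossing
            counts["segments_degenerate"] += res.n_degenerate
            sink[r] = res.residue_tau
            relax_rows.append(
                {
                    "residue": r,
                    "quantity": quantity,
                    "n_segments": len(res.segment_taus),
                    "n_valid": res.n_valid,
                    "tau_mean": res.residue_tau,
                }
            )
    for r, s in zeta_series.items():
        vals = s.values[s.defined_mask]
        mean_zeta[r] = float(vals.mean()) if vals.size else np.nan
        sigma_zeta[r] = float(vals.std()) if vals.size > 1 else np.nan
    for r, s in rmsd_series.items():
        vals = s.values[s.defined_mask]
        sigma_rmsd[r] = float(vals.std()) if vals.size > 1 else np.nan

    summary, headline = coupling.build_summary(
        desc,
        pd.Series(mean_zeta, name="mean_zeta"),
        pd.Series(sigma_zeta, name="sigma_zeta"),
        pd.Series(sigma_rmsd, name="sigma_rmsd"),
        pd.Series(tau_zeta, name="tau_zeta"),
        pd.Series(tau_rmsd, name="tau_rmsd"),
    )
    headline["vzeta_halfwidth"] = _vzeta_halfwidths(
        zeta_series, summary, cfg.vzeta_deltas, cfg.halfwidth_bin
    )
    return PipelineResult(
        summary,
        headline,
        zeta_series,
        rmsd_series,
        desc,
        pd.DataFrame(relax_rows),
        counts,
    )


def _vzeta_halfwidths(zeta_series, summary, deltas, bin_width) -> dict:
    """FWHM of the order-parameter velocity distribution per residue class."""
    out: dict = {}
    for delta in deltas:
        per_class = {}
        for cls in coupling.CLASS_LABELS:
            residues = summary.index[summary["class"] == cls]
            samples = []
            for r in residues:
                if r in zeta_series:
                    try:
                        samples.append(
                            relaxation.order_velocity(zeta_series[r], delta)
                        )
                    except ConfigurationError:
                        break
            pooled = np.concatenate(samples) if samples else np.empty(0)
            try:
                per_class[cls] = relaxation.distribution_halfwidth(
                    pooled, bin_width
                )
            except ConfigurationError:
                per_class[cls] = None
        out[str(delta)] = per_class
    return out


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def _series_frame(series_map: dict[int, GappedSeries]) -> pd.DataFrame:
    data = {f"res_{r + 1}": s.values for r, s in sorted(series_map.items())}
    df = pd.DataFrame(data)
    df.insert(0, "frame", np.arange(len(df)))
    return df


def write_bundle(result: PipelineResult, outdir, config: RunConfig) -> dict:
    """Write the standard output files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary = result.summary.copy()
    summary.insert(0, "residue_id", summary.index + 1)  # 1-based in reports
    paths["residue_summary"] = outdir / "residue_summary.csv"
    summary.to_csv(paths["residue_summary"], index=False)

    paths["headline_stats"] = outdir / "headline_stats.json"
    with open(paths["headline_stats"], "w") as fh:
        json.dump(result.headline, fh, indent=2, sort_keys=True)

    paths["descriptors"] = outdir / "descriptors.csv"
    desc = result.descriptor_table.copy()
    desc.insert(0, "residue_id", desc.index + 1)
    desc.to_csv(paths["descriptors"], index=False)

    paths["relaxation"] = outdir / "relaxation.csv"
    result.relaxation_table.to_csv(paths["relaxation"], index=False)

    paths["zeta_series"] = outdir / "zeta_series.csv"
    _series_frame(result.zeta_series).to_csv(paths["zeta_series"], index=False)
    paths["rmsd_series"] = outdir / "rmsd_series.csv"
    _series_frame(result.rmsd_series).to_csv(paths["rmsd_series"], index=False)

    paths["run_log"] = outdir / "run_log.json"
    with open(paths["run_log"], "w") as fh:
        json.dump(
            {"config": config.to_dict(), "dropped": result.counts},
            fh, indent=2, sort_keys=True,
        )
    return {k: str(v) for k, v in paths.items()}


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Load the configured trajectories, analyze, and optionally write."""
    if config.topology is None or not config.trajectories:
        raise ConfigurationError("config must name a topology and >=1 trajectory")
    framesets = [load_system(config.topology, t) for t in config.trajectories]
    result = analyze(framesets, config)
    if outdir is not None:
        write_bundle(result, outdir, config)
    return result


# ---------------------------------------------------------------------------
# B-factor export
# ---------------------------------------------------------------------------

_BFACTOR_MAX = 999.99
_UNDEFINED_SENTINEL = -1.0


def export_bfactor_pdb(
    frame: Frame,
    topology: Topology,
    values: dict[int, float] | pd.Series,
    field_name: str,
    path,
) -> float:
    """Write a PDB with per-residue values in the B-factor column.

    Residues with undefined values receive the sentinel -1.00 and are
    listed in a REMARK; values exceeding the column range are scaled and
    the factor recorded in a REMARK.  Returns the scale factor applied
    (1.0 when none was needed).
    """
    import MDAnalysis as mda
    from .trajectory import _universe_from_frameset

    vals = pd.Series(dict(values), dtype=float)
    finite = vals.dropna()
    scale = 1.0
    if len(finite) and finite.abs().max() > _BFACTOR_MAX:
        scale = _BFACTOR_MAX / float(finite.abs().max())
    per_res = np.full(topology.n_residues, _UNDEFINED_SENTINEL)
    undefined = []
    for r in topology.protein_residues:
        v = vals.get(int(r), np.nan)
        if np.isfinite(v):
            per_res[int(r)] = v * scale
        else:
            undefined.append(int(r) + 1)

    fs = FrameSet(
        topology,
        frame.coordinates[None],
        frame.box[None],
        np.asarray([frame.time]),
    )
    u = _universe_from_frameset(fs)
    u.add_TopologyAttr("tempfactors",
                       per_res[topology.atom_resindices].round(2))
    remarks = [
        f"per-residue field: {field_name}",
        f"scale factor applied to B-factors: {scale:.6g}",
        "undefined residues (sentinel -1.00): "
        + (",".join(map(str, undefined)) if undefined else "none"),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=False,
                        remarks="; ".join(remarks)) as w:
            w.write(u.atoms)
    return scale
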