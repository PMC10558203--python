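"""Formats, configuration, fixture generation, and reporting.

On-disk dialect: image stacks are multi-page TIFF with a JSON sidecar
listing one (index, t, epoch, wavelength, intensity) entry per page; ROI
masks are 16-bit label TIFFs; traces, calibrations, and kinetics are CSV;
configs and results are JSON/YAML. All writes go through a
write-temp-then-rename helper so interrupted runs never leave truncated
files.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import core_model as cm
from . import monolayer as ml
from .pipeline import FrameStack, ROISet

SCENARIOS = ("fig1-neurons", "fig2-stripes", "three-opsins")


# ---------------------------------------------------------------------------
# Atomic writes
# ---------------------------------------------------------------------------

def atomic_write_bytes(path: Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: Path, text: str) -> None:
    atomic_write_bytes(path, text.encode())


def write_json(path: Path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True,
                                       default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Stack + sidecar dialect
# ---------------------------------------------------------------------------

def write_stack(path_tiff: Path, path_sidecar: Path, stack: np.ndarray,
                t: np.ndarray, labels: np.ndarray,
                wavelengths: np.ndarray | None = None,
                intensities: np.ndarray | None = None) -> None:
    """Multi-page TIFF plus per-frame JSON schedule sidecar."""
    path_tiff = Path(path_tiff)
    path_tiff.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path_tiff.parent,
                               prefix=path_tiff.name + ".tmp")
    os.close(fd)
    try:
        tifffile.imwrite(tmp, np.asarray(stack), photometric="minisblack")
        os.replace(tmp, path_tiff)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    n = len(stack)
    wl = wavelengths if wavelengths is not None else np.full(n, 561.0)
    inten = intensities if intensities is not None else np.zeros(n)
    entries = [{"index": i, "t_s": float(t[i]), "epoch": str(labels[i]),
                "wavelength_nm": float(wl[i]),
                "intensity_mw_cm2": float(inten[i])} for i in range(n)]
    write_json(path_sidecar, {"frames": entries})


def read_stack(path_tiff: Path, path_sidecar: Path) -> FrameStack:
    """Lossless stack load with timestamps/labels attached from the
    sidecar; page/entry count mismatch is an error naming the index."""
    try:
        data = tifffile.imread(path_tiff)
    except Exception as exc:
        raise ValueError(f"unreadable TIFF {path_tiff}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    with open(path_sidecar) as fh:
        sidecar = json.load(fh)
    entries = sidecar["frames"]
    if len(entries) != len(data):
        raise ValueError(
            f"sidecar has {len(entries)} entries but the TIFF has "
            f"{len(data)} pages; first unmatched index "
            f"{min(len(entries), len(data))}")
    t = np.array([e["t_s"] for e in entries])
    labels = np.array([e["epoch"] for e in entries])
    return FrameStack(data=data, t=t, labels=labels)


def write_label_mask(path: Path, mask: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".tmp")
    os.close(fd)
    try:
        tifffile.imwrite(tmp, np.asarray(mask, dtype=np.uint16),
                         photometric="minisblack")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_roi_set(path_mask: Path, categories: dict[int, str],
                 parents: dict[int, int] | None = None) -> ROISet:
    mask = tifffile.imread(path_mask)
    return ROISet(mask=mask, categories=categories, parents=parents or {})


def write_trace_csv(path: Path, trace: cm.SimTrace) -> None:
    df = pd.DataFrame({"t_s": trace.t, "V_mV": trace.V, "pH": trace.pH,
                       "F": trace.F, "epoch": trace.epoch})
    atomic_write_text(path, df.to_csv(index=False))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "geometry": cm.CompartmentGeometry,
    "opsin": cm.OpsinParams,
    "sensor": cm.SensorParams,
    "physiology": cm.PhysiologyParams,
}

_TOP_KEYS = {"geometry", "opsin", "sensor", "physiology", "protocol",
             "monolayer", "pipeline", "ephys", "seed", "out", "log_level"}


def _build(cls, section: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: "
                         f"{sorted(unknown)}")
    kwargs = dict(section)
    if cls is cm.OpsinParams and "spectrum" in kwargs:
        kwargs["spectrum"] = {float(k): float(v)
                              for k, v in kwargs["spectrum"].items()}
    return cls(**kwargs)


def load_config(path: Path) -> dict:
    """YAML/JSON config with unknown top-level keys rejected."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return cfg


def config_to_params(cfg: dict):
    """(geometry, opsin, sensor, physiology, protocol) from a config dict;
    missing sections fall back to package defaults."""
    geom = _build(cm.CompartmentGeometry,
                  cfg.get("geometry", {"shape": "sphere", "radius": 7.5}),
                  "geometry")
    opsin = _build(cm.OpsinParams,
                   cfg.get("opsin", dataclasses.asdict(cm.CHERIFF_LIKE)),
                   "opsin")
    sensor = _build(cm.SensorParams, cfg.get("sensor", {}), "sensor")
    phys = _build(cm.PhysiologyParams, cfg.get("physiology", {}),
                  "physiology")
    pcfg = dict(cfg.get("protocol", {}))
    allowed = {"stim_s", "image_s", "active_total", "recovery_total",
               "stim_intensity", "image_intensity"}
    unknown = set(pcfg) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section 'protocol': "
                         f"{sorted(unknown)}")
    protocol = cm.build_protocol(
        pcfg.get("stim_s", 0.5), pcfg.get("image_s", 1.0),
        pcfg.get("active_total", 150.0), pcfg.get("recovery_total", 150.0),
        stim_intensity=pcfg.get("stim_intensity", cm.DEFAULT_STIM_INTENSITY),
        image_intensity=pcfg.get("image_intensity",
                                 cm.DEFAULT_IMAGE_INTENSITY))
    return geom, opsin, sensor, phys, protocol


def write_resolved_config(path: Path, cfg: dict, seed: int | None) -> None:
    """Record the fully-resolved config + seed beside a run's outputs."""
    out = dict(cfg)
    out["seed"] = seed
    atomic_write_text(path, yaml.safe_dump(out, sort_keys=True))


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def _soma_dendrite_layout(n_cells: int, n_controls: int, frame: int,
                          rng: np.random.Generator):
    """Disk somas with a thin dendrite disk each, plus control somas, on a
    non-overlapping grid."""
    shapes = []
    label = 1
    per_row = max(1, int(np.floor(frame / 16)))
    k = 0
    for i in range(n_cells + n_controls):
        r, c = divmod(k, per_row)
        cy, cx = 8 + 16 * r, 8 + 16 * c
        k += 1
        if cy + 6 > frame:
            break
        if i < n_cells:
            soma_lbl = label
            shapes.append(cm.ROIShape(soma_lbl, (cy, cx), 4.0, "soma"))
            shapes.append(cm.ROIShape(soma_lbl + 1, (cy, cx + 7), 1.5,
                                      "dendrite", parent=soma_lbl))
            label += 2
        else:
            shapes.append(cm.ROIShape(label, (cy, cx), 4.0, "control"))
            label += 1
    return shapes


def make_fixtures(scenario: str, seed: int, out_dir: Path,
                  duration_scale: float = 1.0) -> dict:
    """Write a deterministic synthetic dataset for a named scenario.

    Scenarios: 'fig1-neurons' (somas + dendrites + opsin-negative controls
    under the 150+150-s interleaved protocol), 'fig2-stripes' (monolayer
    with 95/95-um stripes), 'three-opsins' (proton-conducting vs two
    proton-tight populations). ``duration_scale`` shortens the protocols
    proportionally for quick runs. Returns the ground-truth dict that is
    also written to ground_truth.json.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; known: {list(SCENARIOS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth: dict = {"scenario": scenario, "seed": seed}

    if scenario == "fig1-neurons":
        active = 150.0 * duration_scale
        recovery = 150.0 * duration_scale
        protocol = cm.build_protocol(0.5, 1.0, active, recovery)
        frame = 64
        shapes = _soma_dendrite_layout(3, 2, frame, rng)
        sensor = cm.SensorParams(noise_sd=0.01)
        phys = cm.PhysiologyParams()
        traces = []
        truth["rois"] = {}
        for shp in shapes:
            if shp.category == "dendrite":
                geom = cm.CompartmentGeometry("cylinder", 1.0, 60.0)
                opsin = _scaled_opsin(cm.CHERIFF_LIKE, geom)
            elif shp.category == "soma":
                geom = cm.CompartmentGeometry("sphere", 7.5)
                opsin = _scaled_opsin(cm.CHERIFF_LIKE, geom)
            else:
                geom = cm.CompartmentGeometry("sphere", 7.5)
                opsin = dataclasses.replace(
                    _scaled_opsin(cm.CHERIFF_LIKE, geom), f_H=0.0)
            tr = cm.simulate_cell(geom, opsin, sensor, phys, protocol,
                                  seed=int(rng.integers(2 ** 31)), dt=1e-3)
            traces.append(tr)
            truth["rois"][str(shp.label)] = {
                "category": shp.category, "parent": shp.parent,
                "pH_final": float(tr.pH[np.searchsorted(tr.t, active) - 1]),
                "pH_min": float(tr.pH.min())}
        stack, t, labels, mask = cm.render_movie(
            traces, shapes, (frame, frame), seed=seed, frame_rate=4.0,
            pixel_noise_sd=2.0)
        write_stack(out_dir / "stack.tif", out_dir / "stack.json",
                    stack.astype(np.float32), t, labels)
        write_label_mask(out_dir / "rois.tif", mask)
        cats = {s.label: s.category for s in shapes}
        parents = {s.label: s.parent for s in shapes
                   if s.parent is not None}
        write_json(out_dir / "rois.json",
                   {"categories": cats, "parents": parents})
        calib = calibration_pairs_from_sensor(sensor)
        atomic_write_text(out_dir / "calibration.csv",
                          pd.DataFrame(calib, columns=["pH", "dff"])
                          .to_csv(index=False))
        truth["protocol"] = {"stim_s": 0.5, "image_s": 1.0,
                             "active_total": active,
                             "recovery_total": recovery}

    elif scenario == "fig2-stripes":
        grid = ml.MonolayerGrid(n_x=100, n_y=20, g_gap=450.0)
        pattern = ml.stripe_pattern(grid, 95.0, 95.0)
        end = ml.simulate_monolayer(grid, pattern,
                                    13.5 * max(duration_scale, 0.1))
        contrast = ml.acidification_contrast([grid, end], pattern)
        write_label_mask(out_dir / "stripe_mask.tif",
                         pattern.mask.astype(np.uint16))
        np.savetxt(out_dir / "V_map.csv", end.V, delimiter=",")
        np.savetxt(out_dir / "pH_map.csv", end.pH, delimiter=",")
        truth["contrast"] = dataclasses.asdict(contrast)
        truth["stripe_on_um"] = 95.0
        truth["stripe_gap_um"] = 95.0

    else:  # three-opsins
        active = 60.0 * duration_scale
        protocol = cm.build_protocol(0.5, 1.0, active, 0.0)
        geom = cm.CompartmentGeometry("sphere", 7.5)
        sensor = cm.SensorParams(noise_sd=0.01)
        phys = cm.PhysiologyParams()
        pops = {"cheriff_like": cm.CHERIFF_LIKE,
                "chr2_3m_like": cm.CHR2_3M_LIKE,
                "pscatch2_like": cm.PSCATCH2_LIKE}
        truth["populations"] = {}
        for name, opsin in pops.items():
            finals = []
            for _ in range(8):
                tr = cm.simulate_cell(geom, opsin, sensor, phys, protocol,
                                      seed=int(rng.integers(2 ** 31)),
                                      dt=1e-3)
                finals.append(float(tr.pH[-1]))
            truth["populations"][name] = {"f_H": opsin.f_H,
                                          "pH_final": finals}
        write_json(out_dir / "populations.json", truth["populations"])

    write_json(out_dir / "ground_truth.json", truth)
    return truth


def _scaled_opsin(base: cm.OpsinParams,
                  geom: cm.CompartmentGeometry) -> cm.OpsinParams:
    """Scale whole-cell conductance with membrane area (uniform channel
    density), referenced to a 7.5-um soma."""
    ref = cm.CompartmentGeometry("sphere", 7.5).area_um2
    return dataclasses.replace(base, g_max=base.g_max
                               * geom.area_um2 / ref)


def calibration_pairs_from_sensor(sensor: cm.SensorParams,
                                  pH_values=(6.4, 6.7, 7.0, 7.3),
                                  ) -> list[tuple[float, float]]:
    """(pH, dF/F) knots sampled from the sensor's protonation curve, with
    dF/F referenced to pH 7.3 (the calibration baseline convention)."""
    F_ref = float(sensor.fluorescence(7.3))
    return [(float(p), float((sensor.fluorescence(p) - F_ref) / F_ref))
            for p in pH_values]


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def run_report(results_dir: Path, out_dir: Path | None = None) -> dict:
    """Summarize completed analysis outputs: per-group kinetics table,
    comparisons, and trace plots, plus a machine-readable JSON twin."""
    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir
    kin_path = results_dir / "kinetics.csv"
    if not kin_path.exists():
        raise ValueError(f"missing analysis outputs in {results_dir} "
                         "(kinetics.csv not found)")
    kin = pd.read_csv(kin_path)
    summary: dict = {"n_rois": int(len(kin))}
    if "category" in kin.columns:
        grp = kin.groupby("category").agg(
            n=("pH_min", "size"), pH_min_mean=("pH_min", "mean"),
            pH_min_sd=("pH_min", "std"))
        summary["by_category"] = grp.reset_index().to_dict("records")
    comp_path = results_dir / "comparison.json"
    if comp_path.exists():
        with open(comp_path) as fh:
            summary["comparison"] = json.load(fh)

    traces_path = results_dir / "traces.csv"
    if traces_path.exists():
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        tr = pd.read_csv(traces_path)
        fig, ax = plt.subplots(figsize=(6, 4))
        for lbl, sub in tr.groupby("roi"):
            ax.plot(sub["epoch_t_s"], sub.get("pH", sub["dff_raw"]),
                    lw=0.8, label=str(lbl))
        ax.set_xlabel("time (s)")
        ax.set_ylabel("pH" if "pH" in tr.columns else "dF/F")
        fig.tight_layout()
        fig.savefig(out_dir / "traces.png", dpi=120)
        plt.close(fig)

    write_json(out_dir / "report.json", summary)
    return summary
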