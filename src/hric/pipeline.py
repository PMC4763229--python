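"""End-to-end pipelines: validated config in, reproducible artifacts out.

Configuration is a plain mapping (typically loaded from YAML) validated
against a documented schema before any stage runs.  Every run writes a
``manifest.json`` recording the resolved config, the seed, and every output
file with the stage that produced it; numeric artifacts (CSV/JSON) are
byte-reproducible from config + seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import design as design_mod
from .imaging import (
    PseudoColorSpec,
    classify_nuclei,
    measurements_to_dataframe,
    per_nucleus_ratios,
    pseudo_color,
    ratio_image,
    segment_nuclei,
)
from .profiles import (
    CellTypeProfile,
    Sensor,
    SensorSet,
    SimulationConfig,
    SpilloverMatrix,
    Subpopulation,
)
from .ratiometrics import compensate, count_modes, peak_width, ratio_coordinates
from .sample import FlowSample
from .separation import GateBox, classify_gates, classify_nearest_centroid, separation_report
from .simulate import simulate_flow, simulate_images


class ConfigError(ValueError):
    """Raised before any computation when a config fails schema validation."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return dict(cfg)


def _require(cfg: Mapping, key: str, context: str) -> Any:
    if key not in cfg:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return cfg[key]


def build_profiles(cfg: Mapping) -> list[tuple[CellTypeProfile, float]]:
    entries = _require(cfg, "profiles", "config")
    if not isinstance(entries, Sequence) or not entries:
        raise ConfigError("config: 'profiles' must be a non-empty list")
    out = []
    for i, entry in enumerate(entries):
        ctx = f"profiles[{i}]"
        name = _require(entry, "name", ctx)
        knockdown = _require(entry, "knockdown", ctx)
        subpops = None
        if entry.get("subpopulations"):
            subpops = [
                Subpopulation(weight=s["weight"], knockdown=s["knockdown"])
                for s in entry["subpopulations"]
            ]
        try:
            profile = CellTypeProfile(name, dict(knockdown), subpops)
        except ValueError as exc:
            raise ConfigError(f"{ctx}: {exc}") from exc
        out.append((profile, float(entry.get("weight", 1.0))))
    return out


def build_sensors(cfg: Mapping) -> SensorSet:
    block = _require(cfg, "sensors", "config")
    channels = _require(block, "channels", "sensors")
    sensors = [
        Sensor(
            channel=_require(ch, "name", f"sensors.channels[{i}]"),
            target=ch.get("target", "CONTROL"),
            brightness=float(ch.get("brightness", 1.0)),
        )
        for i, ch in enumerate(channels)
    ]
    try:
        return SensorSet(sensors, _require(block, "denominator", "sensors"))
    except ValueError as exc:
        raise ConfigError(f"sensors: {exc}") from exc


def build_simulation_config(cfg: Mapping, seed: int | None = None) -> SimulationConfig:
    block = dict(cfg.get("simulation", {}))
    spill = block.pop("spillover", None)
    if spill is not None:
        spill = SpilloverMatrix(np.asarray(spill, dtype=float))
    if seed is None:
        seed = int(cfg.get("seed", 0))
    try:
        return SimulationConfig(spillover=spill, seed=seed, **block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulation: {exc}") from exc


def build_gates(cfg: Mapping) -> list[GateBox]:
    gates = []
    for i, entry in enumerate(cfg.get("gates", []) or []):
        gates.append(
            GateBox(
                label=_require(entry, "label", f"gates[{i}]"),
                bounds=_require(entry, "bounds", f"gates[{i}]"),
            )
        )
    return gates


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


def _save_histogram(path: Path, ratios: np.ndarray, axis_name: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.log10(ratios), bins=80, color="0.3")
    ax.set_xlabel(f"log10 {axis_name}")
    ax.set_ylabel("events")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _save_density2d(path: Path, coords: np.ndarray, labels, axes: list[str]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if labels is None:
        ax.hexbin(coords[:, 0], coords[:, 1], gridsize=60, cmap="Greys")
    else:
        for name in pd_unique(labels):
            m = np.asarray(labels) == name
            ax.scatter(coords[m, 0], coords[m, 1], s=2, alpha=0.3, label=str(name))
        ax.legend(markerscale=4, fontsize=8)
    ax.set_xlabel(f"log10 {axes[0]}")
    ax.set_ylabel(f"log10 {axes[1]}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pd_unique(labels):
    import pandas as pd

    return pd.unique(np.asarray(labels))


def run_flow_pipeline(
    config: Mapping, outdir: str | Path, seed: int | None = None
) -> dict:
    """Simulate (or load), compensate, ratio, and classify a flow sample.

    Writes event and ratio CSVs, per-axis histograms with mode counts, an
    optional 2-D density plot, and a separation report when gates or
    centroids plus ground truth are available.  Returns the manifest dict
    (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sensors = build_sensors(config)
    manifest: dict[str, Any] = {"pipeline": "flow", "outputs": {}}

    if "input_csv" in config:
        sample = FlowSample.from_csv(config["input_csv"])
        sim = build_simulation_config(config, seed)
    else:
        profiles = build_profiles(config)
        sim = build_simulation_config(config, seed)
        sample = simulate_flow(profiles, sensors, sim)
    manifest["seed"] = sim.seed

    events_csv = outdir / "events.csv"
    sample.to_csv(events_csv)
    manifest["outputs"]["simulate"] = [events_csv.name]

    if sim.spillover is not None:
        sample = compensate(sample, sim.spillover)
        comp_csv = outdir / "events_compensated.csv"
        sample.to_csv(comp_csv)
        manifest["outputs"]["compensate"] = [comp_csv.name]

    gate_min = float(
        config.get("gate_min", 10.0 * float(np.mean(sim.background_vector(sensors.k))))
    )
    ratios = ratio_coordinates(sample, sensors.denominator, min_intensity=gate_min)
    ratios_csv = outdir / "ratios.csv"
    ratios.to_csv(ratios_csv)
    analyze_files = [ratios_csv.name]

    modes_payload = {}
    for axis in ratios.axes:
        values = ratios.values(axis)
        hist_png = outdir / f"hist_{axis.replace('/', '_over_')}.png"
        _save_histogram(hist_png, values, axis)
        analyze_files.append(hist_png.name)
        result = count_modes(values)
        modes_payload[axis] = {
            "n_modes": result.n_modes,
            "locations": [float(v) for v in result.locations],
            "peak_width_95": peak_width(values) if len(values) >= 20 else None,
        }
    modes_json = outdir / "modes.json"
    _write_json(modes_json, modes_payload)
    analyze_files.append(modes_json.name)

    coords = ratios.log10()
    if coords.shape[1] == 2:
        density_png = outdir / "density2d.png"
        _save_density2d(density_png, coords, ratios.labels, ratios.axes)
        analyze_files.append(density_png.name)
    manifest["outputs"]["analyze"] = analyze_files

    gates = build_gates(config)
    centroids = config.get("centroids")
    if gates or centroids:
        if gates:
            assigned = classify_gates(coords, gates)
        else:
            assigned = classify_nearest_centroid(
                coords, {k: list(v) for k, v in centroids.items()}
            )
        classify_files = []
        if ratios.labels is not None:
            report = separation_report(ratios.labels, assigned)
            report_json = outdir / "separation_report.json"
            _write_json(report_json, report.to_json_dict())
            classify_files.append(report_json.name)
        labels_csv = outdir / "assigned_labels.csv"
        import pandas as pd

        pd.DataFrame({"assigned": assigned}).to_csv(labels_csv, index=False)
        classify_files.append(labels_csv.name)
        manifest["outputs"]["classify"] = classify_files

    manifest["n_events"] = int(sample.n_events)
    manifest["excluded_by_gate"] = int(ratios.n_excluded)
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def run_design(config: Mapping, outdir: str | Path) -> dict:
    """Rank sensor panels from an efficiency table; write CSV + JSON reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block = _require(config, "design", "config")
    table_path = _require(block, "table", "design")
    table = design_mod.read_efficiency_table(table_path)
    report = design_mod.enumerate_sets(
        table,
        k=int(block.get("k", 3)),
        cell_types=block.get("cell_types"),
        top_n=block.get("top_n"),
    )
    csv_path = outdir / "design_report.csv"
    json_path = outdir / "design_report.json"
    report.to_csv(csv_path)
    report.to_json(json_path)
    manifest = {
        "pipeline": "design",
        "n_candidates": report.n_candidates,
        "outputs": {"design": [csv_path.name, json_path.name]},
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def run_imaging_pipeline(
    config: Mapping, outdir: str | Path, seed: int | None = None
) -> dict:
    """Simulate a scene, segment nuclei, measure ratios, colour and classify."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sensors = build_sensors(config)
    profiles = build_profiles(config)
    sim = build_simulation_config(config, seed)
    block = dict(config.get("imaging", {}))
    shape = tuple(block.get("shape", (256, 256)))
    scene = simulate_images(
        profiles,
        sensors,
        shape=shape,
        n_nuclei=int(block.get("n_nuclei", 30)),
        radius_range=tuple(block.get("radius_range", (6, 10))),
        config=sim,
    )
    manifest: dict[str, Any] = {"pipeline": "imaging", "seed": sim.seed, "outputs": {}}

    scene_tif = outdir / "scene.tif"
    truth_tif = outdir / "truth_mask.tif"
    scene.to_tiff(scene_tif, mask_path=truth_tif)
    manifest["outputs"]["simulate"] = [scene_tif.name, truth_tif.name]

    mask = segment_nuclei(scene, min_size=int(block.get("min_nucleus_size", 20)))
    import tifffile

    mask_tif = outdir / "segmented_mask.tif"
    tifffile.imwrite(str(mask_tif), mask.astype(np.int32))
    manifest["outputs"]["segment"] = [mask_tif.name]

    den = sensors.denominator
    pairs = [(num, den) for num in sensors.numerators]
    measurements, n_excluded = per_nucleus_ratios(scene, mask, pairs)
    axes = [f"{num}/{den}" for num, _ in pairs]

    pseudo_files = []
    pc_block = block.get("pseudo_color", {})
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for num, _ in pairs:
        axis = f"{num}/{den}"
        lo, hi = pc_block.get(axis, (-0.5, 0.5))
        img = pseudo_color(ratio_image(scene, num, den), PseudoColorSpec(lo, hi))
        png = outdir / f"pseudo_{axis.replace('/', '_over_')}.png"
        plt.imsave(png, img, cmap="viridis", vmin=0, vmax=1)
        pseudo_files.append(png.name)
    manifest["outputs"]["pseudo_color"] = pseudo_files

    gates = build_gates(config)
    labels, overlay = (
        classify_nuclei(measurements, gates, axes, mask=mask)
        if gates
        else ({}, None)
    )
    meas_csv = outdir / "nuclei_measurements.csv"
    measurements_to_dataframe(measurements, labels if gates else None).to_csv(
        meas_csv, index=False, float_format="%.10g"
    )
    measure_files = [meas_csv.name]
    if overlay is not None:
        overlay_png = outdir / "classified_overlay.png"
        plt.imsave(overlay_png, overlay)
        measure_files.append(overlay_png.name)
    manifest["outputs"]["measure"] = measure_files
    manifest["n_nuclei_segmented"] = int(mask.max())
    manifest["excluded_pixels"] = int(n_excluded)
    _write_json(outdir / "manifest.json", manifest)
    return manifest
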