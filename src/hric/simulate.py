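"""Generative simulators for flow-cytometry events and imaging scenes.

The model formalises why co-transfected reporter ratios are tight: the
dominant cell-to-cell variation is the amount of mRNA taken up by each cell,
which is *shared* across co-delivered mRNAs and therefore cancels in any
between-channel ratio.  What remains is a small multiplicative residual per
channel, so a two-channel ratio distributes over a narrow log-normal peak
even when absolute intensities span decades.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .profiles import (
    CONTROL,
    CellTypeProfile,
    SensorSet,
    SimulationConfig,
    SpilloverMatrix,
)
from .sample import FlowSample, ImageScene

Weighted = tuple[CellTypeProfile, float]


def apply_spillover(events: np.ndarray, spillover: SpilloverMatrix) -> np.ndarray:
    """Mix true intensities into observed ones: ``observed = true @ S.T``."""
    return np.asarray(events, dtype=float) @ spillover.matrix.T


def _validate_profiles(
    profiles: Sequence[Weighted], sensors: SensorSet
) -> tuple[list[CellTypeProfile], np.ndarray]:
    if not profiles:
        raise ValueError("at least one (profile, weight) pair is required")
    plist, weights = [], []
    for profile, weight in profiles:
        if not weight > 0:
            raise ValueError(
                f"mixing weight for {profile.name!r} must be > 0, got {weight}"
            )
        for target in sensors.targets():
            if target == CONTROL:
                continue
            profile.efficiency(target)  # raises KeyError with context if unknown
            for i in range(profile.n_subpopulations):
                profile.efficiency(target, subpopulation=i)
        plist.append(profile)
        weights.append(float(weight))
    w = np.asarray(weights)
    return plist, w / w.sum()


def simulate_flow(
    profiles: Sequence[Weighted] | Sequence[CellTypeProfile],
    sensors: SensorSet,
    config: SimulationConfig,
) -> FlowSample:
    """Draw a synthetic flow-cytometry sample from a cell-type mixture.

    For each event a cell type (and subpopulation, if the profile declares
    any) is drawn by weight; the true intensity on channel ``r`` is
    ``U_i * a_r * t_{m(r)} * eps_ir + background_r`` and the observed event
    is the true event passed through the spillover matrix.  Ground-truth
    labels are recorded on the returned sample.  Identical config (including
    seed) gives identical output.
    """
    profiles = [
        p if isinstance(p, tuple) else (p, 1.0) for p in profiles
    ]
    plist, weights = _validate_profiles(profiles, sensors)
    k = sensors.k
    n = config.n_events
    rng = np.random.default_rng(config.seed)

    type_idx = rng.choice(len(plist), size=n, p=weights)
    sub_idx = np.full(n, -1, dtype=int)
    for i, profile in enumerate(plist):
        if profile.n_subpopulations:
            mask = type_idx == i
            sub_w = np.array([s.weight for s in profile.subpopulations], dtype=float)
            sub_idx[mask] = rng.choice(len(sub_w), size=mask.sum(), p=sub_w / sub_w.sum())

    uptake = 10.0 ** rng.normal(config.uptake_log10_mean, config.uptake_log10_sd, n)
    if config.untransfected_fraction > 0:
        uptake[rng.random(n) < config.untransfected_fraction] = 0.0

    sd = config.channel_noise_sd()
    eps = 10.0 ** rng.normal(0.0, sd, size=(n, k)) if sd > 0 else np.ones((n, k))

    # translational efficiency per event x channel
    t = np.empty((n, k))
    for i, profile in enumerate(plist):
        mask = type_idx == i
        if not mask.any():
            continue
        if profile.n_subpopulations:
            for s in range(profile.n_subpopulations):
                m = mask & (sub_idx == s)
                for j, sensor in enumerate(sensors.sensors):
                    t[m, j] = profile.efficiency(sensor.target, subpopulation=s)
        else:
            for j, sensor in enumerate(sensors.sensors):
                t[mask, j] = profile.efficiency(sensor.target)

    background = config.background_vector(k)
    true = uptake[:, None] * sensors.brightness[None, :] * t * eps + background[None, :]
    observed = (
        apply_spillover(true, config.spillover)
        if config.spillover is not None
        else true
    )

    labels = np.array([plist[i].name for i in type_idx], dtype=object)
    return FlowSample(
        channels=sensors.channels,
        events=observed,
        labels=labels,
        subpop_labels=sub_idx if (sub_idx >= 0).any() else None,
        transfected=uptake > 0,
        meta={
            "config": config,
            "sensors": sensors,
            "denominator": sensors.denominator,
        },
    )


def simulate_dilution_series(
    sensors: SensorSet,
    n_steps: int,
    config: SimulationConfig,
    diluted_channel: str | None = None,
) -> list[FlowSample]:
    """Two-fold dilution series of a control mRNA, mimicking miRNA repression.

    Sample ``j`` (j = 0..n_steps-1) has ``diluted_channel``'s brightness
    multiplied by ``2**(-j)``; everything else (including the seed) is held
    fixed, so peak centers step down in exact two-fold increments.  All
    sensors must be CONTROL (no miRNA target sites).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if any(s.target != CONTROL for s in sensors.sensors):
        raise ValueError("dilution series requires an all-CONTROL sensor set")
    if diluted_channel is None:
        diluted_channel = sensors.numerators[0]

    blank = CellTypeProfile("control", {})
    samples = []
    for j in range(n_steps):
        diluted = sensors.with_brightness(diluted_channel, 2.0 ** (-j))
        sample = simulate_flow([(blank, 1.0)], diluted, config)
        sample.meta["dilution_step"] = j
        sample.meta["diluted_channel"] = diluted_channel
        samples.append(sample)
    return samples


def simulate_images(
    profiles: Sequence[Weighted] | Sequence[CellTypeProfile],
    sensors: SensorSet,
    shape: tuple[int, int],
    n_nuclei: int,
    radius_range: tuple[int, int] = (6, 10),
    config: SimulationConfig | None = None,
    pixel_noise_log10_sd: float = 0.05,
    min_separation: float = 3.0,
    max_attempts_per_nucleus: int = 2000,
) -> ImageScene:
    """Render a synthetic imaging-cytometry scene with ground truth.

    Nuclear-localised reporters appear as compact bright disks over a
    constant autofluorescence background.  Each nucleus draws a cell type,
    an uptake and per-channel ratio noise exactly as in the flow model, and
    each member pixel additionally gets small multiplicative noise
    (``pixel_noise_log10_sd`` in log10 units).  Disks are placed by
    rejection sampling with a minimum center separation; an over-crowded
    request fails after a bounded number of attempts.
    """
    if sensors.k != 3:
        raise ValueError(f"imaging scenes use 3 channels, got {sensors.k}")
    if config is None:
        config = SimulationConfig()
    profiles = [p if isinstance(p, tuple) else (p, 1.0) for p in profiles]
    plist, weights = _validate_profiles(profiles, sensors)

    h, w = shape
    rng = np.random.default_rng(config.seed)
    r_lo, r_hi = radius_range
    if r_lo < 1 or r_hi < r_lo:
        raise ValueError(f"invalid radius_range {radius_range}")

    centers: list[tuple[float, float]] = []
    radii: list[int] = []
    for _ in range(n_nuclei):
        for attempt in range(max_attempts_per_nucleus):
            r = int(rng.integers(r_lo, r_hi + 1))
            cy = rng.uniform(r + 1, h - r - 1) if h > 2 * r + 2 else None
            cx = rng.uniform(r + 1, w - r - 1) if w > 2 * r + 2 else None
            if cy is None or cx is None:
                raise ValueError(
                    f"scene {shape} too small for nuclei of radius {r}"
                )
            ok = all(
                math.hypot(cy - py, cx - px) >= r + pr + min_separation
                for (py, px), pr in zip(centers, radii)
            )
            if ok:
                centers.append((cy, cx))
                radii.append(r)
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {len(centers) + 1}/{n_nuclei} in a "
                f"{shape} scene after {max_attempts_per_nucleus} attempts"
            )

    background = config.background_vector(3)
    pixels = np.tile(background[:, None, None], (1, h, w))
    truth_mask = np.zeros((h, w), dtype=np.int32)
    truth_labels: list[str] = []

    sd = config.channel_noise_sd()
    yy, xx = np.mgrid[0:h, 0:w]
    for nucleus_id, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        ti = int(rng.choice(len(plist), p=weights))
        profile = plist[ti]
        sub = None
        if profile.n_subpopulations:
            sub_w = np.array([s.weight for s in profile.subpopulations])
            sub = int(rng.choice(len(sub_w), p=sub_w / sub_w.sum()))
        uptake = 10.0 ** rng.normal(config.uptake_log10_mean, config.uptake_log10_sd)
        eps = 10.0 ** rng.normal(0.0, sd, size=3) if sd > 0 else np.ones(3)

        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        truth_mask[disk] = nucleus_id
        truth_labels.append(profile.name)
        n_px = int(disk.sum())
        for j, sensor in enumerate(sensors.sensors):
            base = uptake * sensor.brightness * profile.efficiency(sensor.target, sub) * eps[j]
            if pixel_noise_log10_sd > 0:
                values = base * 10.0 ** rng.normal(0.0, pixel_noise_log10_sd, n_px)
            else:
                values = np.full(n_px, base)
            pixels[j][disk] = values + background[j]

    return ImageScene(
        channel_names=sensors.channels,
        pixels=pixels,
        truth_mask=truth_mask,
        truth_labels=truth_labels,
    )
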