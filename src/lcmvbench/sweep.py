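"""Amplitude x location x variant benchmarking sweeps.

`run_sweep` reproduces the simulation benchmark: single dipoles at several
interior locations and amplitudes, each dataset simulated, optionally
SSS-like rank reduced, band-pass filtered, variance-rejected, reduced to
noise/data covariances, scanned by every requested beamformer variant, and
scored by localization error, point-spread volume and input SNR.
`run_phantom_suite` does the same over the 8 static-phantom dipoles at
{20, 200, 1000} nAm.  Datasets are mutually independent and every random
draw is seeded, so reruns are bit-identical and any execution order gives
the same rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .beamformer import LCMVBeamformer, get_config
from .forward import compute_leadfield
from .geometry import SensorArray, SphereModel, build_grid, build_helmet_array
from .metrics import input_snr, localization_error, point_spread_volume
from .preprocessing import bandpass_zero_phase, compute_covariance, reject_trials_by_variance
from .synthetic import (
    NAM,
    DipoleSource,
    NoiseModel,
    interior_signal_basis,
    phantom_dataset,
    quiet_noise,
    simulate_trials,
    sss_like_rank_reduction,
)

logger = logging.getLogger("lcmvbench.sweep")

PAPER_AMPLITUDES = (10.0, 30.0, 80.0, 200.0, 300.0, 450.0, 600.0, 800.0)
PHANTOM_AMPLITUDES = (20.0, 200.0, 1000.0)
DEFAULT_SNR_BINS = (-np.inf, 3.0, 15.0, np.inf)
ALL_VARIANTS = ("mne_like", "fieldtrip_like", "spm_like", "brainstorm_like")

RECORD_COLUMNS = [
    "dataset_id", "variant_id", "location_index", "amplitude_nam", "seed",
    "snr_db", "t_max", "le_mm", "psv_mm3",
    "peak_x", "peak_y", "peak_z", "status",
]


@dataclass
class SweepConfig:
    """Study conditions of the simulation sweep.

    Amplitudes are peak dipole moments in nAm; ``sensor_jitter_mm`` perturbs
    the *scanning* forward model's sensor sites (simulation keeps the true
    geometry), emulating coregistration/head-model error.  ``n_sites=34``
    gives a 102-channel triple-sensor array (desk scale); 102 sites give the
    full 306-channel system.
    """

    amplitudes: Sequence[float] = PAPER_AMPLITUDES
    n_locations: int = 25
    variants: Sequence[str] = ALL_VARIANTS
    seeds: Sequence[int] = (0,)
    band: tuple = (2.0, 40.0)
    n_trials: int = 110
    rank_reduction: bool = False
    rank_r: int = 80
    snr_bins: Sequence[float] = DEFAULT_SNR_BINS
    sensor_jitter_mm: float = 0.0
    n_sites: int = 34
    helmet_radius: float = 0.12
    conductor_radius: float = 0.09
    grid_spacing: float = 0.005
    grid_margin: float = 0.0075
    location_seed: int = 909
    jitter_seed: int = 707
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self):
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        edges = np.asarray(self.snr_bins, float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("snr_bins must be strictly increasing")


def default_source_locations(
    n: int,
    sphere: SphereModel,
    seed: int,
    min_radius: float = 0.030,
    margin: float = 0.010,
) -> np.ndarray:
    """Seeded quasi-random single-dipole locations in the upper half-ball.

    Uniform in volume between ``min_radius`` and the conductor radius minus
    ``margin`` (sources stay clear of the surface and of the silent origin),
    z >= 5 mm so every source is inside the upper-half scanning grid.
    """
    rng = np.random.default_rng(seed)
    rmax = sphere.conductor_radius - margin
    out = np.empty((n, 3))
    got = 0
    while got < n:
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        if v[2] < 0:
            v[2] = -v[2]
        r = np.cbrt(rng.uniform(min_radius**3, rmax**3))
        p = r * v
        if p[2] < 0.005:
            continue
        out[got] = sphere.origin + p
        got += 1
    return out


def random_tangential_orientation(location, sphere, rng) -> np.ndarray:
    """Random unit vector tangential to the sphere at ``location``."""
    radial = np.asarray(location, float) - sphere.origin
    radial /= np.linalg.norm(radial)
    v = rng.standard_normal(3)
    v -= (v @ radial) * radial
    return v / np.linalg.norm(v)


def jitter_array(array: SensorArray, sd_m: float, seed: int) -> SensorArray:
    """Displace every sensor site by an isotropic Gaussian offset.

    Channels sharing a site position move together, so the triple-sensor
    structure is preserved; orientations are untouched.
    """
    rng = np.random.default_rng(seed)
    pos = array.channel_position.copy()
    _, site_of = np.unique(np.round(pos, 12), axis=0, return_inverse=True)
    offsets = rng.normal(scale=sd_m, size=(site_of.max() + 1, 3))
    pos = pos + offsets[site_of]
    return SensorArray(
        pos, array.channel_orientation, array.channel_type,
        array.gradiometer_baseline,
    )


def _evaluate_dataset(epochs, true_location, array, sphere, leadfield,
                      variants, band, rank_reduction, rank_r,
                      dataset_id, location_index, amplitude_nam, seed,
                      crop_window=None, sss_basis=None):
    """Preprocess one dataset and score every variant; returns record dicts.

    Epochs are simulated with temporal padding, filtered, then cropped to
    the analysis window: the same order (filter continuous data, then
    epoch) that keeps zero-phase filter transients out of the covariance
    windows in real pipelines."""
    rows = []
    try:
        if rank_reduction:
            epochs = sss_like_rank_reduction(epochs, array, sphere, rank_r,
                                             basis=sss_basis)
        epochs = bandpass_zero_phase(epochs, *band)
        if crop_window is not None:
            epochs = epochs.crop(crop_window)
        epochs, _ = reject_trials_by_variance(epochs)
        data_cov = compute_covariance(epochs, epochs.data_window, "data")
        noise_cov = compute_covariance(epochs, epochs.noise_window, "noise")
        snr_db, t_max = input_snr(epochs, noise_cov)
    except Exception as err:  # dataset-level failure: record and continue
        logger.warning("dataset %s failed: %s", dataset_id, err)
        for v in variants:
            rows.append(dict(
                dataset_id=dataset_id, variant_id=v,
                location_index=location_index, amplitude_nam=amplitude_nam,
                seed=seed, snr_db=np.nan, t_max=np.nan, le_mm=np.nan,
                psv_mm3=np.nan, peak_x=np.nan, peak_y=np.nan, peak_z=np.nan,
                status=f"error: {err}",
            ))
        return rows
    for v in variants:
        try:
            res = LCMVBeamformer(data_cov, noise_cov, leadfield, array,
                                 get_config(v)).fit()
            le = localization_error(res.peak_location, true_location)
            psv = point_spread_volume(res.map)
            peak = res.peak_location
            rows.append(dict(
                dataset_id=dataset_id, variant_id=v,
                location_index=location_index, amplitude_nam=amplitude_nam,
                seed=seed, snr_db=snr_db, t_max=t_max, le_mm=le, psv_mm3=psv,
                peak_x=peak[0], peak_y=peak[1], peak_z=peak[2], status="ok",
            ))
        except Exception as err:
            logger.warning("scan %s/%s failed: %s", dataset_id, v, err)
            rows.append(dict(
                dataset_id=dataset_id, variant_id=v,
                location_index=location_index, amplitude_nam=amplitude_nam,
                seed=seed, snr_db=snr_db, t_max=t_max, le_mm=np.nan,
                psv_mm3=np.nan, peak_x=np.nan, peak_y=np.nan, peak_z=np.nan,
                status=f"error: {err}",
            ))
    return rows


def run_sweep(config: SweepConfig, out_csv: Optional[str] = None) -> pd.DataFrame:
    """Run the full simulation sweep; returns the metrics rows.

    If ``out_csv`` is given, rows are appended incrementally and datasets
    already present in the file are skipped (resumable).
    """
    sphere = SphereModel(conductor_radius=config.conductor_radius)
    array = build_helmet_array(config.n_sites, config.helmet_radius)
    grid = build_grid(sphere, config.grid_spacing, config.grid_margin,
                      region="upper_half")
    scan_array = array
    if config.sensor_jitter_mm > 0:
        scan_array = jitter_array(array, config.sensor_jitter_mm * 1e-3,
                                  config.jitter_seed)
    leadfield = compute_leadfield(grid, scan_array, sphere)
    sss_basis = (interior_signal_basis(array, sphere, config.rank_r)
                 if config.rank_reduction else None)
    locations = default_source_locations(config.n_locations, sphere,
                                         config.location_seed)
    ori_rng = np.random.default_rng(config.location_seed + 1)
    orientations = np.array([
        random_tangential_orientation(loc, sphere, ori_rng) for loc in locations
    ])

    done = set()
    if out_csv and Path(out_csv).exists():
        prev = pd.read_csv(out_csv)
        done = set(zip(prev["dataset_id"], prev["variant_id"]))
    all_rows = []
    for li, loc in enumerate(locations):
        for amp in config.amplitudes:
            for seed in config.seeds:
                dataset_id = f"loc{li:02d}_amp{amp:g}_seed{seed}"
                if all((dataset_id, v) in done for v in config.variants):
                    continue
                source = DipoleSource(loc, orientations[li], amp * NAM)
                epochs = simulate_trials(
                    source, array, sphere, config.noise,
                    n_trials=config.n_trials, seed=seed,
                    epoch_window=(-0.35, 0.35),
                )
                rows = _evaluate_dataset(
                    epochs, loc, array, sphere, leadfield, config.variants,
                    config.band, config.rank_reduction, config.rank_r,
                    dataset_id, li, amp, seed, crop_window=(-0.2, 0.2),
                    sss_basis=sss_basis,
                )
                all_rows.extend(rows)
                if out_csv:
                    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
                    header = not Path(out_csv).exists()
                    df.to_csv(out_csv, mode="a", header=header, index=False)
                logger.info("finished %s", dataset_id)
    records = pd.DataFrame(all_rows, columns=RECORD_COLUMNS)
    if out_csv and Path(out_csv).exists():
        records = pd.read_csv(out_csv)
    return records


@dataclass
class PhantomConfig:
    """Study conditions of the static-phantom suite (306-channel array)."""

    amplitudes: Sequence[float] = PHANTOM_AMPLITUDES
    dipoles: Sequence[int] = (5, 6, 7, 8, 9, 10, 11, 12)
    variants: Sequence[str] = ("mne_like",)
    seeds: Sequence[int] = (0,)
    band: tuple = (2.0, 40.0)
    n_trials: int = 100
    rank_reduction: bool = True
    rank_r: int = 80
    snr_bins: Sequence[float] = DEFAULT_SNR_BINS
    n_sites: int = 102
    helmet_radius: float = 0.12
    conductor_radius: float = 0.075
    grid_spacing: float = 0.005
    grid_margin: float = 0.005
    noise: NoiseModel = field(default_factory=quiet_noise)


def run_phantom_suite(config: PhantomConfig,
                      out_csv: Optional[str] = None) -> pd.DataFrame:
    """Run the 8-dipole x amplitude phantom benchmark; returns metrics rows."""
    sphere = SphereModel(conductor_radius=config.conductor_radius)
    array = build_helmet_array(config.n_sites, config.helmet_radius)
    grid = build_grid(sphere, config.grid_spacing, config.grid_margin,
                      region="upper_half")
    leadfield = compute_leadfield(grid, array, sphere)
    sss_basis = (interior_signal_basis(array, sphere, config.rank_r)
                 if config.rank_reduction else None)
    all_rows = []
    for dip in config.dipoles:
        for amp in config.amplitudes:
            for seed in config.seeds:
                dataset_id = f"dip{dip}_amp{amp:g}_seed{seed}"
                epochs, source = phantom_dataset(
                    dip, amp, noise=config.noise, seed=seed,
                    n_trials=config.n_trials, array=array, sphere=sphere,
                )
                rows = _evaluate_dataset(
                    epochs, source.location, array, sphere, leadfield,
                    config.variants, config.band, config.rank_reduction,
                    config.rank_r, dataset_id, dip, amp, seed,
                    crop_window=(-0.5, 0.5), sss_basis=sss_basis,
                )
                all_rows.extend(rows)
                if out_csv:
                    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
                    header = not Path(out_csv).exists()
                    df.to_csv(out_csv, mode="a", header=header, index=False)
                logger.info("finished %s", dataset_id)
    return pd.DataFrame(all_rows, columns=RECORD_COLUMNS)


def bin_label(edges: Sequence[float]) -> list:
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo):
            labels.append(f"<{hi:g}")
        elif np.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"{lo:g}-{hi:g}")
    return labels


def summarize(records: pd.DataFrame,
              snr_bins: Sequence[float] = DEFAULT_SNR_BINS) -> pd.DataFrame:
    """Mean LE (mm) and mean PSV (cm^3) per (variant, SNR bin).

    Bins are left-closed, right-open.  Failed rows are excluded and counted
    in the ``n_failed`` column.
    """
    edges = list(snr_bins)
    ok = records[records["status"] == "ok"].copy()
    ok["snr_bin"] = pd.cut(ok["snr_db"], bins=edges, right=False,
                           labels=bin_label(edges))
    grouped = ok.groupby(["variant_id", "snr_bin"], observed=False)
    summary = grouped.agg(
        mean_le_mm=("le_mm", "mean"),
        mean_psv_cm3=("psv_mm3", lambda x: x.mean() / 1e3),
        n=("le_mm", "size"),
    ).reset_index()
    failed = (
        records[records["status"] != "ok"]
        .groupby("variant_id")
        .size()
        .rename("n_failed")
    )
    summary = summary.merge(failed, on="variant_id", how="left")
    summary["n_failed"] = summary["n_failed"].fillna(0).astype(int)
    return summary
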