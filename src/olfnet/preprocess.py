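"""Timeseries cleaning and quality control.

The cleaning chain runs in a fixed, logged order: per-run mean centering
and whitening (then concatenation), temporal bandpass (0.01-0.08 Hz,
applied per run), regression of 24 motion-derived nuisance variables,
and scrubbing of high-motion scans by framewise displacement.
Voxel-level COV masking and participant-level QC implement the study's
inclusion rules.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .containers import FdSeries, RoiTimeseries, VoxelRoi

log = logging.getLogger(__name__)

FD_THRESHOLD_MM = 0.5
BANDPASS_LOW_HZ = 0.01
BANDPASS_HIGH_HZ = 0.08


def framewise_displacement(motion: np.ndarray, run_ids: np.ndarray | None = None,
                           threshold: float = FD_THRESHOLD_MM) -> FdSeries:
    """Framewise displacement: sum of absolute successive differences.

    ``motion`` is an (n_scans, 6) array of three translations (mm) and
    three rotations already expressed in mm-equivalent units (50-mm
    sphere convention). FD of the first scan of each run is 0 by
    convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_scans, 6): three translations "
                         "and three mm-equivalent rotations")
    if motion.shape[0] < 1:
        raise ValueError("at least one scan required")
    fd = np.zeros(motion.shape[0])
    fd[1:] = np.abs(np.diff(motion, axis=0)).sum(axis=1)
    if run_ids is not None:
        run_ids = np.asarray(run_ids)
        starts = np.flatnonzero(np.r_[True, run_ids[1:] != run_ids[:-1]])
        fd[starts] = 0.0
    return FdSeries(values=fd, threshold=threshold)


def scrub_spikes(ts: RoiTimeseries, fd: FdSeries) -> RoiTimeseries:
    """Mask scans whose FD exceeds the threshold (spikes are dropped,
    not interpolated)."""
    if fd.values.shape[0] != ts.n_scans:
        raise ValueError("FD series length does not match scan count")
    mask = ts.scan_mask & ~fd.spikes
    if not mask.any():
        warnings.warn("all scans scrubbed: no retained scans remain")
    n_spikes = int((ts.scan_mask & fd.spikes).sum())
    log.info("scrubbing: %d spikes above %.2f mm removed", n_spikes, fd.threshold)
    return ts.copy_with(scan_mask=mask)


def bandpass(ts: RoiTimeseries, low: float = BANDPASS_LOW_HZ,
             high: float = BANDPASS_HIGH_HZ, order: int = 4) -> RoiTimeseries:
    """Zero-phase Butterworth bandpass, applied per run.

    The filter is a forward-backward (zero-phase) Butterworth of the
    given order per edge; run means (0 Hz) are suppressed since they lie
    below the passband. ``high`` must be below the Nyquist frequency.
    """
    nyquist = 0.5 / ts.tr
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyquist:.4f} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / ts.tr,
                        output="sos")
    padlen = 3 * (2 * order + 1)
    out = ts.values.copy()
    for run, idx in ts.iter_runs():
        if idx.size <= padlen:
            raise ValueError(f"run {run} has {idx.size} scans, fewer than the "
                             f"filter warm-up length {padlen + 1}")
        chunk = ts.values[idx] - ts.values[idx].mean(axis=0)
        out[idx] = signal.sosfiltfilt(sos, chunk, axis=0)
    log.info("bandpass %.3f-%.3f Hz (order %d, zero-phase) applied per run",
             low, high, order)
    return ts.copy_with(values=out)


def motion24_design(motion: np.ndarray, run_ids: np.ndarray | None = None) -> np.ndarray:
    """The 24 nuisance regressors: 6 current parameters, 6 previous-scan
    parameters, and the squares of those 12. The previous-scan regressor
    of the first scan of a run repeats that scan (zero difference)."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_scans, 6)")
    prev = np.roll(motion, 1, axis=0)
    prev[0] = motion[0]
    if run_ids is not None:
        run_ids = np.asarray(run_ids)
        starts = np.flatnonzero(np.r_[True, run_ids[1:] != run_ids[:-1]])
        prev[starts] = motion[starts]
    x = np.hstack([motion, prev, motion ** 2, prev ** 2])
    return x


def regress_motion24(ts: RoiTimeseries, motion: np.ndarray) -> RoiTimeseries:
    """Residualize the timeseries on the 24 motion regressors (plus an
    intercept). Residuals are orthogonal to the span of the regressors;
    rank deficiency is handled by the least-squares pseudoinverse with a
    logged warning."""
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != ts.n_scans:
        raise ValueError("motion trace length does not match scan count")
    x = motion24_design(motion, ts.run_ids)
    design = np.column_stack([np.ones(ts.n_scans), x])
    coef, _, rank, _ = np.linalg.lstsq(design, ts.values, rcond=None)
    if rank < design.shape[1]:
        log.warning("motion design rank-deficient (rank %d of %d); "
                    "pseudoinverse solution used", rank, design.shape[1])
    resid = ts.values - design @ coef
    return ts.copy_with(values=resid)


def center_whiten_concatenate(runs) -> RoiTimeseries:
    """Z-score each ROI within each run (mean 0, SD 1), then concatenate.

    ``runs`` may be a list of single-run :class:`RoiTimeseries` or one
    multi-run instance. A zero-variance series raises an error naming
    the ROI and run.
    """
    if isinstance(runs, RoiTimeseries):
        ts = runs
    else:
        runs = list(runs)
        if not runs:
            raise ValueError("no runs supplied")
        first = runs[0]
        for other in runs[1:]:
            if other.roi_names != first.roi_names:
                raise ValueError("runs must share the same ROI set")
            if other.tr != first.tr:
                raise ValueError("runs must share the repetition time")
        values = np.vstack([r.values for r in runs])
        run_ids = np.concatenate([np.full(r.n_scans, i) for i, r in enumerate(runs)])
        mask = np.concatenate([r.scan_mask for r in runs])
        ts = RoiTimeseries(values, list(first.roi_names), run_ids, first.tr, mask)
    out = ts.values.copy()
    for run, idx in ts.iter_runs():
        chunk = ts.values[idx]
        sd = chunk.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = [ts.roi_names[i] for i in dead]
            raise ValueError(f"zero-variance series in run {run} for ROI(s) {names}")
        out[idx] = (chunk - chunk.mean(axis=0)) / sd
    return ts.copy_with(values=out)


def clean_timeseries(ts: RoiTimeseries, motion: np.ndarray,
                     fd_threshold: float = FD_THRESHOLD_MM,
                     low: float = BANDPASS_LOW_HZ, high: float = BANDPASS_HIGH_HZ,
                     order: int = 4,
                     bandpass_before_regression: bool = True) -> RoiTimeseries:
    """Run the full cleaning chain in the fixed order:

    center/whiten (per run) -> bandpass (per run) -> 24-parameter motion
    regression -> FD scrubbing. The relative order of filtering and
    nuisance regression is switchable by config.
    """
    out = center_whiten_concatenate(ts)
    if bandpass_before_regression:
        out = bandpass(out, low=low, high=high, order=order)
        out = regress_motion24(out, motion)
    else:
        out = regress_motion24(out, motion)
        out = bandpass(out, low=low, high=high, order=order)
    fd = framewise_displacement(motion, out.run_ids, threshold=fd_threshold)
    return scrub_spikes(out, fd)


def cov_voxel_mask(roi: VoxelRoi, sigma_mm: float = 5.0,
                   cutoff_sd: float = 0.5) -> np.ndarray:
    """Keep-mask for voxels by locally referenced coefficient of variation.

    For each voxel, a Gaussian-weighted (sigma ``sigma_mm``) neighborhood
    mean and SD of COV are computed over the ROI's voxels; the voxel is
    excluded iff its COV exceeds the neighborhood mean plus
    ``cutoff_sd`` neighborhood SDs. Ties (e.g. a perfectly uniform ROI,
    where the neighborhood SD is 0) are kept.
    """
    if roi.cov.size < 2:
        raise ValueError("at least two voxels required")
    d2 = ((roi.coords[:, None, :] - roi.coords[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * sigma_mm ** 2))
    wsum = w.sum(axis=1)
    mean = (w * roi.cov[None, :]).sum(axis=1) / wsum
    var = (w * (roi.cov[None, :] - mean[:, None]) ** 2).sum(axis=1) / wsum
    excess = roi.cov - (mean + cutoff_sd * np.sqrt(np.maximum(var, 0.0)))
    # ties (uniform neighborhoods) are kept; tolerance absorbs roundoff
    keep = excess <= 1e-12 * np.maximum(1.0, roi.cov)
    if not keep.any():
        warnings.warn("COV masking excluded every voxel in the ROI")
    return keep


def qc_participants(reports: pd.DataFrame, min_voxels: int = 50,
                    max_missing_fraction: float = 0.6, snr_sd: float = 3.0,
                    exempt_rois: tuple[str, ...] = ("OTB",)) -> tuple[list, pd.DataFrame]:
    """Apply the participant inclusion rules to per-ROI QC statistics.

    ``reports`` has one row per (participant, roi) with columns
    ``participant``, ``roi``, ``voxel_count``, ``frac_present`` (fraction
    of the anatomic ROI present in the functional scans) and ``snr``
    (temporal mean / temporal SD). A participant is excluded if any
    non-exempt ROI has fewer than ``min_voxels`` voxels, more than
    ``max_missing_fraction`` of its anatomic voxels missing, or an SNR
    more than ``snr_sd`` SDs below the sample mean for that ROI. The
    olfactory tubercle (``exempt_rois``) is exempt from all three rules.

    Returns the included participant list and a DataFrame of exclusions
    with reason codes (every excluded participant carries at least one).
    """
    required = {"participant", "roi", "voxel_count", "frac_present", "snr"}
    missing = required - set(reports.columns)
    if missing:
        raise ValueError(f"QC report missing columns: {sorted(missing)}")
    if reports["participant"].nunique() < 2:
        raise ValueError("SNR criterion needs a sample of >= 2 participants")
    df = reports[~reports["roi"].isin(exempt_rois)].copy()
    grp = df.groupby("roi")["snr"]
    df["snr_floor"] = grp.transform("mean") - snr_sd * grp.transform("std")
    reasons = []
    for _, row in df.iterrows():
        if row["voxel_count"] < min_voxels:
            reasons.append((row["participant"], row["roi"], "min_voxels"))
        if 1.0 - row["frac_present"] > max_missing_fraction:
            reasons.append((row["participant"], row["roi"], "missing_fraction"))
        if row["snr"] < row["snr_floor"]:
            reasons.append((row["participant"], row["roi"], "low_snr"))
    exclusions = pd.DataFrame(reasons, columns=["participant", "roi", "reason"])
    excluded = set(exclusions["participant"])
    included = [p for p in reports["participant"].unique() if p not in excluded]
    return included, exclusions
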