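"""Convergence diagnostics and sampling-error estimation.

Occupancy statistics from MD are time-correlated, so the naive standard
error of the per-frame series understates the sampling error.  Following
the block-averaging approach of Grossfield & Zuckerman, the series is cut
into non-overlapping blocks of increasing size b and the block standard
error BSE(b) = SD(block means)/sqrt(n_blocks) is tracked: for correlated
data it grows with b and saturates at the true standard error of the mean.
The saturation curve is fitted with a0·(1 − a1·exp(−a2·b)); the fitted a0
is the asymptotic sampling error, and the uncertainty of a difference
occupancy is combined conservatively as δ(ΔR_i) = a0_x + a0_y.

Also provided: the atom-averaged occupancy time series R_ave(k) (mean of
per-frame R_i over atoms whose whole-run occupancy exceeds a small cutoff,
default 0.05) with a running mean, and block-mean tables for eyeballing
stationarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .model import SystemModel, Trajectory
from .occupancy import OccupancyParams, _occupancy_per_frame

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancyTimeSeries",
    "BSECurve",
    "BSEFit",
    "occupancy_timeseries",
    "block_means",
    "block_standard_error",
    "fit_bse",
    "delta_uncertainty",
    "default_block_sizes",
    "per_atom_uncertainties",
]


@dataclass
class OccupancyTimeSeries:
    """Per-frame occupancy series for tracked atoms plus their average."""

    atoms: np.ndarray                 # tracked atom indices
    per_atom: np.ndarray              # (n_frames, n_tracked) instantaneous R_i(k)
    R_ave: np.ndarray                 # (n_frames,) mean over tracked atoms
    running_mean: np.ndarray          # same length, NaN-padded head
    window: int
    cutoff: float


@dataclass
class BSECurve:
    block_sizes: np.ndarray
    bse: np.ndarray
    series_length: int


@dataclass
class BSEFit:
    a0: float
    a1: float
    a2: float
    residual_norm: float
    converged: bool


def occupancy_timeseries(system: SystemModel, traj: Trajectory,
                         params: OccupancyParams = OccupancyParams(),
                         cutoff: float = 0.05,
                         window: int = 50) -> OccupancyTimeSeries:
    """Instantaneous per-frame occupancies and their atom average R_ave(k).

    The tracked atom set is fixed over the series: atoms whose
    whole-trajectory R_i exceeds ``cutoff`` (default 0.05, which captures
    essentially every atom with non-zero occupancy).  The frame-average of
    R_i(k) equals the whole-trajectory R_i exactly.
    """
    per_frame = _occupancy_per_frame(system, traj, params)  # (K, P)
    whole = per_frame.mean(axis=0)
    keep = whole > cutoff
    if not np.any(keep):
        raise ValueError(
            f"no atom has whole-trajectory occupancy above {cutoff}; "
            "try a lower cutoff"
        )
    tracked = system.protein_heavy[keep]
    series = per_frame[:, keep]
    r_ave = series.mean(axis=1)
    if window < 1:
        raise ValueError("running-mean window must be >= 1")
    run = np.full(r_ave.size, np.nan)
    if r_ave.size >= window:
        kernel = np.ones(window) / window
        run[window - 1:] = np.convolve(r_ave, kernel, mode="valid")
    return OccupancyTimeSeries(atoms=tracked, per_atom=series, R_ave=r_ave,
                               running_mean=run, window=window, cutoff=cutoff)


def block_means(series: np.ndarray, block_frames: int) -> list[tuple[float, float]]:
    """Means ± SD of consecutive non-overlapping blocks.

    The trailing partial block is dropped (logged).  Returns a list of
    (mean, sd) per block; SD is the sample SD within the block (0 for
    single-frame blocks).
    """
    series = np.asarray(series, dtype=float)
    if block_frames < 1:
        raise ValueError("block_frames must be >= 1")
    if block_frames > series.size:
        raise ValueError("block_frames exceeds series length")
    n_blocks = series.size // block_frames
    leftover = series.size - n_blocks * block_frames
    if leftover:
        logger.info("block_means: dropping trailing partial block of %d frames",
                    leftover)
    blocks = series[: n_blocks * block_frames].reshape(n_blocks, block_frames)
    means = blocks.mean(axis=1)
    sds = blocks.std(axis=1, ddof=1) if block_frames > 1 else np.zeros(n_blocks)
    return [(float(m), float(s)) for m, s in zip(means, sds)]


def block_standard_error(series: np.ndarray,
                         block_sizes: np.ndarray | list[int] | None = None) -> BSECurve:
    """BSE(b) = SD(non-overlapping block means) / sqrt(n_blocks) per block size.

    BSE(b=1) equals the plain standard error of the mean exactly.  Block
    sizes yielding fewer than 2 blocks are dropped with a warning.
    """
    series = np.asarray(series, dtype=float)
    if block_sizes is None:
        block_sizes = default_block_sizes(series.size)
    sizes, bses = [], []
    for b in sorted(set(int(b) for b in block_sizes)):
        if b < 1:
            raise ValueError("block sizes must be >= 1")
        n_blocks = series.size // b
        if n_blocks < 2:
            logger.warning("block_standard_error: dropping block size %d "
                           "(only %d block)", b, n_blocks)
            continue
        means = series[: n_blocks * b].reshape(n_blocks, b).mean(axis=1)
        bses.append(float(means.std(ddof=1) / np.sqrt(n_blocks)))
        sizes.append(b)
    if not sizes:
        raise ValueError("no usable block sizes for this series length")
    return BSECurve(block_sizes=np.array(sizes), bse=np.array(bses),
                    series_length=series.size)


def default_block_sizes(n: int) -> list[int]:
    """Powers of 2 from 1 up to n//4 (at least [1])."""
    out = []
    b = 1
    while b <= max(1, n // 4):
        out.append(b)
        b *= 2
    return out or [1]


def _model(b, a0, a1, a2):
    # clamp the exponent so optimizer excursions to a2 < 0 cannot overflow
    return a0 * (1.0 - a1 * np.exp(-np.clip(a2 * b, -700.0, 700.0)))


def fit_bse(curve: BSECurve, initial: tuple[float, float, float] | None = None) -> BSEFit:
    """Least-squares fit of BSE(b) to a0·(1 − a1·exp(−a2·b)).

    a0 estimates the asymptotic sampling error.  A degenerate all-zero
    curve returns a0 = 0, converged.  The fit is flagged unconverged when
    the optimizer fails or when a0 exceeds twice the largest observed BSE
    (flat-curve pathology).
    """
    b = curve.block_sizes.astype(float)
    y = curve.bse
    if b.size < 4:
        raise ValueError("need at least 4 points to fit the BSE curve")
    ymax = float(y.max())
    if ymax == 0.0:
        return BSEFit(a0=0.0, a1=0.0, a2=1.0, residual_norm=0.0, converged=True)
    if initial is None:
        a0_0 = ymax
        a1_0 = float(np.clip(1.0 - y[0] / a0_0, 1e-6, 1.0))
        a2_0 = 1.0 / float(np.median(b))
        initial = (a0_0, a1_0, a2_0)
    try:
        popt, _ = curve_fit(_model, b, y, p0=initial, maxfev=20000)
    except RuntimeError:
        return BSEFit(a0=ymax, a1=0.0, a2=1.0, residual_norm=float("inf"),
                      converged=False)
    a0, a1, a2 = (float(v) for v in popt)
    resid = float(np.linalg.norm(_model(b, *popt) - y))
    converged = np.isfinite(resid) and a0 >= 0 and a2 > 0 and a0 <= 2.0 * ymax
    return BSEFit(a0=a0, a1=a1, a2=a2, residual_norm=resid, converged=converged)


def delta_uncertainty(fit_x: BSEFit, fit_y: BSEFit) -> float:
    """Conservative uncertainty of a difference: δ(ΔR) = a0_x + a0_y.

    Either fit unconverged → NaN (caller should flag the atom as missing).
    """
    if not (fit_x.converged and fit_y.converged):
        return float("nan")
    return fit_x.a0 + fit_y.a0


def per_atom_uncertainties(series: OccupancyTimeSeries,
                           block_sizes=None) -> dict[int, float]:
    """Asymptotic sampling error a0 per tracked atom from its own BSE fit.

    Atoms whose fit does not converge fall back to the maximum observed
    BSE of their curve (conservative).
    """
    out: dict[int, float] = {}
    for col, atom in enumerate(series.atoms):
        curve = block_standard_error(series.per_atom[:, col], block_sizes)
        if curve.block_sizes.size < 4:
            out[int(atom)] = float(curve.bse.max())
            continue
        fit = fit_bse(curve)
        out[int(atom)] = fit.a0 if fit.converged else float(curve.bse.max())
    return out
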