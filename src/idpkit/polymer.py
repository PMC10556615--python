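"""Polymer-physics diagnostics of compaction and disorder.

For a disordered chain the mean-square radius of gyration of internal
segments grows as a power law in segment length, <Rg^2(l)> ~ l^(2*nu), with
the Flory exponent nu = 0.5 for an ideal (random-coil) chain and
nu ~= 0.588 for a self-avoiding chain in good solvent.  A second
model-free diagnostic is the amplitude ("shape") ratio

    sqrt(<Rg^2>) / sqrt(<Ree^2>),

which is 1/sqrt(6) ~= 0.408 for Gaussian chains, ~= 0.406 for self-avoiding
walks, and 1/sqrt(12) for a rigid rod.  Ensembles that deviate from both
reference values flag structured subpopulations within nominal disorder.

Error bars on trajectory averages use a blocked delete-one jackknife whose
block length is set by the integrated autocorrelation time of the series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble import Ensemble

__all__ = [
    "ScalingFit",
    "ShapeRatio",
    "radius_of_gyration",
    "end_to_end",
    "segment_mean_square_rg",
    "fit_flory",
    "segment_scaling",
    "shape_ratio",
    "integrated_autocorr_time",
    "blocked_jackknife",
]


@dataclass
class ScalingFit:
    """Least-squares power-law fit of segment size versus segment length."""

    exponent: float           # Flory exponent nu
    prefactor: float          # A in sqrt(<Rg^2>) = A * l^nu  [Angstrom]
    lengths: np.ndarray       # segment lengths used (residues)
    mean_square_rg: np.ndarray  # <Rg^2(l)> per length [A^2]
    residuals: np.ndarray     # log-space fit residuals
    stderr: float             # standard error of nu

    def __post_init__(self):
        if len(self.lengths) < 3:
            raise ValueError("scaling fit needs >= 3 distinct segment lengths")
        if np.any(np.diff(self.lengths) <= 0):
            raise ValueError("segment lengths must be strictly increasing")


@dataclass
class ShapeRatio:
    """rms gyration radius over rms end-to-end distance, with jackknife error."""

    ratio: float
    rms_rg: float    # sqrt(<Rg^2>)  [A]
    rms_ree: float   # sqrt(<Ree^2>) [A]
    stderr: float    # jackknife standard error (nan if too few frames)

    def __post_init__(self):
        if not self.ratio > 0:
            raise ValueError("shape ratio must be positive")


def radius_of_gyration(coords: np.ndarray) -> np.ndarray | float:
    """Mass-unweighted radius of gyration of a point set (Angstrom).

    ``coords`` is (N, 3) for one frame or (F, N, 3) for many; returns a
    scalar or an (F,) array accordingly.
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    if coords.shape[1] < 2:
        raise ValueError("radius of gyration needs at least 2 points")
    centered = coords - coords.mean(axis=1, keepdims=True)
    rg = np.sqrt((centered ** 2).sum(axis=2).mean(axis=1))
    return float(rg[0]) if single else rg


def end_to_end(coords: np.ndarray) -> np.ndarray | float:
    """Distance between the first and last point of a chain (Angstrom)."""
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    if coords.shape[1] < 2:
        raise ValueError("end-to-end distance needs at least 2 points")
    d = np.linalg.norm(coords[:, -1] - coords[:, 0], axis=1)
    return float(d[0]) if single else d


def segment_mean_square_rg(coords: np.ndarray, length: int) -> float:
    """<Rg^2> over all contiguous windows of ``length`` monomers and all frames.

    Uses prefix sums, so the cost is linear in chain length per frame.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    if not 2 <= length <= n:
        raise ValueError(f"segment length {length} outside chain of {n} monomers")
    # prefix sums of r and |r|^2 along the chain
    csum = np.concatenate(
        [np.zeros((coords.shape[0], 1, 3)), np.cumsum(coords, axis=1)], axis=1
    )
    csq = np.concatenate(
        [np.zeros((coords.shape[0], 1)),
         np.cumsum((coords ** 2).sum(axis=2), axis=1)], axis=1
    )
    l = length
    win_sum = csum[:, l:] - csum[:, :-l]          # (F, W, 3)
    win_sq = csq[:, l:] - csq[:, :-l]             # (F, W)
    rg2 = win_sq / l - (win_sum ** 2).sum(axis=2) / l ** 2
    return float(rg2.mean())


def fit_flory(lengths, mean_square_rg) -> ScalingFit:
    """Fit sqrt(<Rg^2(l)>) = A * l^nu by least squares in log-log space.

    The fit is exact on exact power laws; on noisy data the standard error
    of the slope is the usual OLS estimate.
    """
    lengths = np.asarray(lengths, dtype=float)
    msq = np.asarray(mean_square_rg, dtype=float)
    if np.any(msq <= 0):
        raise ValueError("degenerate (non-positive) mean-square gyration radii")
    x = np.log(lengths)
    y = 0.5 * np.log(msq)
    coef, cov = np.polyfit(x, y, 1, cov=True)
    nu = float(coef[0])
    resid = y - np.polyval(coef, x)
    return ScalingFit(
        exponent=nu,
        prefactor=float(np.exp(coef[1])),
        lengths=lengths,
        mean_square_rg=msq,
        residuals=resid,
        stderr=float(np.sqrt(cov[0, 0])),
    )


def segment_scaling(ensemble: Ensemble, lengths, chain: str | None = None,
                    atom_name: str = "CA") -> ScalingFit:
    """Flory-scaling fit over internal segments of a chain ensemble.

    For each requested segment length every contiguous window of the chain
    contributes, in every frame; the exponent comes from the log-log slope
    of the rms segment gyration radius versus length.
    """
    lengths = sorted(int(l) for l in set(lengths))
    if len(lengths) < 3:
        raise ValueError("need >= 3 distinct segment lengths")
    coords = ensemble.atom_coords(atom_name, chain=chain)
    msq = np.array([segment_mean_square_rg(coords, l) for l in lengths])
    return fit_flory(lengths, msq)


def integrated_autocorr_time(series: np.ndarray) -> float:
    """Integrated autocorrelation time, truncated at the first non-positive lag.

    tau = 1/2 + sum_k rho_k over lags k = 1 .. K-1 where K is the first lag
    with rho_K <= 0.  Raises on constant series (tau undefined).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        raise ValueError("autocorrelation time undefined for a constant series")
    # FFT autocorrelation
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acf = np.fft.irfft(f * np.conj(f), m)[:n] / (n * var)
    nonpos = np.flatnonzero(acf[1:] <= 0)
    k_max = (nonpos[0] + 1) if nonpos.size else n
    return float(0.5 + acf[1:k_max].sum())


def blocked_jackknife(series: np.ndarray, statistic=None,
                      tau_series: np.ndarray | None = None):
    """Blocked delete-one jackknife: (estimate, standard error, tau).

    ``series`` is (n,) or (n, k); the default statistic is the mean of a
    scalar series.  The block length is ceil(2 * tau) with tau the
    integrated autocorrelation time of ``tau_series`` (default: the series
    itself, first column for multi-column input).  Constant series yield a
    zero error with a warning, matching the convention that a series with no
    fluctuation carries no statistical uncertainty.
    """
    series = np.asarray(series, dtype=float)
    flat = series.ndim == 1
    data = series[:, None] if flat else series
    if statistic is None:
        if not flat:
            raise ValueError("a statistic is required for multi-column series")
        statistic = lambda s: float(np.mean(s))
    stat_input = (lambda d: d[:, 0]) if flat else (lambda d: d)

    full = statistic(stat_input(data))
    ref = data[:, 0] if tau_series is None else np.asarray(tau_series, dtype=float)
    try:
        tau = integrated_autocorr_time(ref)
    except ValueError:
        warnings.warn("constant series: autocorrelation time undefined, error set to 0")
        return full, 0.0, float("nan")
    block = max(1, int(np.ceil(2.0 * tau)))
    m = len(data) // block
    if m < 10:
        raise ValueError(
            f"only {m} blocks of length {block}; need >= 10 for a jackknife error"
        )
    trimmed = data[: m * block]
    estimates = np.empty(m)
    for i in range(m):
        keep = np.ones(m * block, dtype=bool)
        keep[i * block:(i + 1) * block] = False
        estimates[i] = statistic(stat_input(trimmed[keep]))
    se = float(np.sqrt((m - 1) / m * ((estimates - estimates.mean()) ** 2).sum()))
    return full, se, tau


def shape_ratio(ensemble: Ensemble, chain: str | None = None,
                atom_name: str = "CA", rms_average: bool = True) -> ShapeRatio:
    """Amplitude ratio sqrt(<Rg^2>)/sqrt(<Ree^2>) over an ensemble.

    The rms convention reproduces the Gaussian-chain reference value
    1/sqrt(6) ~= 0.408; ``rms_average=False`` switches the numerator to the
    arithmetic-mean gyration radius for sensitivity checks.  The error bar
    is a blocked jackknife with the correlation time taken from the Rg^2
    series; it is nan when the series is too short to block.
    """
    coords = ensemble.atom_coords(atom_name, chain=chain)
    rg = radius_of_gyration(coords)
    ree = end_to_end(coords)
    rg = np.atleast_1d(rg)
    ree = np.atleast_1d(ree)
    if np.mean(ree ** 2) == 0:
        raise ValueError("zero mean-square end-to-end distance")

    if rms_average:
        stat = lambda d: float(np.sqrt(np.mean(d[:, 0])) / np.sqrt(np.mean(d[:, 1])))
    else:
        stat = lambda d: float(np.mean(np.sqrt(d[:, 0])) / np.sqrt(np.mean(d[:, 1])))
    data = np.column_stack([rg ** 2, ree ** 2])
    try:
        ratio, se, _ = blocked_jackknife(data, statistic=stat, tau_series=rg ** 2)
    except ValueError:
        ratio, se = stat(data), float("nan")
    return ShapeRatio(
        ratio=ratio,
        rms_rg=float(np.sqrt(np.mean(rg ** 2))),
        rms_ree=float(np.sqrt(np.mean(ree ** 2))),
        stderr=se,
    )
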