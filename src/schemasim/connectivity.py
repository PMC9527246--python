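"""Rest-series preprocessing, inter-ROI coupling deltas, and brain-behavior
correlation.

Pipeline per scan: drop the first 6 volumes, flag artifact volumes (global
signal beyond 3 SD, per-axis translation steps > 1 mm, rotation steps >
0.05 rad), regress out 6 motion parameters + their first derivatives + spike
indicators + the top-5 principal components of the noise-mask voxels
(aCompCor), then band-pass 0.008-0.09 Hz.  Coupling is the Fisher z of the
Pearson correlation between denoised ROI-mean series; deltas are post minus
pre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .similarity import fisher_z

__all__ = [
    "N_TRIM_VOLUMES",
    "BAND_HZ",
    "art_flags",
    "acompcor",
    "bandpass",
    "denoise",
    "roi_coupling",
    "preprocess_scan",
    "coupling_delta",
    "brain_behavior",
    "williams_test",
    "CorrelationResult",
]

N_TRIM_VOLUMES = 6
BAND_HZ = (0.008, 0.09)
GLOBAL_SIGNAL_SD = 3.0
TRANSLATION_MM = 1.0
ROTATION_RAD = 0.05


def art_flags(
    data: np.ndarray,
    motion: np.ndarray,
    global_sd: float = GLOBAL_SIGNAL_SD,
    translation_mm: float = TRANSLATION_MM,
    rotation_rad: float = ROTATION_RAD,
) -> np.ndarray:
    """Artifact flags: union of global-signal and motion-step criteria.

    ``data`` is (T, V) voxel data (global signal = spatial mean per volume);
    ``motion`` is (T, 6) with translations in mm, rotations in radians.
    Motion steps are per-axis absolute volume-to-volume differences.
    """
    data = np.asarray(data, dtype=float)
    motion = np.asarray(motion, dtype=float)
    T = data.shape[0]
    if motion.shape != (T, 6):
        raise ValueError("motion table must be (T, 6) aligned to data")
    gs = data.mean(axis=1)
    gz = (gs - gs.mean()) / (gs.std() or 1.0)
    flags = np.abs(gz) > global_sd
    steps = np.abs(np.diff(motion, axis=0))
    flags[1:] |= (steps[:, :3] > translation_mm).any(axis=1)
    flags[1:] |= (steps[:, 3:] > rotation_rad).any(axis=1)
    return flags


def acompcor(noise_data: np.ndarray, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal-component time courses of a noise-mask voxel block.

    Returns (T, k_eff) components and their explained-variance ratios.  If
    ``k`` exceeds the matrix rank, fewer components are returned with a
    warning.
    """
    if k == 0:
        return np.zeros((noise_data.shape[0], 0)), np.zeros(0)
    X = np.asarray(noise_data, dtype=float)
    if X.shape[1] < k:
        warnings.warn(f"only {X.shape[1]} noise voxels for k={k}")
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    nz = s > s[0] * 1e-10 if s.size else np.zeros(0, dtype=bool)
    k_eff = int(min(k, nz.sum()))
    if k_eff < k:
        warnings.warn(f"aCompCor: rank {nz.sum()} < requested k={k}")
    ev = (s**2) / (s**2).sum()
    return U[:, :k_eff] * s[:k_eff], ev[:k_eff]


def bandpass(
    x: np.ndarray,
    tr: float,
    band: tuple = BAND_HZ,
    method: str = "fft",
) -> np.ndarray:
    """Band-pass along axis 0.

    ``method='fft'`` is an ideal filter: rFFT bins strictly outside
    [low, high] Hz (including DC) are zeroed.  ``method='butter'`` is a
    4th-order zero-phase Butterworth alternative.
    """
    x = np.asarray(x, dtype=float)
    low, high = band
    if method == "fft":
        n = x.shape[0]
        freqs = np.fft.rfftfreq(n, d=tr)
        keep = (freqs >= low) & (freqs <= high)
        spec = np.fft.rfft(x, axis=0)
        spec[~keep] = 0.0
        return np.fft.irfft(spec, n=n, axis=0)
    if method == "butter":
        nyq = 0.5 / tr
        sos = sp_signal.butter(4, [low / nyq, high / nyq], btype="band", output="sos")
        return sp_signal.sosfiltfilt(sos, x - x.mean(axis=0), axis=0)
    raise ValueError(f"unknown band-pass method {method!r}")


def _nuisance_matrix(
    motion: np.ndarray, flags: np.ndarray, components: np.ndarray
) -> np.ndarray:
    T = motion.shape[0]
    derivs = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    cols = [np.ones((T, 1)), motion, derivs]
    if components.size:
        cols.append(components)
    for v in np.flatnonzero(flags):
        spike = np.zeros((T, 1))
        spike[v] = 1.0
        cols.append(spike)
    return np.column_stack(cols)


def denoise(
    data: np.ndarray,
    motion: np.ndarray,
    flags: np.ndarray,
    components: np.ndarray,
    tr: float,
    band: tuple = BAND_HZ,
    filter_method: str = "fft",
) -> np.ndarray:
    """Residualize nuisance regressors, then band-pass (in that order)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    squeeze = False
    if data.shape[0] == 1 and motion.shape[0] != 1:
        data, squeeze = data.T, True
    T = data.shape[0]
    if motion.shape[0] != T or len(flags) != T:
        raise ValueError("regressors must align with retained volumes")
    if components.size and components.shape[0] != T:
        raise ValueError("aCompCor components must align with retained volumes")
    X = _nuisance_matrix(motion, flags, components)
    beta, *_ = np.linalg.lstsq(X, data, rcond=None)
    resid = data - X @ beta
    out = bandpass(resid, tr, band, method=filter_method)
    return out[:, 0] if squeeze else out


def roi_coupling(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Fisher z of the Pearson correlation between two ROI-mean series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant series: coupling undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(fisher_z(np.array(r)))


def preprocess_scan(
    roi_data: dict,
    wm: np.ndarray,
    csf: np.ndarray,
    motion: np.ndarray,
    tr: float,
    band: tuple = BAND_HZ,
    k: int = 5,
    n_trim: int = N_TRIM_VOLUMES,
    filter_method: str = "fft",
) -> dict:
    """Full per-scan pipeline; returns denoised ROI-mean series.

    Flagged volumes are absorbed by spike regressors (never deleted), so
    output length is ``T - n_trim``.
    """
    roi_data = {roi: np.asarray(v, dtype=float)[n_trim:] for roi, v in roi_data.items()}
    wm, csf = np.asarray(wm)[n_trim:], np.asarray(csf)[n_trim:]
    motion = np.asarray(motion)[n_trim:]
    allvox = np.concatenate(list(roi_data.values()), axis=1)
    flags = art_flags(allvox, motion)
    comps, _ = acompcor(np.concatenate([wm, csf], axis=1), k=k)
    out = {}
    for roi, vox in roi_data.items():
        mean_series = vox.mean(axis=1)
        out[roi] = denoise(
            mean_series[:, None], motion, flags, comps, tr, band, filter_method
        )[:, 0]
    return out


def coupling_delta(pre: dict, post: dict, roi_a: str, roi_b: str) -> dict:
    """Post-minus-pre Fisher-z coupling for one ROI pair.

    ``pre``/``post`` map ROI name -> denoised mean series (identically
    preprocessed).
    """
    z_pre = roi_coupling(pre[roi_a], pre[roi_b])
    z_post = roi_coupling(post[roi_a], post[roi_b])
    return {"z_pre": z_pre, "z_post": z_post, "delta": z_post - z_pre}


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float
    ci: tuple  # 95% CI on r; upper bound 1.0 for the one-tailed test
    tail: str
    n: int


def brain_behavior(
    deltas: np.ndarray, scores: np.ndarray, tail: str = "one"
) -> CorrelationResult:
    """Pearson correlation between coupling deltas and memory scores.

    ``tail='one'`` tests the a-priori positive direction and reports a
    one-sided 95% CI with upper bound 1; ``tail='two'`` is the standard
    two-sided test with a symmetric Fisher-z CI.
    """
    x = np.asarray(deltas, dtype=float)
    y = np.asarray(scores, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, have {n}")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(max(1.0 - r**2, 1e-15))
    if tail == "two":
        p = 2.0 * sp_stats.t.sf(abs(t), df)
        zcrit = sp_stats.norm.ppf(0.975)
        zr, se = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)), 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(zr - zcrit * se)), float(np.tanh(zr + zcrit * se)))
    else:
        p = float(sp_stats.t.sf(t, df))
        zcrit = sp_stats.norm.ppf(0.95)
        zr, se = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)), 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(zr - zcrit * se)), 1.0)
    return CorrelationResult(r, float(t), df, float(p), ci, tail, n)


def williams_test(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Williams' t for H0: rho12 = rho13 with rho23 shared (df = n - 3).

    Two-sided p; sign(t) = sign(r12 - r13).
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must be in (-1, 1), got {r}")
    if n <= 3:
        raise ValueError("need n > 3")
    det = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * det * (n - 1) / (n - 3) + rbar**2 * (1.0 - r23) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation triple")
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    p = 2.0 * sp_stats.t.sf(abs(t), n - 3)
    return float(t), float(p)
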