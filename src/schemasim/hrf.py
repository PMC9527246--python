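"""Canonical double-gamma hemodynamic response and regressor construction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["HRFSpec", "sample_hrf", "hrf_regressor"]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF: positive peak minus scaled undershoot.

    Defaults are the canonical shape (peak 6 s, undershoot 16 s, unit
    dispersions, 1:6 undershoot ratio, 32 s support).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        peak = gamma_dist.pdf(
            t, self.peak_delay / self.peak_dispersion, scale=self.peak_dispersion
        )
        under = gamma_dist.pdf(
            t,
            self.undershoot_delay / self.undershoot_dispersion,
            scale=self.undershoot_dispersion,
        )
        h = peak - self.undershoot_ratio * under
        h[t < 0] = 0.0
        return h


def sample_hrf(spec: HRFSpec | None = None, dt: float = 0.1) -> np.ndarray:
    """HRF kernel sampled every ``dt`` seconds, peak-normalized to 1."""
    spec = spec or HRFSpec()
    t = np.arange(0.0, spec.length + dt, dt)
    h = spec.evaluate(t)
    m = np.max(np.abs(h))
    if m == 0:
        raise ValueError("degenerate HRF: zero kernel")
    return h / m


def hrf_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_volumes: int,
    tr: float,
    spec: HRFSpec | None = None,
    oversample: int = 15,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at volume acquisition times.

    The boxcar is built on an oversampled grid (``tr / oversample``) so that
    sub-TR onsets and durations are represented faithfully, convolved with
    the kernel, and then sampled at ``t = i * tr``.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if durations.size == 1:
        durations = np.full_like(onsets, durations[0])
    if onsets.shape != durations.shape:
        raise ValueError("onsets and durations must align")

    dt = tr / oversample
    n_fine = n_volumes * oversample + int(np.ceil((spec or HRFSpec()).length / dt))
    box = np.zeros(n_fine)
    for on, dur in zip(onsets, durations):
        i0 = int(np.round(on / dt))
        i1 = int(np.round((on + dur) / dt))
        if i0 >= n_fine:
            raise ValueError(f"onset {on} s outside the run")
        box[i0 : max(i1, i0 + 1)] = 1.0
    kernel = sample_hrf(spec, dt)
    conv = np.convolve(box, kernel)[:n_fine] * dt
    idx = (np.arange(n_volumes) * oversample).astype(int)
    return conv[idx]
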