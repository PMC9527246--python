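"""Condition-paired, cross-run pattern similarity.

Two pairing schemes over retrieval-trial patterns, always restricted to
pairs from different runs and to pairs sharing the same operational
congruency:

congruency scheme
    Trials where the context was retrieved (coarse + detailed).  Pairs are
    labeled ``within_context`` / ``across_context``.

granularity scheme
    Detailed trials only.  Pairs are labeled ``same_scene`` /
    ``similar_scene`` (the other scene of the same context) /
    ``other_context``.

Forgotten-trial variants reuse both schemes with a grain filter.  Pearson r
per pair is Fisher-transformed with clipping at |r| = 1 - 1e-7.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FISHER_CLIP",
    "zscore_pattern",
    "zscore_patterns",
    "fisher_z",
    "pair_table",
    "compute_similarity_table",
    "univariate_mean",
]

FISHER_CLIP = 1.0 - 1e-7

SCHEMES = ("congruency", "granularity")


class ConstantPatternError(ValueError):
    """Pattern vector has zero variance and cannot be z-scored."""


def zscore_pattern(vec: np.ndarray) -> np.ndarray:
    """Z-score one voxel vector (population sd)."""
    vec = np.asarray(vec, dtype=float)
    if vec.ndim != 1 or vec.size < 2:
        raise ValueError("pattern must be a vector of length >= 2")
    sd = vec.std()
    if sd == 0:
        raise ConstantPatternError("constant pattern vector")
    return (vec - vec.mean()) / sd


def zscore_patterns(mats: np.ndarray, axis: str = "voxel") -> tuple[np.ndarray, np.ndarray]:
    """Z-score a (n_trials, V) matrix.

    ``axis='voxel'`` normalizes each trial vector across voxels (default);
    ``axis='trial'`` normalizes each voxel across trials.  Returns the
    z-scored matrix and a boolean mask of degenerate (constant) rows, which
    are excluded from similarity.
    """
    mats = np.asarray(mats, dtype=float)
    if axis == "voxel":
        sd = mats.std(axis=1, keepdims=True)
        degenerate = sd[:, 0] == 0
        sd = np.where(sd == 0, 1.0, sd)
        return (mats - mats.mean(axis=1, keepdims=True)) / sd, degenerate
    if axis == "trial":
        sd = mats.std(axis=0, keepdims=True)
        z = (mats - mats.mean(axis=0, keepdims=True)) / np.where(sd == 0, 1.0, sd)
        return z, np.zeros(mats.shape[0], dtype=bool)
    raise ValueError(f"unknown z-scoring axis {axis!r}")


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping at |r| = 1 - 1e-7 so z stays finite."""
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def _granularity_label(row_i, row_j) -> str:
    if row_i.scene_id == row_j.scene_id:
        return "same_scene"
    if row_i.context == row_j.context:
        return "similar_scene"
    return "other_context"


def pair_table(meta: pd.DataFrame, scheme: str, forgotten: bool = False) -> pd.DataFrame:
    """Enumerate admissible unordered trial pairs under a scheme.

    ``meta`` is the pattern metadata for one participant x ROI x delay with
    columns ``run, congruency, grain, context, scene_id, object_id``; the
    positional index of each row addresses the pattern matrix.

    Returns a frame with ``i, j, pair_label, congruency`` (i < j positions).
    Same-run pairs and cross-congruency pairs are never emitted.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if forgotten:
        eligible = meta["grain"] == "forgotten"
    elif scheme == "congruency":
        eligible = meta["grain"].isin(["coarse", "detailed"])
    else:
        eligible = meta["grain"] == "detailed"
    idx = np.flatnonzero(eligible.to_numpy())
    sub = meta.iloc[idx]
    m = len(idx)
    if m < 2:
        return pd.DataFrame(columns=["i", "j", "pair_label", "congruency"])
    run = sub["run"].to_numpy()
    cong = sub["congruency"].to_numpy()
    ctx = sub["context"].to_numpy()
    scene = sub["scene_id"].to_numpy()
    ii, jj = np.triu_indices(m, k=1)
    keep = (run[ii] != run[jj]) & (cong[ii] == cong[jj])
    ii, jj = ii[keep], jj[keep]
    if scheme == "congruency":
        labels = np.where(ctx[ii] == ctx[jj], "within_context", "across_context")
    else:
        labels = np.where(
            scene[ii] == scene[jj],
            "same_scene",
            np.where(ctx[ii] == ctx[jj], "similar_scene", "other_context"),
        )
    return pd.DataFrame(
        {
            "i": idx[ii].astype(int),
            "j": idx[jj].astype(int),
            "pair_label": labels,
            "congruency": cong[ii],
        }
    )


def compute_similarity_table(
    meta: pd.DataFrame,
    mats: np.ndarray,
    scheme: str,
    forgotten: bool = False,
    zscore_axis: str = "voxel",
) -> pd.DataFrame:
    """Long-format similarity records for one participant x ROI block.

    Patterns are z-scored, Pearson-correlated pairwise, and filtered by the
    pairing scheme; each admissible unordered pair appears exactly once.

    Columns: participant, roi, scheme, pair_label, congruency, delay,
    trial_i, trial_j, run_i, run_j, r, z.
    """
    if len(meta) != mats.shape[0]:
        raise ValueError("meta rows must match pattern matrix rows")
    meta = meta.reset_index(drop=True)
    frames = []
    for delay, dmeta in meta.groupby("delay", sort=True):
        dmeta = dmeta.copy()
        pos = dmeta.index.to_numpy()  # positions into mats
        dmeta = dmeta.reset_index(drop=True)
        block = mats[pos]
        z, degenerate = zscore_patterns(block, axis=zscore_axis)
        pairs = pair_table(dmeta, scheme, forgotten=forgotten)
        if degenerate.any():
            bad = set(np.flatnonzero(degenerate))
            pairs = pairs[~(pairs["i"].isin(bad) | pairs["j"].isin(bad))]
        if pairs.empty:
            continue
        v = z.shape[1]
        zi, zj = z[pairs["i"].to_numpy()], z[pairs["j"].to_numpy()]
        # rows are z-scored (population), so Pearson r is the mean product
        zin, _ = zscore_patterns(zi, axis="voxel")
        zjn, _ = zscore_patterns(zj, axis="voxel")
        r = (zin * zjn).sum(axis=1) / v
        frames.append(
            pd.DataFrame(
                {
                    "participant": dmeta["participant"].iloc[0],
                    "roi": dmeta["roi"].iloc[0],
                    "scheme": scheme + ("_forgotten" if forgotten else ""),
                    "pair_label": pairs["pair_label"].to_numpy(),
                    "congruency": pairs["congruency"].to_numpy(),
                    "delay": delay,
                    "trial_i": dmeta["object_id"].to_numpy()[pairs["i"]],
                    "trial_j": dmeta["object_id"].to_numpy()[pairs["j"]],
                    "run_i": dmeta["run"].to_numpy()[pairs["i"]],
                    "run_j": dmeta["run"].to_numpy()[pairs["j"]],
                    "r": r,
                    "z": fisher_z(r),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "participant", "roi", "scheme", "pair_label", "congruency",
                "delay", "trial_i", "trial_j", "run_i", "run_j", "r", "z",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def univariate_mean(values: np.ndarray, roi_indices: np.ndarray | None = None) -> float:
    """Mean t-value over an ROI — the simple univariate-activation control."""
    values = np.asarray(values, dtype=float)
    if roi_indices is not None:
        values = values[np.asarray(roi_indices)]
    if values.size == 0:
        raise ValueError("empty ROI")
    return float(values.mean())
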