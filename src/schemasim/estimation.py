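"""Single-trial pattern estimation via least-squares-single (LSS) GLMs.

Each retrieval trial is estimated in its own ordinary-least-squares model:
one target regressor for the trial's cue period, up to five nuisance
regressors grouping the remaining same-run trials by outcome type (coarse
congruent, coarse incongruent, detailed congruent, detailed incongruent,
forgotten), a response-window regressor, six rigid-body motion columns, and
one indicator column per motion-flagged volume.  The per-voxel t-map of the
target column is the trial's pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TrialEvent
from .hrf import HRFSpec, hrf_regressor

__all__ = [
    "TRIAL_TYPES",
    "FD_THRESHOLD_MM",
    "DesignMatrix",
    "TrialTMap",
    "framewise_displacement",
    "build_lss_design",
    "lss_fit",
    "estimate_all_trials",
]

FD_THRESHOLD_MM = 0.9
ROTATION_RADIUS_MM = 50.0

TRIAL_TYPES = (
    "coarse_congruent",
    "coarse_incongruent",
    "detailed_congruent",
    "detailed_incongruent",
    "forgotten",
)


class RankDeficientDesign(np.linalg.LinAlgError):
    pass


def framewise_displacement(
    motion: np.ndarray, threshold: float = FD_THRESHOLD_MM
) -> tuple[np.ndarray, np.ndarray]:
    """Power-style framewise displacement and over-threshold flags.

    FD(t) = sum |Delta translation| + 50 mm * sum |Delta rotation|, with the
    first volume set to 0.

    Parameters
    ----------
    motion
        (T, 6): translations in mm then rotations in radians.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must be (T, 6), got {motion.shape}")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = diffs[:, :3].sum(axis=1) + ROTATION_RADIUS_MM * diffs[:, 3:].sum(axis=1)
    return fd, fd > threshold


def _trial_type(outcome_row) -> str:
    grain = outcome_row["grain"]
    if grain == "forgotten":
        return "forgotten"
    return f"{grain}_{outcome_row['congruency']}"


@dataclass
class DesignMatrix:
    X: np.ndarray  # (T, p)
    columns: list
    target_index: int = 0

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))


def build_lss_design(
    events: list[TrialEvent],
    outcomes: pd.DataFrame,
    target_object_id: str,
    motion: np.ndarray,
    flags: np.ndarray,
    n_volumes: int,
    tr: float,
    hrf: HRFSpec | None = None,
    joint_response_window: bool = True,
) -> DesignMatrix:
    """LSS design for one target trial within one run.

    ``events`` must all come from the run containing the target trial;
    ``outcomes`` supplies ``object_id``, ``grain``, ``congruency`` for the
    grouping of the non-target trials.
    """
    if not events:
        raise ValueError("empty run")
    if motion.shape[0] != n_volumes:
        raise ValueError("motion table must have one row per volume")
    by_obj = {ev.pair.object_id: ev for ev in events}
    if target_object_id not in by_obj:
        raise ValueError(f"target trial {target_object_id!r} not in this run")
    omap = outcomes.set_index("object_id")

    hrf = hrf or HRFSpec()
    target = by_obj[target_object_id]
    cue_dur = target.durations[0][1]
    cols = [hrf_regressor([target.onset], [cue_dur], n_volumes, tr, hrf)]
    names = ["target"]

    groups: dict[str, list] = {t: [] for t in TRIAL_TYPES}
    for ev in events:
        if ev.pair.object_id == target_object_id:
            continue
        groups[_trial_type(omap.loc[ev.pair.object_id])].append(ev)
    for ttype in TRIAL_TYPES:
        evs = groups[ttype]
        if not evs:
            continue  # empty trial-type groups are dropped
        onsets = [e.onset for e in evs]
        durs = [e.durations[0][1] for e in evs]
        cols.append(hrf_regressor(onsets, durs, n_volumes, tr, hrf))
        names.append(f"tt_{ttype}")

    # response windows: everything after the cue component, all trials
    resp_onsets, resp_durs = [], []
    for ev in events:
        t0 = ev.onset + ev.durations[0][1]
        dur = sum(d for name, d in ev.durations[1:] if name != "jitter")
        resp_onsets.append(t0)
        resp_durs.append(dur)
    if joint_response_window:
        cols.append(hrf_regressor(resp_onsets, resp_durs, n_volumes, tr, hrf))
        names.append("response")
    else:
        for k, (o, d) in enumerate(zip(resp_onsets, resp_durs)):
            cols.append(hrf_regressor([o], [d], n_volumes, tr, hrf))
            names.append(f"response_{k}")

    X = np.column_stack(cols + [motion])
    names += [f"motion_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]

    flags = np.asarray(flags, dtype=bool)
    for v in np.flatnonzero(flags):
        spike = np.zeros(n_volumes)
        spike[v] = 1.0
        X = np.column_stack([X, spike])
        names.append(f"spike_{v}")

    X = np.column_stack([X, np.ones(n_volumes)])
    names.append("intercept")

    # drop exactly-zero columns (e.g., degenerate regressors)
    keep = ~np.all(X == 0, axis=0)
    X, names = X[:, keep], [n for n, k in zip(names, keep) if k]
    return DesignMatrix(X, names, target_index=names.index("target"))


@dataclass
class TrialTMap:
    trial_id: str
    t: np.ndarray  # per-voxel t of the target column (+inf where residual 0)
    beta: np.ndarray  # per-voxel target beta
    dof: int
    meta: dict = field(default_factory=dict)


def lss_fit(data: np.ndarray, design: DesignMatrix, trial_id: str = "") -> TrialTMap:
    """Per-voxel OLS for one LSS model; returns the target-column t-map.

    t = beta / SE, SE^2 = sigma^2 * (X'X)^{-1}_target.  Zero-residual voxels
    get a +/-inf sentinel in the t-map (the beta map is exact there).
    """
    X = design.X
    n, p = X.shape
    if data.shape[0] != n:
        raise ValueError("data rows must match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        gram = X.T @ X
        corr = np.corrcoef(X.T + 1e-12 * np.random.default_rng(0).standard_normal(X.T.shape))
        bad = [
            (design.columns[i], design.columns[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        raise RankDeficientDesign(
            f"rank-deficient design (rank {rank} < {p}); "
            f"near-collinear column pairs: {bad[:5]}"
        )
    pinv = np.linalg.pinv(X)
    beta_all = pinv @ data  # (p, V)
    resid = data - X @ beta_all
    dof = n - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    # numerically zero residuals (perfect fit) get the +/-inf sentinel
    scale = np.maximum((data**2).mean(axis=0), np.finfo(float).tiny)
    sigma2 = np.where(sigma2 < 1e-18 * scale, 0.0, sigma2)
    xtx_inv_tt = float((pinv @ pinv.T)[design.target_index, design.target_index])
    beta = beta_all[design.target_index]
    se = np.sqrt(sigma2 * xtx_inv_tt)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    return TrialTMap(trial_id, t, beta, dof)


def estimate_all_trials(
    runs: dict,
    outcomes: pd.DataFrame,
    tr: float,
    hrf: HRFSpec | None = None,
) -> list[TrialTMap]:
    """One t-map per retrieval trial across all runs, deterministic order.

    ``runs`` maps run_index -> dict with keys ``events`` (TrialEvent list),
    ``data`` ((T, V) array), ``motion`` ((T, 6) array).
    """
    maps: list[TrialTMap] = []
    for run_index in sorted(runs):
        run = runs[run_index]
        events, data, motion = run["events"], run["data"], run["motion"]
        run_out = outcomes[outcomes["run"] == run_index]
        _, flags = framewise_displacement(motion)
        for ev in sorted(events, key=lambda e: e.trial_index):
            oid = ev.pair.object_id
            try:
                design = build_lss_design(
                    events, run_out, oid, motion, flags, data.shape[0], tr, hrf
                )
                tmap = lss_fit(data, design, trial_id=oid)
            except Exception as err:
                raise RuntimeError(
                    f"LSS failed for trial {oid!r} in run {run_index}"
                ) from err
            tmap.meta.update(run=run_index, trial_index=ev.trial_index)
            maps.append(tmap)
    return maps
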