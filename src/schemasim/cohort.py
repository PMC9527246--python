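"""Synthetic cohort generation with known ground truth.

Every measured quantity in the pipeline has a generative counterpart here:
per-trial memory outcomes drawn from condition-dependent probabilities,
trial-level ROI patterns built from shared context/scene/item components,
BOLD runs via HRF convolution with AR(1) noise and drift, and pre/post rest
series whose inter-ROI coupling change is linked to simulated memory scores.
Defaults are qualitative shapes only — no real-data fitting is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import design as dsg
from .hrf import HRFSpec, hrf_regressor

__all__ = [
    "BehaviorModel",
    "PatternWeights",
    "BoldNoise",
    "RestModel",
    "CohortConfig",
    "LatentComponents",
    "SimulatedRun",
    "RestScan",
    "simulate_judgments",
    "simulate_behavior",
    "draw_latent_components",
    "simulate_trial_patterns",
    "simulate_bold_run",
    "simulate_rest_pair",
    "simulate_cohort",
]

CONDITIONS = [
    ("congruent", "short"),
    ("congruent", "long"),
    ("incongruent", "short"),
    ("incongruent", "long"),
]


@dataclass
class BehaviorModel:
    """P(grain | congruency, delay) plus response-construction knobs."""

    #: (congruency, delay) -> (P(detailed), P(coarse)); P(forgotten) is the rest
    probs: dict = field(
        default_factory=lambda: {
            ("congruent", "short"): (0.65, 0.05),
            ("congruent", "long"): (0.40, 0.15),
            ("incongruent", "short"): (0.55, 0.05),
            ("incongruent", "long"): (0.30, 0.05),
        }
    )
    #: P(judging "related" on one encoding run | intended congruency)
    p_related_congruent: float = 0.9
    p_related_incongruent: float = 0.1
    p_missing_judgment: float = 0.0
    #: among coarse trials, fraction answering "don't know" at the scene
    #: screen (the rest choose the wrong scene of the same context)
    coarse_dont_know_ratio: float = 0.5
    #: among forgotten trials, fraction choosing the wrong context (the rest
    #: answer "don't know" to the context question)
    forgotten_wrong_context: float = 0.5

    def validate(self) -> None:
        for key in CONDITIONS:
            if key not in self.probs:
                raise ValueError(f"behavior probability table missing cell {key}")
            pd_, pc = self.probs[key]
            if pd_ < 0 or pc < 0 or pd_ + pc > 1 + 1e-12:
                raise ValueError(
                    f"invalid probabilities for {key}: detailed={pd_}, coarse={pc}"
                )


@dataclass(frozen=True)
class PatternWeights:
    """Component weights of the trial-pattern generative model."""

    w_ctx: float = 0.3
    w_scene: float = 0.4
    w_item: float = 0.6
    noise_sd: float = 1.0

    def expected_r(self, other: "PatternWeights", shared: str) -> float:
        """Large-V expected Pearson r between two trials sharing components.

        ``shared`` is one of ``'context'`` (same context, different scene,
        different item), ``'scene'`` (same scene, different item), ``'item'``
        (hypothetical identical item + scene + context), ``'none'``.
        """
        num = {
            "none": 0.0,
            "context": self.w_ctx * other.w_ctx,
            "scene": self.w_ctx * other.w_ctx + self.w_scene * other.w_scene,
            "item": self.w_ctx * other.w_ctx
            + self.w_scene * other.w_scene
            + self.w_item * other.w_item,
        }[shared]
        va = self.w_ctx**2 + self.w_scene**2 + self.w_item**2 + self.noise_sd**2
        vb = other.w_ctx**2 + other.w_scene**2 + other.w_item**2 + other.noise_sd**2
        return num / np.sqrt(va * vb)


def default_pattern_weights() -> dict:
    """Context integration grows for congruent pairs at the long delay only."""
    return {
        ("congruent", "short"): PatternWeights(w_ctx=0.30),
        ("congruent", "long"): PatternWeights(w_ctx=0.55),
        ("incongruent", "short"): PatternWeights(w_ctx=0.30),
        ("incongruent", "long"): PatternWeights(w_ctx=0.30),
    }


@dataclass
class BoldNoise:
    white_sd: float = 1.0
    ar1: float = 0.3
    drift_amplitude: float = 0.5
    drift_order: int = 2
    #: expected number of injected >0.9 mm FD motion spikes per run
    spikes_per_run: float = 1.0
    spike_size_mm: float = 1.2


@dataclass
class RestModel:
    """Pre/post rest coupling and its link to memory scores.

    Target correlations are parameterized in r units; the shared-latent
    construction gives series with E[corr] = r_target.  The post-minus-pre
    Fisher-z delta is ``delta_mean + link_beta * standardized score + noise``.
    """

    r_pre_mean: float = 0.30
    r_pre_sd: float = 0.08
    delta_mean: float = 0.10
    link_beta: float = 0.25
    link_noise_sd: float = 0.17
    n_volumes: int = 240  # 6 min at TR = 1.5 s, before trimming
    n_voxels: int = 30
    n_noise_voxels: int = 40
    band: tuple = (0.008, 0.09)
    #: out-of-band sinusoid contamination (Hz, amplitude)
    contam_freq_hz: float = 0.2
    contam_amplitude: float = 1.0
    #: shared nuisance leak into both ROIs (removed by aCompCor)
    nuisance_leak: float = 0.2
    voxel_noise_sd: float = 0.5
    motion_spikes_per_scan: float = 1.0
    global_spikes_per_scan: float = 1.0


@dataclass
class CohortConfig:
    n_participants: int = 23
    n_group_a: int = 11  # counterbalancing group A; the rest are group B
    rois: dict = field(
        default_factory=lambda: {"mpfc": 300, "ant_hpc": 300, "post_hpc": 300}
    )
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    pattern_weights: dict = field(default_factory=default_pattern_weights)
    #: optional per-ROI overrides: roi -> {(congruency, delay): PatternWeights}
    roi_pattern_weights: dict = field(default_factory=dict)
    bold: BoldNoise = field(default_factory=BoldNoise)
    rest: RestModel = field(default_factory=RestModel)
    tr: float = 1.5
    hrf: HRFSpec = field(default_factory=HRFSpec)

    def validate(self) -> None:
        self.behavior.validate()
        for name, v in self.rois.items():
            if v < 10:
                raise ValueError(f"ROI {name!r} must have >= 10 voxels")
        for key in CONDITIONS:
            if key not in self.pattern_weights:
                raise ValueError(f"pattern weights missing cell {key}")

    def weights_for(self, roi: str, congruency: str, delay: str) -> PatternWeights:
        table = self.roi_pattern_weights.get(roi, self.pattern_weights)
        return table[(congruency, delay)]

    # -- YAML round-trip (tuple keys flattened to 'congruency/delay') -------
    def to_dict(self) -> dict:
        d = {
            "n_participants": self.n_participants,
            "n_group_a": self.n_group_a,
            "rois": dict(self.rois),
            "tr": self.tr,
            "behavior": {
                **{
                    k: v
                    for k, v in asdict(self.behavior).items()
                    if k != "probs"
                },
                "probs": {
                    f"{c}/{dl}": list(self.behavior.probs[(c, dl)])
                    for c, dl in CONDITIONS
                },
            },
            "pattern_weights": {
                f"{c}/{dl}": asdict(self.pattern_weights[(c, dl)])
                for c, dl in CONDITIONS
            },
            "bold": asdict(self.bold),
            "rest": {**asdict(self.rest), "band": list(self.rest.band)},
            "hrf": asdict(self.hrf),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        cfg = cls()
        cfg.n_participants = d.get("n_participants", cfg.n_participants)
        cfg.n_group_a = d.get("n_group_a", cfg.n_group_a)
        cfg.rois = dict(d.get("rois", cfg.rois))
        cfg.tr = d.get("tr", cfg.tr)
        if "behavior" in d:
            b = dict(d["behavior"])
            probs = b.pop("probs", None)
            cfg.behavior = BehaviorModel(**b)
            if probs is not None:
                cfg.behavior.probs = {
                    tuple(k.split("/")): tuple(v) for k, v in probs.items()
                }
        if "pattern_weights" in d:
            cfg.pattern_weights = {
                tuple(k.split("/")): PatternWeights(**v)
                for k, v in d["pattern_weights"].items()
            }
        if "bold" in d:
            cfg.bold = BoldNoise(**d["bold"])
        if "rest" in d:
            r = dict(d["rest"])
            if "band" in r:
                r["band"] = tuple(r["band"])
            cfg.rest = RestModel(**r)
        if "hrf" in d:
            cfg.hrf = HRFSpec(**d["hrf"])
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_judgments(
    pairs: list[dsg.StimulusPair], config: CohortConfig, rng: np.random.Generator
) -> list[bhv.EncodingJudgments]:
    """Three per-run relatedness judgments per pair, noisy around the
    intended congruency."""
    bm = config.behavior
    out = []
    for pair in pairs:
        p_rel = (
            bm.p_related_congruent
            if pair.intended_congruency == "congruent"
            else bm.p_related_incongruent
        )
        js = []
        for _ in range(3):
            if rng.random() < bm.p_missing_judgment:
                js.append("missing")
            elif rng.random() < p_rel:
                js.append("related")
            else:
                js.append("unrelated")
        out.append(bhv.EncodingJudgments(pair.object_id, tuple(js)))
    return out


def simulate_behavior(
    config: CohortConfig,
    retrieval_events: list[dsg.TrialEvent],
    judgments: list[bhv.EncodingJudgments],
    rng: np.random.Generator,
    participant: str = "sub-01",
) -> pd.DataFrame:
    """Draw per-trial outcomes for one participant and one delay list.

    The grain is drawn from P(grain | operational congruency, delay) and the
    response fields are constructed to be consistent with it, so that
    re-scoring the constructed responses recovers the drawn grain exactly.
    """
    config.behavior.validate()
    bm = config.behavior
    jmap = {j.object_id: j for j in judgments}
    scene_of_context = {
        ctx: [s for s, c in dsg.SCENES.items() if c == ctx] for ctx in dsg.CONTEXTS
    }
    rows = []
    for ev in retrieval_events:
        pair = ev.pair
        try:
            cong = bhv.operationalize_congruency(jmap[pair.object_id])
        except bhv.IndeterminateCongruency:
            continue  # dropped from condition totals, as in scoring
        p_det, p_coarse = bm.probs[(cong, pair.delay_list)]
        u = rng.random()
        if u < p_det:
            grain = "detailed"
            ctx_resp, scene_resp = pair.context, pair.scene_id
        elif u < p_det + p_coarse:
            grain = "coarse"
            ctx_resp = pair.context
            if rng.random() < bm.coarse_dont_know_ratio:
                scene_resp = "dont_know"
            else:
                scene_resp = next(
                    s for s in scene_of_context[pair.context] if s != pair.scene_id
                )
        else:
            grain = "forgotten"
            if rng.random() < bm.forgotten_wrong_context:
                wrong_ctx = "beach" if pair.context == "kitchen" else "kitchen"
                ctx_resp = wrong_ctx
                scene_resp = str(rng.choice(scene_of_context[wrong_ctx] + ["dont_know"]))
            else:
                ctx_resp, scene_resp = "dont_know", "absent"
        rows.append(
            {
                "participant": participant,
                "delay": pair.delay_list,
                "object_id": pair.object_id,
                "run": ev.run_index,
                "trial_index": ev.trial_index,
                "scene_id": pair.scene_id,
                "context": pair.context,
                "congruency": cong,
                "intended_congruency": pair.intended_congruency,
                "context_response": ctx_resp,
                "scene_response": scene_resp,
                "grain": grain,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trial patterns
# ---------------------------------------------------------------------------

@dataclass
class LatentComponents:
    """Per-participant, per-ROI component vectors (i.i.d. standard normal)."""

    context: dict  # context -> (V,)
    scene: dict  # scene_id -> (V,)
    item: dict  # object_id -> (V,)


def draw_latent_components(
    n_voxels: int, object_ids: list[str], rng: np.random.Generator
) -> LatentComponents:
    return LatentComponents(
        context={c: rng.standard_normal(n_voxels) for c in dsg.CONTEXTS},
        scene={s: rng.standard_normal(n_voxels) for s in dsg.SCENES},
        item={o: rng.standard_normal(n_voxels) for o in object_ids},
    )


def simulate_trial_patterns(
    config: CohortConfig,
    outcomes: pd.DataFrame,
    roi: str,
    rng: np.random.Generator,
    components: LatentComponents | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Trial-level ROI patterns for every outcome row.

    pattern = w_ctx*u_context + w_scene*u_scene + w_item*u_item + noise,
    with weights looked up by (operational congruency, delay, ROI).

    Returns (metadata frame, n_trials x V matrix); row order follows
    ``outcomes``.
    """
    if roi not in config.rois:
        raise ValueError(f"unknown ROI {roi!r}")
    n_vox = config.rois[roi]
    if components is None:
        components = draw_latent_components(
            n_vox, sorted(outcomes["object_id"].unique()), rng
        )
    mats = np.empty((len(outcomes), n_vox))
    for i, row in enumerate(outcomes.itertuples(index=False)):
        if row.scene_id not in dsg.SCENES or row.context not in dsg.CONTEXTS:
            raise ValueError(
                f"unknown scene/context label ({row.scene_id!r}, {row.context!r})"
            )
        w = config.weights_for(roi, row.congruency, row.delay)
        mats[i] = (
            w.w_ctx * components.context[row.context]
            + w.w_scene * components.scene[row.scene_id]
            + w.w_item * components.item[row.object_id]
            + w.noise_sd * rng.standard_normal(n_vox)
        )
    meta = outcomes.reset_index(drop=True).copy()
    meta["roi"] = roi
    return meta, mats


# ---------------------------------------------------------------------------
# BOLD runs
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRun:
    """One simulated BOLD run: (volumes x voxels) data plus ground truth."""

    data: np.ndarray  # (T, V)
    motion: np.ndarray  # (T, 6): 3 translations mm, 3 rotations rad
    tr: float
    events: list  # TrialEvent, this run only
    amplitudes: np.ndarray  # (n_trials, V) ground-truth cue amplitudes
    spike_volumes: list  # injected >threshold motion spikes

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


def _ar1_noise(
    shape: tuple, phi: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    white = rng.standard_normal(shape) * sd
    if phi == 0.0:
        return white
    out = np.empty_like(white)
    out[0] = white[0] / np.sqrt(1 - phi**2)
    for t in range(1, shape[0]):
        out[t] = phi * out[t - 1] + white[t]
    return out


def simulate_bold_run(
    events: list[dsg.TrialEvent],
    amplitudes: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
    n_volumes: int | None = None,
) -> SimulatedRun:
    """Simulate one run: per-voxel signal is the sum over trials of
    amplitude x (HRF * cue boxcar), plus AR(1) noise and polynomial drift.

    ``amplitudes`` is (n_trials, V) in event order.  The motion table is a
    slow random walk with occasional injected translation spikes that exceed
    the downstream framewise-displacement threshold.
    """
    if not events:
        raise ValueError("empty run")
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if amplitudes.shape[0] != len(events):
        raise ValueError("amplitudes rows must match number of events")
    tr = config.tr
    end = max(ev.onset + ev.total_duration for ev in events)
    need = int(np.ceil((end + config.hrf.length) / tr))
    if n_volumes is None:
        n_volumes = need
    elif n_volumes * tr < end:
        raise ValueError(f"run of {n_volumes} volumes too short for schedule")

    n_vox = amplitudes.shape[1]
    data = np.zeros((n_volumes, n_vox))
    for ev, amp in zip(events, amplitudes):
        # the cue/overlay window is the first duration component
        cue_dur = ev.durations[0][1]
        reg = hrf_regressor([ev.onset], [cue_dur], n_volumes, tr, config.hrf)
        data += np.outer(reg, amp)

    noise = config.bold
    if noise.white_sd > 0:
        data += _ar1_noise((n_volumes, n_vox), noise.ar1, noise.white_sd, rng)
    if noise.drift_amplitude > 0:
        t = np.linspace(-1, 1, n_volumes)
        for k in range(1, noise.drift_order + 1):
            coef = noise.drift_amplitude * rng.standard_normal(n_vox)
            data += np.outer(t**k, coef)

    motion = np.cumsum(rng.standard_normal((n_volumes, 6)) * 0.01, axis=0)
    motion[:, 3:] *= 0.002  # rotations in radians, much smaller
    n_spikes = rng.poisson(noise.spikes_per_run)
    spike_volumes = sorted(
        int(v) for v in rng.choice(np.arange(2, n_volumes - 1), size=min(n_spikes, 5), replace=False)
    ) if n_spikes else []
    for v in spike_volumes:
        axis = int(rng.integers(0, 3))
        motion[v:, axis] += noise.spike_size_mm
    return SimulatedRun(data, motion, tr, list(events), amplitudes, spike_volumes)


# ---------------------------------------------------------------------------
# rest scans
# ---------------------------------------------------------------------------

@dataclass
class RestScan:
    """One rest scan: per-ROI voxel blocks plus noise-mask blocks."""

    roi_data: dict  # roi -> (T, V)
    wm: np.ndarray  # (T, n_noise)
    csf: np.ndarray  # (T, n_noise)
    motion: np.ndarray  # (T, 6)
    tr: float
    motion_spike_volumes: list
    global_spike_volumes: list


def bandlimited_noise(
    n: int,
    tr: float,
    band: tuple,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """(n, size) columns of unit-variance noise restricted to ``band`` Hz."""
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError("band empty for this series length")
    spec = np.fft.rfft(rng.standard_normal((n, size)), axis=0)
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n=n, axis=0)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return x


def _rest_scan(
    config: CohortConfig,
    coupling_r: float,
    roi_names: tuple,
    rng: np.random.Generator,
) -> RestScan:
    """Two coupled ROIs sharing a band-limited latent, with out-of-band
    contamination, a shared nuisance leak mirrored in the noise masks, and
    per-voxel white noise."""
    rm = config.rest
    T, tr = rm.n_volumes, config.tr
    c = float(np.sqrt(np.clip(coupling_r, 0.0, 1.0)))
    latent = bandlimited_noise(T, tr, rm.band, rng, 3)  # shared, privA, privB
    nuis = bandlimited_noise(T, tr, rm.band, rng, 1)[:, 0]

    t = np.arange(T) * tr
    roi_data = {}
    for i, roi in enumerate(roi_names):
        mean_sig = c * latent[:, 0] + np.sqrt(1 - c**2) * latent[:, i + 1]
        contam = rm.contam_amplitude * np.sin(
            2 * np.pi * rm.contam_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
        base = mean_sig + contam + rm.nuisance_leak * nuis
        vox = base[:, None] + rm.voxel_noise_sd * rng.standard_normal((T, rm.n_voxels))
        roi_data[roi] = vox

    def noise_block():
        load = rng.standard_normal(rm.n_noise_voxels)
        return np.outer(nuis, load) + 0.3 * rng.standard_normal((T, rm.n_noise_voxels))

    wm, csf = noise_block(), noise_block()

    motion = np.cumsum(rng.standard_normal((T, 6)) * 0.01, axis=0)
    motion[:, 3:] *= 0.002
    n_mspike = rng.poisson(rm.motion_spikes_per_scan)
    mspikes = sorted(
        int(v) for v in rng.choice(np.arange(8, T - 1), size=min(n_mspike, 4), replace=False)
    ) if n_mspike else []
    for v in mspikes:
        motion[v:, int(rng.integers(0, 3))] += 1.5
    n_gspike = rng.poisson(rm.global_spikes_per_scan)
    gspikes = sorted(
        int(v)
        for v in rng.choice(np.arange(8, T - 1), size=min(n_gspike, 4), replace=False)
    ) if n_gspike else []
    for v in gspikes:
        for roi in roi_data:
            roi_data[roi][v] += 6.0 * rm.voxel_noise_sd + 4.0
    return RestScan(roi_data, wm, csf, motion, tr, mspikes, gspikes)


def simulate_rest_pair(
    config: CohortConfig,
    score: float,
    score_mean: float,
    score_sd: float,
    rng: np.random.Generator,
    roi_names: tuple = ("ant_hpc", "mpfc"),
) -> tuple[RestScan, RestScan, dict]:
    """(pre, post) rest scans for one participant.

    The true post-minus-pre Fisher-z coupling delta is
    ``delta_mean + link_beta * (score - score_mean)/score_sd + noise``.
    Returns the two scans plus a ground-truth dict.
    """
    rm = config.rest
    r_pre = float(np.clip(rng.normal(rm.r_pre_mean, rm.r_pre_sd), 0.02, 0.95))
    z_pre = np.arctanh(r_pre)
    std_score = (score - score_mean) / score_sd if score_sd > 0 else 0.0
    delta = rm.delta_mean + rm.link_beta * std_score + rng.normal(0, rm.link_noise_sd)
    z_post = z_pre + delta
    r_post = float(np.clip(np.tanh(z_post), 0.02, 0.95))
    pre = _rest_scan(config, r_pre, roi_names, rng)
    post = _rest_scan(config, r_post, roi_names, rng)
    truth = {
        "r_pre": r_pre,
        "r_post": r_post,
        "z_pre": z_pre,
        "z_post": float(np.arctanh(r_post)),
        "delta_z": float(np.arctanh(r_post) - z_pre),
        "std_score": std_score,
    }
    return pre, post, truth


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    config: CohortConfig
    seed: int
    participants: list
    groups: dict  # participant -> 'A' | 'B'
    outcomes: pd.DataFrame  # all participants x delays, trial level
    scores: pd.DataFrame  # tidy per-condition scores (pre-exclusion)
    designs: dict  # participant -> {'short': [...pairs], 'long': [...]}
    schedules: dict  # participant -> {delay: retrieval TrialEvent list}
    judgments: dict  # participant -> {delay: [EncodingJudgments]}


def participant_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent, reproducible per-participant streams."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def simulate_cohort(config: CohortConfig, seed: int = 0) -> Cohort:
    """Design + behavioral outcomes + scores for a full cohort.

    Trial patterns, BOLD runs, and rest scans are generated on demand by the
    dedicated functions; this keeps the behavioral ledger light.
    """
    config.validate()
    rngs = participant_rngs(seed, config.n_participants)
    participants = [f"sub-{i + 1:02d}" for i in range(config.n_participants)]
    groups = {
        p: ("A" if i < config.n_group_a else "B") for i, p in enumerate(participants)
    }
    all_outcomes, designs, schedules, judgments = [], {}, {}, {}
    for pid, rng in zip(participants, rngs):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        short, long = dsg.make_stimulus_lists(seed=sub_seed)
        designs[pid] = {"short": short, "long": long}
        schedules[pid], judgments[pid] = {}, {}
        for delay, pairs in (("short", short), ("long", long)):
            sched = dsg.make_retrieval_schedule(
                pairs, seed=int(rng.integers(0, 2**31 - 1))
            )
            schedules[pid][delay] = sched
            js = simulate_judgments(pairs, config, rng)
            judgments[pid][delay] = js
            all_outcomes.append(
                simulate_behavior(config, sched, js, rng, participant=pid)
            )
    outcomes = pd.concat(all_outcomes, ignore_index=True)
    scores = bhv.compute_scores(outcomes)
    scores["group"] = scores["participant"].map(groups)
    return Cohort(
        config, seed, participants, groups, outcomes, scores, designs, schedules, judgments
    )
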