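"""Seeded synthetic simulation-suite experiments with known ground truth.

The generator emulates a high-fidelity ICU simulation study: each of
``n_participants`` physicians works through six sepsis scenarios — four with
a safe AI dosing recommendation and two with a deliberately extreme unsafe
one — in a permuted order whose first trial is always safe.  Per trial it
emits:

* a 120 Hz gaze stream built as alternating fixations and saccades, with
  blinks inserted as pupil-confidence dips after fixations;
* ROI box tracks for the nine regions (four clinical surfaces, the AI
  recommendation and four explanation panels nested in the AI screen), all
  jittered jointly by a smooth head-motion random walk, with the explanation
  panels rotating between screen quadrants from trial to trial;
* a prescribing record F = P + w (A - P) + noise with a planted per-trial
  advice weight w, plus per-participant explanation usefulness ratings drawn
  independently of gaze (planted zero dependence).

Attention follows a two-level Dirichlet model: each participant has a profile
over the nine regions (plus "elsewhere"), each trial perturbs it, and under
the unsafe condition the mean weight of the AI-screen family is multiplied by
``unsafe_ai_multiplier`` (other regions renormalized), so the expected
AI-screen fixation count ratio between conditions equals the multiplier
exactly.

Every random draw descends from a single seed through spawned substreams, so
runs are bit-reproducible.  All planted quantities (weights, per-ROI event
counts, full event lists) are returned as ground truth consistent with the
emitted streams by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from clingaze import io as cgio
from clingaze.io import RoiHierarchy, default_roi_hierarchy

ELSEWHERE = "elsewhere"

#: mean attention weights over leaf regions under the safe condition; the
#: AI-screen family (recommendation + panels) totals 0.40
DEFAULT_ATTENTION_WEIGHTS = {
    "ai_recommendation": 0.24,
    "xai_qdiff": 0.04,
    "xai_mortality": 0.04,
    "xai_features": 0.04,
    "xai_examples": 0.04,
    "vitals_monitor": 0.25,
    "icu_chart": 0.12,
    "patient_mannequin": 0.13,
    ELSEWHERE: 0.10,
}

#: base world-view boxes (x_min, y_min, x_max, y_max); areas are sized so
#: strongly-watched small surfaces (monitor) show a high actual/chance ratio
DEFAULT_ROI_LAYOUT = {
    "ai_screen": (0.68, 0.05, 0.96, 0.27),
    "ai_recommendation": (0.68, 0.05, 0.96, 0.11),
    "vitals_monitor": (0.05, 0.08, 0.25, 0.18),
    "icu_chart": (0.35, 0.55, 0.65, 0.80),
    "patient_mannequin": (0.30, 0.15, 0.70, 0.40),
}

#: four screen quadrants available to the explanation panels (rotated per trial)
XAI_SLOTS = (
    (0.68, 0.11, 0.82, 0.19),
    (0.82, 0.11, 0.96, 0.19),
    (0.68, 0.19, 0.82, 0.27),
    (0.82, 0.19, 0.96, 0.27),
)

DEFAULT_FIXATION_MEAN_MS = {
    "patient_mannequin": 135.0,
    "vitals_monitor": 150.0,
    "icu_chart": 155.0,
    "ai_recommendation": 150.0,
    "xai_qdiff": 150.0,
    "xai_mortality": 150.0,
    "xai_features": 145.0,
    "xai_examples": 160.0,
    ELSEWHERE: 120.0,
}

DEFAULT_BLINK_RATE_BPM = {
    "patient_mannequin": 14.7,
    "vitals_monitor": 15.2,
    "icu_chart": 6.1,
    "ai_recommendation": 19.9,
    "xai_qdiff": 19.9,
    "xai_mortality": 19.9,
    "xai_features": 19.9,
    "xai_examples": 19.9,
    ELSEWHERE: 12.0,
}


@dataclass
class AdviceModel:
    """Prescribing model: P ~ N(ref, sd) truncated at 0; A near the reference
    dose when safe, extreme over/under-dose when unsafe; F = P + w (A - P) +
    noise with w ~ Beta per condition."""

    reference_doses: dict = field(default_factory=lambda: {
        "fluid": (250.0, 150.0, 300.0, 200.0, 100.0, 350.0),        # ml/h
        "vasopressor": (0.05, 0.10, 0.20, 0.15, 0.08, 0.30),        # mcg/kg/min
    })
    baseline_sd: dict = field(default_factory=lambda: {
        "fluid": 270.0, "vasopressor": 0.05})
    post_noise_sd: dict = field(default_factory=lambda: {
        "fluid": 30.0, "vasopressor": 0.02})
    safe_advice_range: tuple = (0.8, 1.2)       # x reference dose
    unsafe_over_factor: float = 3.5             # extreme overdose
    unsafe_under_factor: float = 0.1            # extreme underdose
    weight_safe: tuple = (2.0, 3.0)             # Beta(a, b), mean 0.4
    weight_unsafe: tuple = (1.2, 6.0)           # Beta(a, b), mean ~0.17


@dataclass
class GeneratorConfig:
    """Study-design and signal parameters for the synthetic experiment."""

    n_participants: int = 19
    n_scenarios: int = 6
    n_unsafe: int = 2
    sample_rate_hz: float = 120.0
    trial_duration_s: float = 324.0          # 5.4 min mean completion
    trial_duration_sd_s: float = 72.0        # 1.2 min between-trial spread
    track_rate_hz: float = 30.0
    head_jitter_sd: float = 0.002            # per-frame random-walk step
    head_jitter_decay: float = 0.97
    roi_layout: dict = field(default_factory=lambda: dict(DEFAULT_ROI_LAYOUT))
    xai_slots: tuple = XAI_SLOTS
    attention_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_ATTENTION_WEIGHTS))
    participant_concentration: float = 40.0  # Dirichlet, between physicians
    trial_concentration: float = 8.0         # Dirichlet, between trials
    unsafe_ai_multiplier: float = 962.0 / 704.0
    fixation_mean_ms: dict = field(
        default_factory=lambda: dict(DEFAULT_FIXATION_MEAN_MS))
    fixation_sigma: float = 0.25             # lognormal shape
    min_fixation_ms: float = 95.0            # refixation floor (resampled below)
    saccade_gap_ms: tuple = (30.0, 80.0)
    gaze_jitter_sd: float = 0.002            # within-fixation tremor
    blink_rate_bpm: dict = field(default_factory=lambda: dict(DEFAULT_BLINK_RATE_BPM))
    blink_duration_ms: tuple = (100.0, 300.0)
    advice: AdviceModel = field(default_factory=AdviceModel)
    rating_mean: tuple = (2.5, 2.2, 2.8, 2.0)   # per explanation panel, 0-4
    rating_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        w = self.attention_weights
        if any(v < 0 for v in w.values()):
            raise ValueError("attention weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("attention weights must sum to 1")
        ai_total = sum(w[k] for k in w if k in cgio.AI_ROIS)
        if self.unsafe_ai_multiplier * ai_total >= 1.0:
            raise ValueError("unsafe multiplier pushes AI-screen weight to >= 1")
        if self.unsafe_ai_multiplier <= 0:
            raise ValueError("unsafe_ai_multiplier must be positive")
        if any(v < 0 for v in self.blink_rate_bpm.values()):
            raise ValueError("blink rates must be non-negative")
        if self.n_unsafe >= self.n_scenarios:
            raise ValueError("need at least one safe scenario")
        if self.trial_duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("durations and rates must be positive")

    def condition_weights(self, condition: str,
                          base: dict[str, float] | None = None) -> dict[str, float]:
        """Mean leaf weights for a condition: under unsafe AI, the AI-screen
        family is multiplied by the configured factor and the remaining
        regions renormalized, so expected AI-screen fixation counts scale by
        exactly the multiplier."""
        w = dict(base if base is not None else self.attention_weights)
        if condition == "safe":
            return w
        return _apply_ai_multiplier(w, self.unsafe_ai_multiplier)


def _apply_ai_multiplier(w: dict[str, float], m: float) -> dict[str, float]:
    """Scale the AI-screen family's mean weight by m, renormalizing the rest.
    The boosted AI total is capped at 0.95 so extreme profiles stay valid."""
    ai_leaves = [k for k in w if k in cgio.AI_ROIS]
    ai_total = sum(w[k] for k in ai_leaves)
    if ai_total == 0.0 or m == 1.0:
        return dict(w)
    m_eff = min(m, 0.95 / ai_total)
    scale_rest = (1.0 - m_eff * ai_total) / (1.0 - ai_total)
    return {k: (w[k] * m_eff if k in ai_leaves else w[k] * scale_rest) for k in w}


@dataclass
class SyntheticExperiment:
    """In-memory bundle of a generated experiment."""

    config: GeneratorConfig
    hierarchy: RoiHierarchy
    trials: pd.DataFrame
    gaze: dict = field(default_factory=dict)      # (pid, sid) -> DataFrame
    tracks: dict = field(default_factory=dict)    # (pid, sid) -> DataFrame
    ground_truth: dict = field(default_factory=dict)


# --------------------------------------------------------------------------- #
# Trial planning (event level)


def _plan_trial(rng: np.random.Generator, duration_ms: float,
                weights: dict[str, float], cfg: GeneratorConfig) -> pd.DataFrame:
    """Plan the fixation/blink/saccade timeline of one trial (vectorized).

    Returns one row per planted fixation: roi, onset_ms, duration_ms,
    has_blink, blink_duration_ms (the blink follows the fixation dwell).
    """
    leaves = sorted(weights)
    p = np.asarray([weights[k] for k in leaves], dtype=float)
    p = p / p.sum()
    mean_fix = float(np.dot(p, [cfg.fixation_mean_ms[k] for k in leaves]))
    mean_cycle = mean_fix + np.mean(cfg.saccade_gap_ms) + 20.0
    n_est = int(duration_ms / mean_cycle * 1.5) + 30

    roi_idx = rng.choice(len(leaves), size=n_est, p=p)
    mu = np.log([cfg.fixation_mean_ms[leaves[i]] for i in roi_idx])
    mu -= 0.5 * cfg.fixation_sigma**2
    durs = rng.lognormal(mean=mu, sigma=cfg.fixation_sigma)
    # refixation floor: dwells shorter than the floor are resampled
    short = durs < cfg.min_fixation_ms
    while short.any():
        durs[short] = rng.lognormal(mean=mu[short], sigma=cfg.fixation_sigma)
        short = durs < cfg.min_fixation_ms
    gaps = rng.uniform(*cfg.saccade_gap_ms, size=n_est)
    rates = np.asarray([cfg.blink_rate_bpm[leaves[i]] for i in roi_idx])
    has_blink = rng.random(n_est) < rates * durs / 60_000.0
    blink_durs = np.where(has_blink, rng.uniform(*cfg.blink_duration_ms, size=n_est), 0.0)

    seg = durs + blink_durs + gaps
    onsets = np.concatenate(([0.0], np.cumsum(seg)[:-1]))
    keep = onsets + durs <= duration_ms
    plan = pd.DataFrame({
        "roi": [leaves[i] for i in roi_idx[keep]],
        "onset_ms": onsets[keep],
        "duration_ms": durs[keep],
        "has_blink": has_blink[keep],
        "blink_duration_ms": blink_durs[keep],
    })
    return plan


def _plan_counts(plan: pd.DataFrame) -> tuple[dict, dict]:
    fix = plan.groupby("roi").size().to_dict()
    blink = plan[plan["has_blink"]].groupby("roi").size().to_dict()
    return fix, blink


# --------------------------------------------------------------------------- #
# Track + gaze realization


def _trial_layout(cfg: GeneratorConfig, rng: np.random.Generator) -> dict[str, tuple]:
    """Per-trial ROI layout: explanation panels permuted over the four
    screen quadrants (mitigates position bias, exercises moving hit-testing)."""
    layout = dict(cfg.roi_layout)
    panels = ["xai_qdiff", "xai_mortality", "xai_features", "xai_examples"]
    for panel, slot in zip(panels, rng.permutation(len(cfg.xai_slots))):
        layout[panel] = cfg.xai_slots[slot]
    return layout


def _head_offsets(cfg: GeneratorConfig, rng: np.random.Generator,
                  duration_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Smooth AR(1) head-motion offset applied to all boxes jointly."""
    times = np.arange(0.0, duration_ms, 1000.0 / cfg.track_rate_hz)
    off = np.zeros((len(times), 2))
    step = rng.normal(0.0, cfg.head_jitter_sd, size=(len(times), 2))
    for k in range(1, len(times)):
        off[k] = cfg.head_jitter_decay * off[k - 1] + step[k]
    np.clip(off, -0.035, 0.035, out=off)
    return times, off


def _tracks_frame(layout: dict, times: np.ndarray, off: np.ndarray) -> pd.DataFrame:
    frames = []
    for rid in sorted(layout):
        x0, y0, x1, y1 = layout[rid]
        frames.append(pd.DataFrame({
            "t_ms": times,
            "roi_id": rid,
            "x_min": x0 + off[:, 0], "y_min": y0 + off[:, 1],
            "x_max": x1 + off[:, 0], "y_max": y1 + off[:, 1],
            "visible": True,
        }))
    return pd.concat(frames, ignore_index=True)


def _offset_at(times: np.ndarray, off: np.ndarray, t: float) -> np.ndarray:
    k = int(np.searchsorted(times, t, side="right")) - 1
    return off[max(k, 0)]


def _sample_centroid(rng, roi, layout, times, off, t_mid, prev_xy, min_sep):
    """Uniform point inside the ROI's box at the fixation midpoint (with a
    15% inset so the full fixation stays inside despite head motion), at
    least ``min_sep`` away (L1) from the previous fixation target."""
    o = _offset_at(times, off, t_mid)
    if roi == ELSEWHERE:
        boxes = [np.asarray(layout[r]) + np.tile(o, 2)
                 for r in ("ai_screen", "vitals_monitor", "icu_chart", "patient_mannequin")]
        for _ in range(100):
            x, y = rng.uniform(0.0, 1.0, size=2)
            inside = any(b[0] <= x < b[2] and b[1] <= y < b[3] for b in boxes)
            far = abs(x - prev_xy[0]) + abs(y - prev_xy[1]) >= min_sep
            if not inside and far:
                return x, y
        return x, y
    x0, y0, x1, y1 = np.asarray(layout[roi]) + np.tile(o, 2)
    mx, my = 0.15 * (x1 - x0), 0.15 * (y1 - y0)
    for _ in range(100):
        x = rng.uniform(x0 + mx, x1 - mx)
        y = rng.uniform(y0 + my, y1 - my)
        if abs(x - prev_xy[0]) + abs(y - prev_xy[1]) >= min_sep:
            return x, y
    return x, y


def _realize_gaze(cfg: GeneratorConfig, rng: np.random.Generator,
                  plan: pd.DataFrame, layout: dict,
                  times: np.ndarray, off: np.ndarray,
                  duration_ms: float) -> tuple[pd.DataFrame, list[dict]]:
    """Turn a trial plan into a 120 Hz gaze stream plus the planted event list."""
    period = 1000.0 / cfg.sample_rate_hz
    min_sep = 0.04  # planted targets separated by more than the dispersion threshold
    ts, xs, ys, cs = [], [], [], []
    events: list[dict] = []
    prev_xy = (-1.0, -1.0)
    prev_end, prev_cx, prev_cy = None, None, None

    for rec in plan.itertuples(index=False):
        onset, dur = rec.onset_ms, rec.duration_ms
        cx, cy = _sample_centroid(rng, rec.roi, layout, times, off,
                                  onset + dur / 2.0, prev_xy, min_sep)
        # saccade: linear sweep from the previous target to this one
        if prev_end is not None and onset - prev_end > period:
            st = np.arange(prev_end, onset, period)
            if len(st):
                frac = (st - prev_end) / (onset - prev_end)
                ts.append(st)
                xs.append(prev_cx + frac * (cx - prev_cx))
                ys.append(prev_cy + frac * (cy - prev_cy))
                cs.append(rng.uniform(0.8, 1.0, len(st)))
        ft = np.arange(onset, onset + dur, period)
        ts.append(ft)
        xs.append(cx + rng.normal(0.0, cfg.gaze_jitter_sd, len(ft)))
        ys.append(cy + rng.normal(0.0, cfg.gaze_jitter_sd, len(ft)))
        cs.append(rng.uniform(0.8, 1.0, len(ft)))
        events.append({"type": "fixation", "roi": rec.roi,
                       "onset_ms": onset, "offset_ms": onset + dur,
                       "x": cx, "y": cy})
        end = onset + dur
        if rec.has_blink:
            bt = np.arange(end, end + rec.blink_duration_ms, period)
            ts.append(bt)
            xs.append(np.full(len(bt), cx))
            ys.append(np.full(len(bt), cy))
            cs.append(np.full(len(bt), 0.05))
            events.append({"type": "blink", "roi": rec.roi,
                           "onset_ms": end, "offset_ms": end + rec.blink_duration_ms,
                           "x": cx, "y": cy})
            end += rec.blink_duration_ms
        prev_end, prev_cx, prev_cy = end, cx, cy
        prev_xy = (cx, cy)

    gaze = pd.DataFrame({
        "t_ms": np.concatenate(ts),
        "x": np.concatenate(xs),
        "y": np.concatenate(ys),
        "confidence": np.clip(np.concatenate(cs), 0.0, 1.0),
    })
    gaze = gaze[gaze["t_ms"] < duration_ms].reset_index(drop=True)
    return gaze, events


# --------------------------------------------------------------------------- #
# Design + prescriptions


def _assign_design(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per participant: which scenarios are unsafe and in what order they are
    met, with the first trial always safe."""
    rows = []
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        unsafe = set(rng.choice(cfg.n_scenarios, size=cfg.n_unsafe, replace=False))
        order = list(rng.permutation(cfg.n_scenarios))
        if order[0] in unsafe:
            safe_positions = [i for i, s in enumerate(order) if s not in unsafe]
            j = int(rng.choice(safe_positions))
            order[0], order[j] = order[j], order[0]
        for k, s in enumerate(order):
            rows.append({
                "participant_id": pid,
                "scenario_id": s + 1,
                "condition": "unsafe" if s in unsafe else "safe",
                "order_index": k + 1,
            })
    return pd.DataFrame(rows)


def _prescriptions(cfg: GeneratorConfig, rng: np.random.Generator,
                   scenario_id: int, condition: str, w: float) -> list[dict]:
    adv = cfg.advice
    out = []
    for drug in cgio.DRUGS:
        ref = adv.reference_doses[drug][scenario_id - 1]
        initial = max(0.0, rng.normal(ref, adv.baseline_sd[drug]))
        if condition == "safe":
            ai = ref * rng.uniform(*adv.safe_advice_range)
        else:
            factor = (adv.unsafe_over_factor if scenario_id % 2 == 0
                      else adv.unsafe_under_factor)
            ai = ref * factor
        final = max(0.0, initial + w * (ai - initial)
                    + rng.normal(0.0, adv.post_noise_sd[drug]))
        out.append({"drug": drug, "initial_dose": initial,
                    "final_dose": final, "ai_dose": ai})
    return out


def _ratings(cfg: GeneratorConfig, rng: np.random.Generator) -> dict:
    vals = {}
    for col, mean in zip(cgio.RATING_COLUMNS, cfg.rating_mean):
        vals[col] = int(np.clip(np.round(rng.normal(mean, cfg.rating_sd)), 0, 4))
    return vals


# --------------------------------------------------------------------------- #
# Top level


def generate_experiment(
    config: GeneratorConfig | None = None,
    out_dir: str | Path | None = None,
    realize: bool = True,
) -> SyntheticExperiment:
    """Generate a complete seeded experiment.

    With ``realize=False`` only the event-level plan is drawn (trial records,
    planted per-ROI fixation/blink counts and weights, no gaze or track
    streams) — useful for replicate studies of the statistical layer.  When
    ``out_dir`` is given, the standard CSV schemas plus ``roi_definitions.yaml``
    and ``ground_truth.json`` are written there.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    hierarchy = default_roi_hierarchy()
    root = np.random.SeedSequence(cfg.seed)
    ss_design, ss_trials = root.spawn(2)
    design_rng = np.random.default_rng(ss_design)
    design = _assign_design(cfg, design_rng)

    exp = SyntheticExperiment(config=cfg, hierarchy=hierarchy, trials=pd.DataFrame())
    trial_rows = []
    ratings_by_pid: dict[str, dict] = {}
    seniority_by_pid: dict[str, str] = {}
    profile_by_pid: dict[str, dict] = {}
    trial_streams = ss_trials.spawn(len(design))
    leaves = sorted(cfg.attention_weights)

    for i, rec in enumerate(design.itertuples(index=False)):
        rng = np.random.default_rng(trial_streams[i])
        pid, sid, cond = rec.participant_id, rec.scenario_id, rec.condition
        if pid not in ratings_by_pid:
            ratings_by_pid[pid] = _ratings(cfg, rng)
            seniority_by_pid[pid] = str(
                rng.choice(["consultant", "SpR", "SHO"], p=[0.3, 0.4, 0.3]))
            # the participant's stable attention profile (safe-condition base)
            prof = rng.dirichlet(np.asarray(
                [cfg.attention_weights[k] for k in leaves])
                * cfg.participant_concentration)
            profile_by_pid[pid] = dict(zip(leaves, prof))

        duration_ms = max(60_000.0, rng.normal(
            cfg.trial_duration_s, cfg.trial_duration_sd_s) * 1000.0)
        weights_mean = cfg.condition_weights(cond, base=profile_by_pid[pid])
        w_trial = rng.dirichlet(np.asarray(
            [weights_mean[k] for k in leaves]) * cfg.trial_concentration)
        trial_weights = dict(zip(leaves, w_trial))

        plan = _plan_trial(rng, duration_ms, trial_weights, cfg)
        fix_counts, blink_counts = _plan_counts(plan)

        advice_w = float(rng.beta(*(cfg.advice.weight_safe if cond == "safe"
                                    else cfg.advice.weight_unsafe)))
        gt: dict = {
            "participant_id": pid, "scenario_id": int(sid), "condition": cond,
            "duration_ms": float(duration_ms),
            "advice_weight": advice_w,
            "weights": {k: float(v) for k, v in trial_weights.items()},
            "expected_weights": weights_mean,
            "fixation_counts": {k: int(v) for k, v in fix_counts.items()},
            "blink_counts": {k: int(v) for k, v in blink_counts.items()},
        }

        if realize:
            layout = _trial_layout(cfg, rng)
            times, off = _head_offsets(cfg, rng, duration_ms)
            gaze, events = _realize_gaze(cfg, rng, plan, layout, times, off,
                                         duration_ms)
            exp.gaze[(pid, sid)] = gaze
            exp.tracks[(pid, sid)] = _tracks_frame(layout, times, off)
            gt["events"] = events
        exp.ground_truth[(pid, sid)] = gt

        for rx in _prescriptions(cfg, rng, sid, cond, advice_w):
            trial_rows.append({
                "participant_id": pid, "scenario_id": sid, "condition": cond,
                "order_index": rec.order_index, **rx,
                **ratings_by_pid[pid], "seniority": seniority_by_pid[pid],
            })

    exp.trials = pd.DataFrame(trial_rows)[cgio.TRIAL_COLUMNS]
    if out_dir is not None:
        _write_experiment(exp, Path(out_dir))
    return exp


def _write_experiment(exp: SyntheticExperiment, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cgio.write_trials(exp.trials, out / "trials.csv")
    cgio.write_roi_definitions(exp.hierarchy, out / "roi_definitions.yaml")
    for (pid, sid), gaze in exp.gaze.items():
        cgio.write_gaze_stream(gaze, out / f"gaze_{pid}_s{sid}.csv")
    for (pid, sid), tracks in exp.tracks.items():
        cgio.write_roi_tracks(tracks, out / f"tracks_{pid}_s{sid}.csv")
    gt_json = {
        f"{pid}|s{sid}": gt for (pid, sid), gt in exp.ground_truth.items()
    }
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump({"config": _config_dict(exp.config), "trials": gt_json},
                  fh, indent=1)


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["xai_slots"] = [list(s) for s in cfg.xai_slots]
    return d


def generate_uniform_gaze(
    duration_s: float, sample_rate_hz: float, seed: int,
) -> pd.DataFrame:
    """Gaze samples i.i.d. uniform over the world-view at full confidence —
    the reference input under which every ROI's actual/chance ratio is 1."""
    if duration_s <= 0 or sample_rate_hz <= 0:
        raise ValueError("duration and sample rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) * (1000.0 / sample_rate_hz)
    return pd.DataFrame({
        "t_ms": t,
        "x": rng.uniform(0.0, 1.0, n),
        "y": rng.uniform(0.0, 1.0, n),
        "confidence": np.ones(n),
    })
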