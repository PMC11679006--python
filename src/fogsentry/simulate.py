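"""Synthetic two-foot plantar-pressure trials with ground-truth annotations.

The simulator emulates the study protocol: a participant stands briefly,
then walks a path with turns and one mid-trial standing bout, freezing
episodes are injected into the walking portions.  It produces the same
100 Hz per-foot force + COP traces the pipeline consumes, with every
regime known exactly, so it grounds every downstream test.

Gait model (deliberately simple, not biomechanically validated):

* alternating single support driven by a continuous gait phase; the stance
  foot carries essentially all load while its AP COP progresses heel to
  toe; the swing foot keeps a small residual force (~2% of the total, below
  the 5% validity rule); load hand-overs are linear crossfades across the
  double-support fraction of the cycle (~0.1 s);
* pre-FOG precursor: over the 2 s before an onset, cadence inflates and AP
  excursion shrinks, both linearly ramped (festination-like faster, smaller
  steps) — a modelling choice that makes the target class carry signal, not
  a claim about physiology;
* trembling FOG: both feet loaded, AP/ML COP oscillating at the configured
  tremble frequency with no effective stepping;
* akinetic FOG: both feet loaded, COP static apart from noise;
* Gaussian noise on forces and COP throughout.

All randomness flows from one root seed through named substreams, so every
trial and cohort is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    Dataset,
    EventInterval,
    EventKind,
    FootTrack,
    GridTrack,
    ParticipantRecord,
    TrialRecord,
)

__all__ = ["SimConfig", "SimTruth", "simulate_trial", "simulate_cohort", "emit_grid"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate a 60 s freeze-inducing trial."""

    fs: float = 100.0
    duration: float = 60.0            # s
    cadence: float = 1.8              # steps/s, both feet combined
    stance_ratio: float = 0.6         # stance fraction of the per-foot cycle
    ap_excursion: float = 160.0       # heel-to-toe COP travel per stance, mm
    ml_sway: float = 8.0              # ML COP oscillation amplitude, mm
    tremble_freq: float = 6.0         # Hz, trembling FOG oscillation, in [3, 8]
    tremble_amp: float = 12.0         # mm
    episode_rate: float = 1.5         # expected FOG episodes per trial (Poisson)
    episode_duration_log_mu: float = float(np.log(2.0))   # log-normal, s
    episode_duration_log_sigma: float = 0.7
    episode_duration_min: float = 0.8
    episode_duration_max: float = 10.0
    prefog: float = 2.0               # precursor horizon before onset, s
    prefog_cadence_factor: float = 2.0
    prefog_excursion_factor: float = 0.25
    prefog_ramp: float = 0.5          # s to reach full precursor effect
    p_trembling: float = 0.7          # phenotype mix; remainder akinetic
    n_turns: int = 2
    turn_duration: float = 2.0        # s
    initial_stand: float = 2.0        # s
    mid_stand_duration: float = 2.0   # s
    body_force: float = 1000.0        # arbitrary linear units
    swing_residual: float = 0.02      # swing-foot force fraction of body force
    force_noise_sd: float = 8.0
    cop_noise_sd: float = 1.0         # mm

    def __post_init__(self) -> None:
        if not 3.0 <= self.tremble_freq <= 8.0:
            raise ValueError("tremble_freq must lie in [3, 8] Hz")
        for name in ("episode_rate", "tremble_amp", "ap_excursion", "ml_sway",
                     "force_noise_sd", "cop_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted next to the trial: events, phenotypes, regimes."""

    events: list[EventInterval]
    phenotypes: list[str]             # per FOG episode, in onset order
    segments: list[tuple[str, float, float]]  # regime tag, start, end


_WALK, _STAND, _TURN, _TREMBLE, _AKINETIC = range(5)


def _fixed_schedule(cfg: SimConfig, rng: np.random.Generator):
    """Turn and stand intervals, jittered ~N(0, 0.5 s) around fixed anchors."""
    segs = [("STAND", 0.0, cfg.initial_stand)]
    anchors = []
    for i in range(cfg.n_turns):
        frac = 0.25 + 0.3 * i
        anchors.append(("TURN", frac * cfg.duration, cfg.turn_duration))
    anchors.append(("STAND", 0.85 * cfg.duration, cfg.mid_stand_duration))
    for kind, center, dur in anchors:
        start = center + rng.normal(0.0, 0.5)
        start = float(np.clip(start, cfg.initial_stand + 2.0, cfg.duration - dur - 2.0))
        segs.append((kind, start, start + dur))
    segs = sorted(segs, key=lambda s: s[1])
    for (_, _, e0), (_, s1, _) in zip(segs, segs[1:]):
        if s1 < e0:
            raise ValueError("infeasible schedule: overlapping turn/stand segments")
    return segs


def _place_episodes(cfg: SimConfig, rng: np.random.Generator,
                    schedule, min_episodes: int):
    """FOG (onset, duration, phenotype), rejection-sampled into clean walking."""
    count = max(int(rng.poisson(cfg.episode_rate)), min_episodes)
    blocked = [
        (s - cfg.prefog - 1.0, e + 1.5) for _, s, e in schedule
    ]
    placed: list[tuple[float, float]] = []
    episodes = []
    for _ in range(count):
        dur = float(
            np.clip(
                rng.lognormal(cfg.episode_duration_log_mu, cfg.episode_duration_log_sigma),
                cfg.episode_duration_min,
                cfg.episode_duration_max,
            )
        )
        lo = cfg.initial_stand + cfg.prefog + 1.5
        hi = cfg.duration - dur - 1.5
        if hi <= lo:
            continue
        for _attempt in range(200):
            onset = float(rng.uniform(lo, hi))
            span = (onset - cfg.prefog - 1.0, onset + dur + 1.5)
            clash = any(span[0] < e and span[1] > s for s, e in blocked)
            clash |= any(span[0] < e and span[1] > s for s, e in placed)
            if not clash:
                placed.append(span)
                phen = "trembling" if rng.random() < cfg.p_trembling else "akinetic"
                episodes.append((onset, dur, phen))
                break
    return sorted(episodes)


def simulate_trial(
    cfg: SimConfig,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str = "SIM",
    trial_id: str = "T01",
    min_episodes: int = 0,
) -> tuple[TrialRecord, SimTruth]:
    """Generate one trial; identical (cfg, seed) gives a bit-identical trial."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_sched, rng_ep, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    schedule = _fixed_schedule(cfg, rng_sched)
    episodes = _place_episodes(cfg, rng_ep, schedule, min_episodes)

    regime = np.full(n, _WALK, dtype=np.int8)
    for kind, s, e in schedule:
        code = _STAND if kind == "STAND" else _TURN
        regime[(t >= s) & (t < e)] = code
    for onset, dur, phen in episodes:
        code = _TREMBLE if phen == "trembling" else _AKINETIC
        regime[(t >= onset) & (t <= onset + dur)] = code

    stepping = (regime == _WALK) | (regime == _TURN)

    # pre-FOG ramps: cadence up, AP excursion down, linear over the horizon
    cad_factor = np.ones(n)
    exc_factor = np.ones(n)
    for onset, _dur, _phen in episodes:
        m = (t >= onset - cfg.prefog) & (t < onset)
        ramp = np.clip(
            (t[m] - (onset - cfg.prefog)) / max(cfg.prefog_ramp, 1e-9), 0.0, 1.0
        )
        cad_factor[m] = 1.0 + (cfg.prefog_cadence_factor - 1.0) * ramp
        exc_factor[m] = 1.0 + (cfg.prefog_excursion_factor - 1.0) * ramp

    # continuous per-foot gait phase (cycles); frozen while not stepping
    cycle_freq = np.where(stepping, cfg.cadence * cad_factor / 2.0, 0.0)
    phase = np.cumsum(cycle_freq) / cfg.fs

    u_l = np.mod(phase, 1.0)
    u_r = np.mod(phase + 0.5, 1.0)
    sr = cfg.stance_ratio
    ds = max(sr - 0.5, 0.05)  # double-support fraction of the cycle (~0.1 s)

    def load_of(u):
        return np.clip(
            np.where(
                u < ds, u / ds,
                np.where(u < sr - ds, 1.0,
                         np.where(u < sr, (sr - u) / ds, 0.0)),
            ),
            0.0, 1.0,
        )

    load_l = load_of(u_l)
    load_r = load_of(u_r)
    # normalize shares while stepping; both feet down otherwise
    tot = load_l + load_r
    with np.errstate(invalid="ignore", divide="ignore"):
        share_l = np.where(stepping & (tot > 0), load_l / np.maximum(tot, 1e-9), 0.5)
    share_r = np.where(stepping, 1.0 - share_l, 0.5)

    def stance_ap(u):
        progress = np.clip(u / cfg.stance_ratio, 0.0, 1.0)
        return cfg.ap_excursion * exc_factor * (progress - 0.5)

    ap_l = stance_ap(u_l)
    ap_r = stance_ap(u_r)
    ml_l = cfg.ml_sway * np.sin(2 * np.pi * u_l)
    ml_r = cfg.ml_sway * np.sin(2 * np.pi * u_r)

    # freezing regimes override the stepping COP
    trembling = regime == _TREMBLE
    akinetic = regime == _AKINETIC
    osc_ap = cfg.tremble_amp * np.sin(2 * np.pi * cfg.tremble_freq * t)
    osc_ml = 0.6 * cfg.tremble_amp * np.sin(2 * np.pi * cfg.tremble_freq * t + np.pi / 3)
    for ap, ml, foot_sign in ((ap_l, ml_l, 1.0), (ap_r, ml_r, -1.0)):
        ap[trembling] = foot_sign * osc_ap[trembling]
        ml[trembling] = foot_sign * osc_ml[trembling]
        ap[akinetic] = 0.0
        ml[akinetic] = 0.0
        ap[regime == _STAND] = 0.0
        ml[regime == _STAND] = 0.0

    res = cfg.swing_residual
    force_l = cfg.body_force * (share_l * (1 - res) + res)
    force_r = cfg.body_force * (share_r * (1 - res) + res)
    force_l = np.maximum(force_l + rng_noise.normal(0, cfg.force_noise_sd, n), 0.0)
    force_r = np.maximum(force_r + rng_noise.normal(0, cfg.force_noise_sd, n), 0.0)
    ap_l = ap_l + rng_noise.normal(0, cfg.cop_noise_sd, n)
    ap_r = ap_r + rng_noise.normal(0, cfg.cop_noise_sd, n)
    ml_l = ml_l + rng_noise.normal(0, cfg.cop_noise_sd, n)
    ml_r = ml_r + rng_noise.normal(0, cfg.cop_noise_sd, n)

    valid_l = force_l > 0.05 * (force_l + force_r)
    valid_r = force_r > 0.05 * (force_l + force_r)

    events = [
        EventInterval(start=s, end=e, kind=EventKind(kind)) for kind, s, e in schedule
    ] + [
        EventInterval(start=onset, end=onset + dur, kind=EventKind.FOG)
        for onset, dur, _ in episodes
    ]

    trial = TrialRecord(
        participant_id=participant_id,
        trial_id=trial_id,
        fs=cfg.fs,
        left=FootTrack(times=t, force=force_l, cop_x=ml_l, cop_y=ap_l, valid=valid_l),
        right=FootTrack(times=t, force=force_r, cop_x=ml_r, cop_y=ap_r, valid=valid_r),
        events=events,
    )
    truth = SimTruth(
        events=trial.events,
        phenotypes=[phen for _, _, phen in episodes],
        segments=[("WALK", 0.0, cfg.duration)]
        + [(k, s, e) for k, s, e in schedule]
        + [(phen.upper(), onset, onset + dur) for onset, dur, phen in episodes],
    )
    return trial, truth


def _jitter_config(cfg: SimConfig, rng: np.random.Generator, freezer: bool) -> SimConfig:
    """Per-participant gait variability around the template config."""
    return replace(
        cfg,
        cadence=cfg.cadence * rng.uniform(0.9, 1.1),
        ap_excursion=cfg.ap_excursion * rng.uniform(0.85, 1.15),
        ml_sway=cfg.ml_sway * rng.uniform(0.8, 1.2),
        tremble_freq=float(np.clip(rng.uniform(4.5, 7.5), 3.0, 8.0)),
        tremble_amp=cfg.tremble_amp * rng.uniform(0.8, 1.2),
        episode_rate=cfg.episode_rate * rng.uniform(0.7, 1.3) if freezer else 0.0,
    )


def simulate_cohort(
    n_freezers: int,
    n_nonfreezers: int,
    trials_per_participant: int,
    cfg: SimConfig | None = None,
    seed: int = 0,
) -> tuple[Dataset, dict[tuple[str, str], SimTruth]]:
    """A synthetic cohort: freezers first, then non-freezers (episode rate 0).

    Per-participant gait parameters are jittered around the template; every
    freezer is guaranteed at least one FOG episode overall.  Returns the
    Dataset plus the per-trial ground truth keyed by (participant, trial).
    """
    cfg = cfg or SimConfig()
    root = np.random.SeedSequence(seed)
    truths: dict[tuple[str, str], SimTruth] = {}
    participants = []
    part_seeds = root.spawn(n_freezers + n_nonfreezers)
    for i, pss in enumerate(part_seeds):
        freezer = i < n_freezers
        pid = f"P{i + 1:02d}"
        streams = pss.spawn(trials_per_participant + 1)
        rng_p = np.random.default_rng(streams[0])
        pcfg = _jitter_config(cfg, rng_p, freezer)
        trials = []
        for j in range(trials_per_participant):
            tid = f"T{j + 1:02d}"
            trial, truth = simulate_trial(pcfg, streams[j + 1], pid, tid)
            trials.append(trial)
            truths[(pid, tid)] = truth
        if freezer and not any(tr.fog_events() for tr in trials):
            trial, truth = simulate_trial(pcfg, streams[1], pid, "T01", min_episodes=1)
            trials[0] = trial
            truths[(pid, "T01")] = truth
        participants.append(
            ParticipantRecord(
                id=pid,
                age=float(np.round(rng_p.normal(73, 6))),
                years_since_diagnosis=float(np.round(np.clip(rng_p.normal(10, 5), 1, 30))),
                nfogq=float(np.round(rng_p.uniform(10, 28))) if freezer else float(np.round(rng_p.uniform(0, 10))),
                updrs3=float(np.round(rng_p.uniform(8, 30))),
                froze=any(tr.fog_events() for tr in trials),
                trials=trials,
            )
        )
    return Dataset(name=f"synthetic-{n_freezers}f{n_nonfreezers}n", participants=participants), truths


def emit_grid(
    trial: TrialRecord, nx: int = 4, ny: int = 8, margin: float = 10.0
) -> TrialRecord:
    """Re-express a signal-form trial on a small sensel grid.

    Each frame's force is spread over the four sensels bracketing the COP
    with bilinear weights, so the pressure-weighted centroid reproduces the
    intended COP exactly (well under 0.1 mm).  Zero-force frames map to
    all-zero sensels; a COP outside the grid hull is an error.
    """
    grids = []
    for track in (trial.left, trial.right):
        if not isinstance(track, FootTrack):
            raise TypeError("emit_grid expects a signal-form trial")
        gx = np.linspace(track.cop_x.min() - margin, track.cop_x.max() + margin, nx)
        gy = np.linspace(track.cop_y.min() - margin, track.cop_y.max() + margin, ny)
        sx, sy = (a.ravel() for a in np.meshgrid(gx, gy, indexing="ij"))
        n = len(track)
        pressure = np.zeros((n, nx * ny))
        cx, cy, force = track.cop_x, track.cop_y, track.force
        if nx > 1 and np.any((cx < gx[0]) | (cx > gx[-1])):
            raise ValueError("emit_grid: COP outside sensel hull")
        if ny > 1 and np.any((cy < gy[0]) | (cy > gy[-1])):
            raise ValueError("emit_grid: COP outside sensel hull")

        def bracket(vals, grid):
            # single-point axis: all mass on that sensel (COP forced onto it)
            if len(grid) < 2:
                return np.zeros(n, dtype=int), np.zeros(n)
            i = np.clip(np.searchsorted(grid, vals) - 1, 0, len(grid) - 2)
            return i, (vals - grid[i]) / (grid[i + 1] - grid[i])

        ix, wx = bracket(cx, gx)
        iy, wy = bracket(cy, gy)
        rows = np.arange(n)
        for dx, dy, wgt in (
            (0, 0, (1 - wx) * (1 - wy)),
            (0, 1, (1 - wx) * wy),
            (1, 0, wx * (1 - wy)),
            (1, 1, wx * wy),
        ):
            cols = np.minimum(ix + dx, nx - 1) * ny + np.minimum(iy + dy, ny - 1)
            np.add.at(pressure, (rows, cols), force * wgt)
        grids.append(GridTrack(times=track.times, sensel_x=sx, sensel_y=sy, pressure=pressure))
    return TrialRecord(
        participant_id=trial.participant_id,
        trial_id=trial.trial_id,
        fs=trial.fs,
        left=grids[0],
        right=grids[1],
        events=list(trial.events),
    )
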