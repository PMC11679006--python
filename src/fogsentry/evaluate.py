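"""Episode-level evaluation: MTDs, target zones, outcomes and cross-validation.

A model trigger decision (MTD) fires at the end of the third (and every
later) window of a run of consecutive target-class windows.  A 2.5 s no-cue
interval then thins the candidates: an MTD is suppressed if it falls less
than 2.5 s after the previous kept MTD — mirroring a cueing device that
stays silent while a cue is already playing.

Each FOG episode owns an MTD target zone running from up to 6 s before its
onset (the prediction zone) through the episode's end.  The zone start is
pushed later by events inside the initial 6 s: other FOG episodes (zone
starts at their end) and turn-to-walk or stand-to-walk transitions (zone
starts 1 s after their end), and is clipped to the trial start.  A kept MTD
inside a zone is a true positive matched to that episode; outside all zones
it is ignored if it falls within a standing interval or the first second of
walking after one (gait initiation), and otherwise counts as a false
positive.

Episode outcomes: *predicted* if a matched true positive precedes onset,
*detected* if one falls between onset and episode end, *identified* if
either; the identification delay (ID) is the first true positive's instant
minus onset — negative means prediction.

Cross-validation is leave-one-freezer-out: each participant who froze is
held out once, participants who never froze stay in every training set.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .config import RunConfig
from .core import Dataset, EventInterval, EventKind, TrialRecord
from .features import FEATURE_NAMES, Window, feature_matrix
from .rusboost import Ensemble, fit_rusboost, predict_class, predict_score

__all__ = [
    "MtdStatus",
    "MtdEvent",
    "TargetZone",
    "EpisodeOutcome",
    "MetricsReport",
    "detect_mtds",
    "apply_no_cue",
    "build_target_zones",
    "classify_mtds",
    "episode_outcomes",
    "window_metrics",
    "id_histogram",
    "evaluate_trial",
    "lofo_crossval",
]

_EPS = 1e-9


class MtdStatus(str, Enum):
    CANDIDATE = "CANDIDATE"
    TP = "TP"
    FP = "FP"
    SUPPRESSED_NOCUE = "SUPPRESSED_NOCUE"
    IGNORED_STAND_OR_INIT = "IGNORED_STAND_OR_INIT"


@dataclass
class MtdEvent:
    instant: float
    status: MtdStatus = MtdStatus.CANDIDATE
    matched_episode: int | None = None


@dataclass(frozen=True)
class TargetZone:
    episode: int
    zone_start: float
    onset: float
    zone_end: float

    def __post_init__(self) -> None:
        assert self.zone_start <= self.onset + _EPS <= self.zone_end + _EPS
        assert self.onset - self.zone_start <= 6.0 + _EPS

    def contains(self, t: float) -> bool:
        return self.zone_start - _EPS <= t <= self.zone_end + _EPS


@dataclass
class EpisodeOutcome:
    episode: int
    identified: bool
    predicted: bool
    detected: bool
    id_delay: float | None


@dataclass
class MetricsReport:
    """Pooled window- and episode-level evaluation results."""

    sensitivity: float | None
    specificity: float | None
    pct_identified: float
    pct_predicted: float
    pct_detected: float
    mean_id: float | None
    fp_rate: float
    n_windows: int
    n_episodes: int

    def __post_init__(self) -> None:
        hi = max(self.pct_predicted, self.pct_detected)
        assert hi - _EPS <= self.pct_identified <= self.pct_predicted + self.pct_detected + _EPS

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# MTD mechanics


def detect_mtds(
    window_ends: np.ndarray, is_target: np.ndarray, run_length: int = 3
) -> list[MtdEvent]:
    """Candidate MTDs: the end of the 3rd and every later window of a run."""
    window_ends = np.asarray(window_ends, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    out = []
    run = 0
    for t, tgt in zip(window_ends, is_target):
        run = run + 1 if tgt else 0
        if run >= run_length:
            out.append(MtdEvent(instant=float(t)))
    return out


def apply_no_cue(candidates: list[MtdEvent], interval: float = 2.5) -> list[MtdEvent]:
    """Greedy refractory thinning: suppress MTDs < interval after a kept one."""
    last_kept = -np.inf
    out = []
    for cand in sorted(candidates, key=lambda c: c.instant):
        if cand.instant - last_kept < interval - _EPS:
            out.append(MtdEvent(cand.instant, MtdStatus.SUPPRESSED_NOCUE))
        else:
            out.append(MtdEvent(cand.instant, MtdStatus.CANDIDATE))
            last_kept = cand.instant
    return out


def build_target_zones(
    events: list[EventInterval],
    trial_start: float = 0.0,
    zone_length: float = 6.0,
    post_event_delay: float = 1.0,
) -> list[TargetZone]:
    """One MTD target zone per FOG episode.

    ``zone_start = max(onset - zone_length, trial_start, end of the last
    overlapping turn/stand + post_event_delay, end of the last overlapping
    FOG episode)``, clipped to not exceed the onset; ``zone_end`` is the
    episode's end.
    """
    fogs = sorted(
        (e for e in events if e.kind is EventKind.FOG), key=lambda e: e.start
    )
    others = [e for e in events if e.kind is not EventKind.FOG]
    zones = []
    for i, ep in enumerate(fogs):
        init = ep.start - zone_length
        start = max(init, trial_start)
        for ev in others:
            if ev.start < ep.start and ev.end > init:
                start = max(start, min(ev.end + post_event_delay, ep.start))
        for other_ep in fogs:
            if other_ep is not ep and other_ep.start < ep.start and other_ep.end > init:
                start = max(start, min(other_ep.end, ep.start))
        zones.append(TargetZone(episode=i, zone_start=start, onset=ep.start, zone_end=ep.end))
    return zones


def classify_mtds(
    mtds: list[MtdEvent],
    zones: list[TargetZone],
    stand_events: list[EventInterval],
    gait_init: float = 1.0,
) -> list[MtdEvent]:
    """Assign TP / FP / IGNORED status to the kept MTDs.

    Suppressed MTDs pass through unchanged.  An MTD inside any zone becomes
    a TP matched to the earliest containing episode; outside all zones it is
    ignored during standing or the first ``gait_init`` seconds of walking
    after standing, else it is an FP.
    """
    out = []
    for m in mtds:
        if m.status is MtdStatus.SUPPRESSED_NOCUE:
            out.append(m)
            continue
        zone = next((z for z in zones if z.contains(m.instant)), None)
        if zone is not None:
            out.append(MtdEvent(m.instant, MtdStatus.TP, zone.episode))
        elif any(
            s.start - _EPS <= m.instant <= s.end + gait_init + _EPS for s in stand_events
        ):
            out.append(MtdEvent(m.instant, MtdStatus.IGNORED_STAND_OR_INIT))
        else:
            out.append(MtdEvent(m.instant, MtdStatus.FP))
    return out


def episode_outcomes(
    zones: list[TargetZone], mtds: list[MtdEvent]
) -> list[EpisodeOutcome]:
    """Per-episode prediction/detection outcome from the matched TPs."""
    out = []
    for z in zones:
        tps = sorted(
            (m.instant for m in mtds if m.status is MtdStatus.TP and m.matched_episode == z.episode)
        )
        predicted = any(t < z.onset - _EPS for t in tps)
        detected = any(z.onset - _EPS <= t <= z.zone_end + _EPS for t in tps)
        identified = predicted or detected
        out.append(
            EpisodeOutcome(
                episode=z.episode,
                identified=identified,
                predicted=predicted,
                detected=detected,
                id_delay=(tps[0] - z.onset) if identified else None,
            )
        )
    return out


def window_metrics(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[float | None, float | None]:
    """Pooled window sensitivity and specificity in percent.

    A metric whose class is absent from the truth vector is None.
    """
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    pos = truth.sum()
    neg = (~truth).sum()
    sens = float(100.0 * (predicted & truth).sum() / pos) if pos else None
    spec = float(100.0 * (~predicted & ~truth).sum() / neg) if neg else None
    return sens, spec


def id_histogram(
    id_delays: list[float], bin_width: float = 1.0, start: float = -6.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of first-identification delays.

    Fixed 1 s bins starting at ``start``; extends right as far as the data
    require.  Returns ``(edges, fractions)`` with fractions summing to 1.
    """
    ids = [d for d in id_delays if d is not None]
    if not ids:
        raise ValueError("id_histogram: no identified episodes")
    hi = max(max(ids) + _EPS, start + bin_width)
    n_bins = int(np.ceil((hi - start) / bin_width))
    edges = start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(ids, bins=edges)
    return edges, counts / counts.sum()


# ---------------------------------------------------------------------------
# trial- and dataset-level evaluation


@dataclass
class TrialEvaluation:
    trial_id: str
    windows: list[Window]
    truth: np.ndarray
    predicted: np.ndarray
    mtds: list[MtdEvent]
    zones: list[TargetZone]
    outcomes: list[EpisodeOutcome]

    @property
    def n_fp(self) -> int:
        return sum(m.status is MtdStatus.FP for m in self.mtds)


def evaluate_trial(
    trial: TrialRecord,
    windows: list[Window],
    predicted: np.ndarray,
    truth: np.ndarray,
    cfg: RunConfig,
) -> TrialEvaluation:
    """Run the full MTD pipeline for one trial's window classifications."""
    ends = np.array([w.end for w in windows])
    candidates = detect_mtds(ends, predicted, cfg.mtd_run_length)
    thinned = apply_no_cue(candidates, cfg.no_cue)
    zones = build_target_zones(
        trial.events, 0.0, cfg.target_zone, cfg.post_event_delay
    )
    stands = trial.events_of(EventKind.STAND)
    mtds = classify_mtds(thinned, zones, stands, cfg.gait_init)
    outcomes = episode_outcomes(zones, mtds)
    return TrialEvaluation(
        trial_id=trial.trial_id,
        windows=windows,
        truth=truth,
        predicted=np.asarray(predicted, bool),
        mtds=mtds,
        zones=zones,
        outcomes=outcomes,
    )


@dataclass
class FoldResult:
    held_out: str
    ensemble: Ensemble
    trials: list[TrialEvaluation]
    fp_per_trial: float


def _pool_metrics(folds: list[FoldResult]) -> MetricsReport:
    truth = np.concatenate([t.truth for f in folds for t in f.trials])
    pred = np.concatenate([t.predicted for f in folds for t in f.trials])
    sens, spec = window_metrics(pred, truth)
    outcomes = [o for f in folds for t in f.trials for o in t.outcomes]
    n_ep = len(outcomes)
    ids = [o.id_delay for o in outcomes if o.identified]
    fp_rates = [f.fp_per_trial for f in folds]
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        pct_identified=100.0 * sum(o.identified for o in outcomes) / n_ep if n_ep else 0.0,
        pct_predicted=100.0 * sum(o.predicted for o in outcomes) / n_ep if n_ep else 0.0,
        pct_detected=100.0 * sum(o.detected for o in outcomes) / n_ep if n_ep else 0.0,
        mean_id=float(np.mean(ids)) if ids else None,
        fp_rate=float(np.mean(fp_rates)) if fp_rates else 0.0,
        n_windows=len(truth),
        n_episodes=n_ep,
    )


def lofo_crossval(
    dataset: Dataset,
    cfg: RunConfig | None = None,
    seed: int = 0,
    features_cache: dict | None = None,
) -> tuple[list[FoldResult], MetricsReport]:
    """Leave-one-freezer-out cross-validation over a dataset.

    One fold per freezer: the ensemble trains on every other participant
    (freezers and all non-freezers) and is evaluated on the held-out
    freezer's windows and episodes.  Windows and episodes are pooled across
    folds for the report; the false-positive rate is FPs per trial averaged
    over held-out participants.  ``features_cache`` maps
    ``(participant_id, trial_id)`` to precomputed feature tuples and is
    filled on the fly, so repeated calls (e.g. over dataset modifications)
    reuse extraction.
    """
    cfg = cfg or RunConfig()
    freezers = sorted(p.id for p in dataset.freezers())
    if len(freezers) < 2:
        raise ValueError("lofo_crossval: need at least 2 freezers")
    cache = features_cache if features_cache is not None else {}

    def trial_features(p, trial):
        key = (p.id, trial.trial_id)
        if key not in cache:
            cache[key] = feature_matrix(trial, cfg)
        return cache[key]

    folds = []
    for k, held in enumerate(freezers):
        X_parts, y_parts = [], []
        for p in dataset.participants:
            if p.id == held:
                continue
            for trial in p.trials:
                _, X, y, _ = trial_features(p, trial)
                X_parts.append(X)
                y_parts.append(y)
        ens = fit_rusboost(
            np.vstack(X_parts),
            np.concatenate(y_parts),
            n_learners=cfg.n_learners,
            max_splits=cfg.max_splits,
            sampling_ratio=cfg.sampling_ratio,
            learn_rate=cfg.learn_rate,
            seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] & 0x7FFFFFFF),
            feature_names=FEATURE_NAMES,
        )
        p = dataset.get(held)
        evals = []
        for trial in p.trials:
            windows, X, y, _ = trial_features(p, trial)
            pred = predict_class(predict_score(ens, X), cfg.score_threshold)
            evals.append(evaluate_trial(trial, windows, pred, y, cfg))
        n_trials = len(p.trials)
        fp_per_trial = sum(e.n_fp for e in evals) / n_trials if n_trials else 0.0
        folds.append(
            FoldResult(held_out=held, ensemble=ens, trials=evals, fp_per_trial=fp_per_trial)
        )
    return folds, _pool_metrics(folds)
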