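"""Synthetic generators for every pipeline input, with ground truth.

Four generators cover the study's data surfaces:

* :func:`make_design` -- randomized three-night crossover assignments over
  the six condition orderings.
* :func:`make_schedule` / :func:`simulate_night` -- playback schedules and
  1 Hz noise/heart-rate traces for a single exposure night, with annotated
  event and heart-rate-surge onsets.
* :func:`simulate_cohort` -- participant x period outcome table under an
  additive crossover model (condition + period + participant intercept +
  residual).
* :func:`simulate_npx` -- a log2-scale protein x sample matrix with a known
  responder-associated protein subset.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace_io import NightTrace

CONDITIONS = ("control", "noise30", "noise60")

#: The six condition orderings used for randomization.
SEQUENCES = (
    ("control", "noise30", "noise60"),
    ("control", "noise60", "noise30"),
    ("noise30", "control", "noise60"),
    ("noise30", "noise60", "control"),
    ("noise60", "control", "noise30"),
    ("noise60", "noise30", "control"),
)

#: Playback constants: calibration tone, silent lead-in, event length (s).
TONE_DURATION = 30
LEAD_IN_SILENCE = 2400
EVENT_DURATION = 75
EVENT_COUNTS = {"control": 0, "noise30": 30, "noise60": 60}
INTER_EVENT_GAPS = {"noise30": 700, "noise60": 575}


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )


@dataclass(frozen=True)
class StudyDesign:
    """Crossover assignment of participants to condition orderings."""

    n_participants: int
    sequences: tuple = SEQUENCES
    assignments: np.ndarray = None  # sequence index per participant
    period_count: int = 3

    @property
    def participants(self) -> list[str]:
        return [f"p{i + 1:03d}" for i in range(self.n_participants)]

    def condition(self, participant_index: int, period: int) -> str:
        """Condition for a participant (0-based) in a period (1-based)."""
        return self.sequences[self.assignments[participant_index]][period - 1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant": pid,
                "sequence": self.assignments[i],
                "period": period,
                "condition": self.condition(i, period),
            }
            for i, pid in enumerate(self.participants)
            for period in range(1, self.period_count + 1)
        ]
        return pd.DataFrame(rows)


def make_design(n_participants: int = 74, seed: int | None = None) -> StudyDesign:
    """Randomly assign participants to the six orderings, balanced to ±1.

    Each ordering is used either ``floor(n/6)`` or ``ceil(n/6)`` times; which
    orderings receive the extra participant is randomized, as is the mapping
    of participants to orderings.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if n_participants < 6:
        raise ValueError("need at least 6 participants to use all 6 sequences")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_participants, 6)
    pool = np.repeat(np.arange(6), base)
    if extra:
        pool = np.concatenate([pool, rng.choice(6, size=extra, replace=False)])
    rng.shuffle(pool)
    return StudyDesign(n_participants=n_participants, assignments=pool)


@dataclass(frozen=True)
class PlaybackSchedule:
    """Timing of one night's playback file.

    The night opens with a calibration tone and a silent lead-in; events of
    ``event_duration`` seconds then alternate with silent gaps of
    ``inter_event_gap`` seconds (gap measured from event end to next onset).
    """

    condition: str
    tone_duration: int = TONE_DURATION
    lead_in_silence: int = LEAD_IN_SILENCE
    n_events: int = 0
    event_duration: int = EVENT_DURATION
    inter_event_gap: int = 0
    event_onsets: tuple = ()
    duration: int = 0

    def validate(self) -> None:
        onsets = np.asarray(self.event_onsets)
        assert len(onsets) == self.n_events
        if self.n_events:
            assert onsets[0] == self.tone_duration + self.lead_in_silence
            spacing = self.event_duration + self.inter_event_gap
            assert np.all(np.diff(onsets) == spacing)


# Control nights have no events, so their span is not derivable from the
# event arithmetic; default to the 30-event night's span so all three
# conditions cover a comparable sleep window.
def _noise30_span() -> int:
    n, gap = EVENT_COUNTS["noise30"], INTER_EVENT_GAPS["noise30"]
    return TONE_DURATION + LEAD_IN_SILENCE + n * EVENT_DURATION + (n - 1) * gap


def make_schedule(condition: str, control_duration: int | None = None) -> PlaybackSchedule:
    """Build the playback schedule for a condition.

    Total span is tone + lead-in + n*event_duration + (n-1)*gap, derived
    exactly from the printed constants. ``control_duration`` overrides the
    span of the event-free control night (default: the 30-event span).
    """
    _check_condition(condition)
    n = EVENT_COUNTS[condition]
    gap = INTER_EVENT_GAPS.get(condition, 0)
    first = TONE_DURATION + LEAD_IN_SILENCE
    if n == 0:
        duration = control_duration if control_duration is not None else _noise30_span()
        onsets: tuple = ()
    else:
        spacing = EVENT_DURATION + gap
        onsets = tuple(int(first + k * spacing) for k in range(n))
        duration = first + n * EVENT_DURATION + (n - 1) * gap
    sched = PlaybackSchedule(
        condition=condition,
        n_events=n,
        inter_event_gap=gap,
        event_onsets=onsets,
        duration=int(duration),
    )
    sched.validate()
    return sched


@dataclass
class TraceParams:
    """Acoustic and physiological parameters for one simulated night.

    ``response_probability`` is the per-peak chance of an event-locked
    heart-rate surge; pass the condition-specific value when simulating a
    particular night.
    """

    background_level: float = 30.7      # dB(A)
    background_jitter_sd: float = 1.5   # dB
    event_peak_level: float = 60.0      # dB(A)
    apex_width: int = 5                 # s of flat apex per event
    incidental_peak_rate: float = 3.0   # expected unintended peaks per night
    incidental_peak_level: float = 45.0  # dB(A)
    incidental_duration: int = 21       # s
    hr_baseline_start: float = 62.0     # bpm at lights-out
    hr_baseline_end: float = 54.0       # bpm at morning
    hr_noise_sd: float = 1.5            # bpm
    response_probability: float = 0.3
    response_amplitude: float = 8.0     # bpm
    response_duration: int = 30         # s
    seed: int | None = None

    def validate(self) -> None:
        if not self.event_peak_level > self.background_level + 10:
            raise ValueError("event_peak_level must exceed background by >10 dB")
        if self.apex_width < 4:
            raise ValueError("apex_width must be >= 4 (the detection run length)")
        if not 0.0 <= self.response_probability <= 1.0:
            raise ValueError("response_probability must be in [0, 1]")
        if self.incidental_peak_rate < 0:
            raise ValueError("incidental_peak_rate must be >= 0")


@dataclass
class NightTruth:
    """Ground-truth annotations for a simulated night."""

    event_onsets: np.ndarray
    incidental_onsets: np.ndarray
    surge_onsets: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [{"kind": "event", "onset_s": int(t)} for t in self.event_onsets]
            + [{"kind": "incidental", "onset_s": int(t)} for t in self.incidental_onsets]
            + [{"kind": "surge", "onset_s": int(t)} for t in self.surge_onsets]
        )
        return pd.DataFrame(rows, columns=["kind", "onset_s"])


@dataclass
class SimulatedNight:
    """A simulated night: the 1 Hz trace plus its ground truth."""

    trace: NightTrace
    truth: NightTruth
    schedule: PlaybackSchedule
    params: TraceParams


def _passby_profile(duration: int, apex_width: int) -> np.ndarray:
    """Normalized rise-apex-fall profile: raised-cosine shoulders around a
    flat apex of ``apex_width`` seconds, values in [0, 1]."""
    shoulder = (duration - apex_width) // 2
    apex = duration - 2 * shoulder
    up = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, shoulder + 1) / (shoulder + 1)))
    return np.concatenate([up, np.ones(apex), up[::-1]])


def simulate_night(
    schedule: PlaybackSchedule,
    params: TraceParams | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedNight:
    """Simulate 1 Hz noise and heart-rate traces over a schedule's span.

    Scheduled events are smooth pass-by bumps whose flat apex sits exactly at
    ``event_peak_level``; background jitter is attenuated inside event bumps
    so every apex sample strictly exceeds every non-event sample. Heart-rate
    surges start 0-9 s after a (scheduled or incidental) peak onset with
    probability ``response_probability``.
    """
    params = params or TraceParams()
    params.validate()
    if params.apex_width > schedule.event_duration:
        raise ValueError("apex_width cannot exceed event_duration")
    rng = rng if rng is not None else np.random.default_rng(params.seed)

    n = schedule.duration
    t = np.arange(n, dtype=np.int64)

    # intended events
    event_shape = np.zeros(n)
    profile = _passby_profile(schedule.event_duration, params.apex_width)
    for onset in schedule.event_onsets:
        event_shape[onset : onset + schedule.event_duration] = np.maximum(
            event_shape[onset : onset + schedule.event_duration], profile
        )

    # incidental (unintended) noise peaks, uniform over the quiet part of the
    # night, never overlapping an intended event
    n_incidental = rng.poisson(params.incidental_peak_rate)
    inc_profile = _passby_profile(params.incidental_duration, max(4, params.apex_width))
    incidental_onsets = []
    guard = schedule.event_duration + params.incidental_duration
    candidates = np.ones(n, dtype=bool)
    for onset in schedule.event_onsets:
        candidates[max(0, onset - guard) : onset + guard] = False
    candidates[n - params.incidental_duration :] = False
    free = np.flatnonzero(candidates)
    incidental_shape = np.zeros(n)
    if n_incidental and free.size:
        for onset in np.sort(rng.choice(free, size=min(n_incidental, free.size), replace=False)):
            incidental_onsets.append(int(onset))
            seg = slice(onset, onset + params.incidental_duration)
            incidental_shape[seg] = np.maximum(
                incidental_shape[seg],
                inc_profile * ((params.incidental_peak_level - params.background_level)
                               / (params.event_peak_level - params.background_level)),
            )

    bump = np.maximum(
        event_shape, incidental_shape
    ) * (params.event_peak_level - params.background_level)
    jitter = rng.normal(0.0, params.background_jitter_sd, size=n) * (1.0 - event_shape)
    noise_db = params.background_level + bump + jitter

    # heart rate: linear overnight decline + noise + event-locked surges
    hr = (
        params.hr_baseline_start
        + (params.hr_baseline_end - params.hr_baseline_start) * t / max(n - 1, 1)
        + rng.normal(0.0, params.hr_noise_sd, size=n)
    )
    surge_profile = _passby_profile(params.response_duration, 4) * params.response_amplitude
    surge_onsets = []
    all_peaks = sorted(list(schedule.event_onsets) + incidental_onsets)
    for onset in all_peaks:
        if rng.random() < params.response_probability:
            start = onset + int(rng.integers(0, 10))
            end = min(start + params.response_duration, n)
            if end > start:
                hr[start:end] += surge_profile[: end - start]
                surge_onsets.append(start)

    trace = NightTrace(t=t, noise_db=noise_db, hr_bpm=hr, condition=schedule.condition)
    truth = NightTruth(
        event_onsets=np.asarray(schedule.event_onsets, dtype=np.int64),
        incidental_onsets=np.asarray(incidental_onsets, dtype=np.int64),
        surge_onsets=np.asarray(surge_onsets, dtype=np.int64),
    )
    return SimulatedNight(trace=trace, truth=truth, schedule=schedule, params=params)


@dataclass
class CohortParams:
    """Generating parameters for the crossover outcome table.

    Defaults are calibrated to condition means of 9.35 / 8.19 / 7.73 % FMD
    and an intervention effect of 1.02 % on the post-intervention FMD change
    in the 60-event condition.
    """

    fmd_condition_means: dict = field(
        default_factory=lambda: {"control": 9.35, "noise30": 8.19, "noise60": 7.73}
    )
    fmd_participant_sd: float = 2.5
    fmd_residual_sd: float = 2.1
    period_effects: tuple = (0.0, 0.0, 0.0)
    vitc_effect: float = 1.02          # applied at noise60 to fmd_change_pct
    vitc_effects: dict | None = None   # optional per-condition override
    fmd_change_sd: float = 1.5
    n_vitc: int = 31
    relative_change: bool = False
    secondary_endpoints: dict = field(
        default_factory=lambda: {
            # name: (per-condition means in CONDITIONS order, residual sd)
            "hr_mean_bpm": ((58.0, 58.6, 59.23), 4.0),
            "hr_max_bpm": ((85.0, 85.57, 92.95), 8.0),
            "sleep_quality": ((7.0, 5.6, 5.2), 1.5),
        }
    )
    seed: int | None = None

    def validate(self) -> None:
        if abs(sum(self.period_effects)) > 1e-9:
            raise ValueError("period_effects must sum to 0 for identifiability")
        if set(self.fmd_condition_means) != set(CONDITIONS):
            raise ValueError(f"fmd_condition_means must cover {CONDITIONS}")

    def vitc_effect_for(self, condition: str) -> float:
        if self.vitc_effects is not None:
            return float(self.vitc_effects.get(condition, 0.0))
        return self.vitc_effect if condition == "noise60" else 0.0


def simulate_cohort(
    design: StudyDesign,
    params: CohortParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one row per participant-period under the additive model

    ``outcome = condition mean + period effect + participant intercept +
    residual``. The first ``n_vitc`` randomly chosen participants carry the
    intervention flag; their post-intervention FMD change is shifted by the
    condition-specific intervention effect.
    """
    params = params or CohortParams()
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed)

    n = design.n_participants
    intercepts = rng.normal(0.0, params.fmd_participant_sd, size=n)
    vitc_ids = set(rng.choice(n, size=min(params.n_vitc, n), replace=False).tolist())
    sec_intercepts = {
        name: rng.normal(0.0, sd / 2.0, size=n)
        for name, (_, sd) in params.secondary_endpoints.items()
    }

    rows = []
    for i, pid in enumerate(design.participants):
        vitc = int(i in vitc_ids)
        for period in range(1, design.period_count + 1):
            cond = design.condition(i, period)
            fmd = (
                params.fmd_condition_means[cond]
                + params.period_effects[period - 1]
                + intercepts[i]
                + rng.normal(0.0, params.fmd_residual_sd)
            )
            change = vitc * params.vitc_effect_for(cond) + rng.normal(
                0.0, params.fmd_change_sd
            )
            if params.relative_change and fmd != 0:
                change = 100.0 * change / fmd
            row = {
                "participant": pid,
                "period": period,
                "condition": cond,
                "fmd_pct": fmd,
                "vitc": vitc,
                "fmd_change_pct": change,
            }
            for name, (means, sd) in params.secondary_endpoints.items():
                row[name] = (
                    means[CONDITIONS.index(cond)]
                    + sec_intercepts[name][i]
                    + rng.normal(0.0, sd)
                )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ProteomeParams:
    """Generating parameters for the synthetic NPX protein matrix."""

    n_proteins: int = 179
    n_subjects: int = 40
    responder_protein_count: int = 12
    responder_shift: float = 3.0  # NPX (log2) units
    baseline_sd: float = 1.0      # NPX units, per-sample noise
    subject_sd: float = 0.3       # NPX units, per-subject offset
    seed: int | None = None

    def validate(self) -> None:
        if self.responder_protein_count > self.n_proteins:
            raise ValueError("responder_protein_count cannot exceed n_proteins")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


def simulate_npx(
    params: ProteomeParams | None = None,
    fmd_changes: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate a proteins x (subject, pre/post) NPX matrix on log2 scale.

    Subjects in the top half of ``|fmd_changes|`` ("strong responders") get
    ``responder_shift`` NPX added post-exposure on a random subset of
    ``responder_protein_count`` proteins. Returns the matrix together with
    the list of shifted protein ids.
    """
    from .proteomics import NPXMatrix  # local import avoids cycle at import time

    params = params or ProteomeParams()
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if fmd_changes is None:
        fmd_changes = rng.normal(1.5, 1.0, size=params.n_subjects)
    fmd_changes = np.asarray(fmd_changes, dtype=float)
    if fmd_changes.size != params.n_subjects:
        raise ValueError(
            f"fmd_changes has length {fmd_changes.size}, expected {params.n_subjects}"
        )

    n_p, n_s = params.n_proteins, params.n_subjects
    proteins = [f"P{j + 1:03d}" for j in range(n_p)]
    subjects = [f"s{i + 1:02d}" for i in range(n_s)]

    order = np.argsort(-np.abs(fmd_changes), kind="stable")
    strong = np.zeros(n_s, dtype=bool)
    strong[order[: n_s // 2]] = True

    shifted = sorted(rng.choice(n_p, size=params.responder_protein_count, replace=False).tolist())
    protein_means = rng.normal(5.0, 1.0, size=n_p)
    subj_offsets = rng.normal(0.0, params.subject_sd, size=n_s)

    base = protein_means[:, None] + subj_offsets[None, :]
    pre = base + rng.normal(0.0, params.baseline_sd, size=(n_p, n_s))
    post = base + rng.normal(0.0, params.baseline_sd, size=(n_p, n_s))
    shift = np.zeros((n_p, n_s))
    shift[np.ix_(shifted, np.flatnonzero(strong))] = params.responder_shift
    post = post + shift

    values = pd.DataFrame(
        np.concatenate([pre, post], axis=1),
        index=proteins,
        columns=[f"{s}_pre" for s in subjects] + [f"{s}_post" for s in subjects],
    )
    annotation = pd.DataFrame(
        {
            "sample": list(values.columns),
            "subject": subjects + subjects,
            "timepoint": ["pre"] * n_s + ["post"] * n_s,
        }
    ).set_index("sample")
    annotation["fmd_change"] = annotation["subject"].map(dict(zip(subjects, fmd_changes)))

    matrix = NPXMatrix(values=values, annotation=annotation)
    truth = [proteins[j] for j in shifted]
    return matrix, truth


def simulate_occurrence(
    n_participants: int,
    peaks_per_condition: int,
    probabilities: dict,
    participant_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a per-peak binary response dataset for the occurrence model.

    Each participant contributes ``peaks_per_condition`` Bernoulli outcomes
    per condition; the success probability is ``probabilities[condition]``
    on the logit scale plus a participant intercept of sd
    ``participant_sd``, so the conditions' conditional odds ratios equal the
    odds ratios of the supplied probabilities. Conditions are rotated over
    periods 1..3 so period effects are estimable.
    """
    rng = rng if rng is not None else np.random.default_rng()
    conds = list(probabilities)
    rows = []
    for i in range(n_participants):
        b = rng.normal(0.0, participant_sd)
        for j, cond in enumerate(conds):
            period = ((i + j) % len(conds)) + 1
            p = probabilities[cond]
            eta = np.log(p / (1.0 - p)) + b
            y = rng.random(peaks_per_condition) < 1.0 / (1.0 + np.exp(-eta))
            rows.extend(
                {
                    "participant": f"p{i + 1:03d}",
                    "period": period,
                    "condition": cond,
                    "occurred": int(v),
                }
                for v in y
            )
    return pd.DataFrame(rows)


def simulate_edges(
    proteins,
    edge_probability: float = 0.08,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Random protein-interaction edge list with uniform [0, 1) confidence
    scores, for exercising the network-filter stage without external data."""
    rng = rng if rng is not None else np.random.default_rng()
    proteins = list(proteins)
    rows = []
    for i, a in enumerate(proteins):
        for b in proteins[i + 1 :]:
            if rng.random() < edge_probability:
                rows.append({"node_a": a, "node_b": b, "score": float(rng.random())})
    return pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
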