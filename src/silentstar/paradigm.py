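"""Auditory oddball event schedules.

Generates timed tone schedules for an event-related oddball task: frequent
Standard tones interleaved with rare Deviant (frequency-shifted) and Novel
(unique per onset) tones, with a minimum run of Standards enforced between
non-standard onsets, silent rest blocks, and a mid-run swap of the
Standard/Deviant tone identities to counter habituation.

Tones sit on a fixed slot grid of period ``tone_duration + isi``; rest
blocks and the swap cue pause the grid and shift subsequent slots in time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParadigmConfig",
    "ToneEvent",
    "Schedule",
    "generate_schedule",
    "validate_schedule",
    "write_events",
    "read_events",
]

TONE_TYPES = ("standard", "deviant", "novel")
EVENT_TYPES = TONE_TYPES + ("rest", "swap_cue")


class InfeasibleParadigmError(ValueError):
    """Configured probabilities are incompatible with the spacing constraint."""


@dataclass(frozen=True)
class ParadigmConfig:
    """Parameters of the oddball design.

    Defaults follow the published design: tone-type probabilities
    .84/.09/.07 (Standard/Deviant/Novel), 80 ms tones at 625 ms ISI, five
    initial Standards, at least three Standards between non-standard
    onsets, six evenly spaced 10 s rest blocks, and a swap of the
    Standard/Deviant tone identities at the midpoint tone.
    """

    p_deviant: float = 0.09
    p_novel: float = 0.07
    p_standard: float = 0.84
    tone_duration: float = 0.080
    isi: float = 0.625
    n_initial_standards: int = 5
    min_standards_between: int = 3
    n_rest_blocks: int = 6
    rest_duration: float = 10.0
    # 10 volumes of initial silence; 10 x TR of the slower (radial) arm so a
    # single schedule covers both acquisition arms.
    initial_silence: float = 26.48
    total_duration: float = 636.0
    swap_at_half: bool = True
    swap_pauses_stream: bool = True  # swap cue occupies one slot of silence
    seed: int = 0

    @property
    def slot_period(self) -> float:
        return self.tone_duration + self.isi

    def validate(self) -> None:
        psum = self.p_deviant + self.p_novel + self.p_standard
        if abs(psum - 1.0) > 1e-9:
            raise ValueError(f"tone probabilities sum to {psum}, not 1")
        if min(self.p_deviant, self.p_novel, self.p_standard) < 0:
            raise ValueError("tone probabilities must be nonnegative")
        if self.min_standards_between < 0:
            raise ValueError("min_standards_between must be >= 0")
        r = self.p_deviant + self.p_novel
        if r > 1.0 / (self.min_standards_between + 1) + 1e-12:
            raise InfeasibleParadigmError(
                f"p_deviant + p_novel = {r:.4f} exceeds the maximum rate "
                f"1/(min_standards_between+1) = "
                f"{1.0 / (self.min_standards_between + 1):.4f} attainable "
                "under the spacing constraint"
            )
        if self.total_duration <= self.initial_silence:
            raise ValueError("total_duration must exceed initial_silence")


@dataclass(frozen=True)
class ToneEvent:
    onset: float
    duration: float
    trial_type: str
    tone_id: str = ""

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError(f"negative onset {self.onset}")
        if self.trial_type not in EVENT_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")


@dataclass
class Schedule:
    events: list[ToneEvent]
    config: ParadigmConfig | None = None
    swap_time: float | None = None

    @property
    def tones(self) -> list[ToneEvent]:
        return [e for e in self.events if e.trial_type in TONE_TYPES]

    def onsets(self, trial_type: str) -> np.ndarray:
        return np.array(
            [e.onset for e in self.events if e.trial_type == trial_type],
            dtype=float,
        )

    def duration(self) -> float:
        if self.config is not None:
            return self.config.total_duration
        return max((e.onset + e.duration for e in self.events), default=0.0)


def _draw_probability(config: ParadigmConfig) -> float:
    """Free-slot probability of a non-standard tone.

    With a forced window of m Standards after every non-standard onset, a
    free-slot draw probability q yields a long-run non-standard rate of
    1/(m + 1/q) (renewal argument: one non-standard slot, m forced
    Standards, then a geometric wait of mean 1/q - 1 free Standards).
    Inverting for the target rate r = p_deviant + p_novel gives
    q = r/(1 - m r), so realized type fractions converge to the configured
    probabilities.  Feasibility (r <= 1/(m+1)) guarantees q <= 1.
    """
    r = config.p_deviant + config.p_novel
    if r == 0:
        return 0.0
    m = config.min_standards_between
    return min(1.0, r / (1.0 - m * r))


def generate_schedule(config: ParadigmConfig | None = None, seed: int | None = None) -> Schedule:
    """Generate one oddball run satisfying all design rules.

    Parameters
    ----------
    config
        Paradigm parameters; defaults to the published design.
    seed
        Overrides ``config.seed`` when given.  Identical seeds yield
        identical schedules.
    """
    if config is None:
        config = ParadigmConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    q = _draw_probability(config)
    p_dev_given_ns = (
        config.p_deviant / (config.p_deviant + config.p_novel)
        if config.p_deviant + config.p_novel > 0
        else 0.0
    )

    # rest blocks at the interior points dividing the post-silence run into
    # n_rest_blocks + 1 equal spans
    post = config.total_duration - config.initial_silence
    rest_times = [
        config.initial_silence + (j + 1) * post / (config.n_rest_blocks + 1)
        for j in range(config.n_rest_blocks)
    ]

    # first pass: count slots to locate the midpoint tone for the swap
    events: list[ToneEvent] = []
    t = config.initial_silence
    period = config.slot_period
    next_rest = 0
    standards_since_ns = config.min_standards_between  # start unconstrained
    tone_index = 0
    novel_counter = 0
    tone_records: list[tuple[int, str]] = []  # (event list idx, trial_type)

    while t + config.tone_duration <= config.total_duration:
        if next_rest < len(rest_times) and t >= rest_times[next_rest]:
            events.append(ToneEvent(t, config.rest_duration, "rest"))
            t += config.rest_duration
            next_rest += 1
            continue
        if tone_index < config.n_initial_standards:
            ttype = "standard"
        elif standards_since_ns < config.min_standards_between:
            ttype = "standard"
        elif rng.random() < q:
            ttype = "deviant" if rng.random() < p_dev_given_ns else "novel"
        else:
            ttype = "standard"
        if ttype == "standard":
            standards_since_ns += 1
        else:
            standards_since_ns = 0
        tone_records.append((len(events), ttype))
        events.append(ToneEvent(t, config.tone_duration, ttype))
        tone_index += 1
        t += period

    # trailing rest blocks that were scheduled past the last tone slot
    while next_rest < len(rest_times):
        events.append(ToneEvent(rest_times[next_rest], config.rest_duration, "rest"))
        next_rest += 1
    events.sort(key=lambda e: e.onset)
    # re-locate tone indices after the sort
    tone_positions = [i for i, e in enumerate(events) if e.trial_type in TONE_TYPES]

    swap_time: float | None = None
    swap_tone = len(tone_positions) // 2 if config.swap_at_half else None
    if swap_tone is not None and swap_tone < len(tone_positions):
        swap_time = events[tone_positions[swap_tone]].onset

    # assign tone identities: Standard and Deviant are fixed tones whose
    # roles swap at the midpoint; every Novel tone is unique
    out: list[ToneEvent] = []
    for i, e in enumerate(events):
        if e.trial_type not in TONE_TYPES:
            out.append(e)
            continue
        after_swap = swap_time is not None and e.onset >= swap_time
        if e.trial_type == "standard":
            tid = "tone_B" if after_swap else "tone_A"
        elif e.trial_type == "deviant":
            tid = "tone_A" if after_swap else "tone_B"
        else:
            novel_counter += 1
            tid = f"novel_{novel_counter:03d}"
        out.append(dataclasses.replace(e, tone_id=tid))
    events = out

    if swap_time is not None and config.swap_pauses_stream:
        # the swap cue occupies one slot: insert the cue and push every
        # later event back by one slot period, keeping events in the run
        shifted: list[ToneEvent] = []
        for e in events:
            if e.onset >= swap_time:
                shifted.append(dataclasses.replace(e, onset=e.onset + period))
            else:
                shifted.append(e)
        shifted.append(ToneEvent(swap_time, period, "swap_cue"))
        shifted.sort(key=lambda e: e.onset)
        events = [
            e for e in shifted if e.onset + e.duration <= config.total_duration + period
        ]

    return Schedule(events=events, config=config, swap_time=swap_time)


def validate_schedule(schedule: Schedule) -> list[str]:
    """Check every design rule; return a report of violations (empty = valid).

    Each entry names the violated rule and the offending event index.
    """
    report: list[str] = []
    cfg = schedule.config
    events = schedule.events

    last_end = -np.inf
    for i, e in enumerate(events):
        if e.onset < 0:
            report.append(f"negative onset: event {i}")
        if e.onset < last_end - 1e-9:
            report.append(f"overlapping events: event {i}")
        last_end = max(last_end, e.onset + e.duration)

    novel_ids = [e.tone_id for e in events if e.trial_type == "novel"]
    if len(novel_ids) != len(set(novel_ids)):
        dup = [i for i, e in enumerate(events)
               if e.trial_type == "novel" and novel_ids.count(e.tone_id) > 1]
        report.append(f"duplicate novel tone_id: events {dup}")

    tones = [e for e in events if e.trial_type in TONE_TYPES]
    if cfg is not None:
        for i, e in enumerate(tones[: cfg.n_initial_standards]):
            if e.trial_type != "standard":
                report.append(f"initial-standards rule: tone {i} is {e.trial_type}")
        m = cfg.min_standards_between
        since = m
        for i, e in enumerate(tones):
            if i < cfg.n_initial_standards:
                since = since + 1 if e.trial_type == "standard" else 0
                continue
            if e.trial_type == "standard":
                since += 1
            else:
                if since < m:
                    report.append(
                        f"spacing rule: non-standard tone {i} after only "
                        f"{since} standards (need {m})"
                    )
                since = 0
        rests = [e for e in events if e.trial_type == "rest"]
        if len(rests) != cfg.n_rest_blocks:
            report.append(
                f"rest-block count: found {len(rests)}, require {cfg.n_rest_blocks}"
            )
        for i, e in enumerate(rests):
            if abs(e.duration - cfg.rest_duration) > 1e-9:
                report.append(f"rest-block duration: rest {i} lasts {e.duration}")
        for i, e in enumerate(events):
            if e.trial_type in TONE_TYPES and e.onset < cfg.initial_silence - 1e-9:
                report.append(f"initial-silence rule: tone event {i} at {e.onset}")
    return report


def write_events(schedule: Schedule, path) -> None:
    """Serialize a schedule as a BIDS-style events table (TSV)."""
    df = pd.DataFrame(
        {
            "onset": [e.onset for e in schedule.events],
            "duration": [e.duration for e in schedule.events],
            "trial_type": [e.trial_type for e in schedule.events],
            "tone_id": [e.tone_id if e.tone_id else "n/a" for e in schedule.events],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path) -> Schedule:
    """Read an events TSV back into a :class:`Schedule`.

    Raises ``ValueError`` naming the offending line for malformed rows.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"events table missing columns {required - set(df.columns)}")
    events = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            onset = float(row["onset"])
            duration = float(row["duration"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {line}: non-numeric onset/duration") from exc
        tid = row.get("tone_id", "")
        tid = "" if (pd.isna(tid) or tid == "n/a") else str(tid)
        try:
            events.append(ToneEvent(onset, duration, str(row["trial_type"]), tid))
        except ValueError as exc:
            raise ValueError(f"line {line}: {exc}") from exc
    return Schedule(events=events, config=None)
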