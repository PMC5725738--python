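"""Audio-visual event-stream construction for the rate-discrimination task.

A trial presents a 900 ms stream of brief (12 ms) events -- clicks and/or
flashes -- separated by short (48 ms) or long (96 ms) pauses.  The nominal
rate label (8-14 Hz) equals the number of events in the stream; the second,
"standard" stream always runs at 11 Hz.  Audio-visual streams are either
congruent (equal event counts) or in conflict, with the visual stream
carrying two more (delta = +2) or two fewer (delta = -2) events than the
auditory stream.  The per-trial evidence used throughout the analysis is the
*accumulated rate*: the cumulative event count up to each point in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_DUR_MS = 12
STREAM_DUR_MS = 900
SHORT_PAUSE_MS = 48
LONG_PAUSE_MS = 96
RATE_MIN = 8
RATE_MAX = 14
STANDARD_RATE = 11
N_BINS = STREAM_DUR_MS // EVENT_DUR_MS  # 75 accumulated-rate time points

#: modality/reliability condition labels
UNISENSORY = ("AUD", "VH", "VL")
MULTISENSORY = ("AVH", "AVL")

_MAX_REJECTIONS = 10_000


class StreamInfeasibleError(ValueError):
    """Requested rate cannot be placed in the stream window."""


@dataclass(frozen=True)
class EventStream:
    """One modality's event-onset times for a single trial.

    onsets are in ms from stream start; every event occupies
    [onset, onset + 12) ms and consecutive events are separated by 48 or
    96 ms pauses.  The tail of the window may be silent padding.
    """

    onsets: tuple[float, ...]
    rate: int
    event_dur_ms: int = EVENT_DUR_MS
    stream_dur_ms: int = STREAM_DUR_MS

    def __post_init__(self) -> None:
        on = np.asarray(self.onsets, dtype=float)
        if len(on) != self.rate:
            raise ValueError(
                f"stream has {len(on)} events but rate label {self.rate}"
            )
        if np.any(on < 0):
            raise ValueError("negative event onset")
        if np.any(on + self.event_dur_ms > self.stream_dur_ms):
            raise ValueError("event exceeds stream window")
        gaps = np.diff(on) - self.event_dur_ms
        if gaps.size and not np.all(
            np.isclose(gaps, SHORT_PAUSE_MS) | np.isclose(gaps, LONG_PAUSE_MS)
        ):
            raise ValueError("inter-event pause not in {48, 96} ms")

    @property
    def gaps(self) -> np.ndarray:
        """Internal inter-event pauses in ms (length rate - 1)."""
        return np.diff(np.asarray(self.onsets)) - self.event_dur_ms


def generate_event_stream(
    rate: int,
    rng: np.random.Generator,
    *,
    stream_dur_ms: int = STREAM_DUR_MS,
    allow_leading_pause: bool = True,
) -> EventStream:
    """Draw one randomized event stream at the given nominal rate.

    Internal pauses are drawn i.i.d. from {48, 96} ms and the sequence is
    accepted iff the occupied time fits the window, which makes the accepted
    sequence uniform over the feasible set.  With probability 1/2 the first
    event is itself preceded by a drawn pause, otherwise it starts at t = 0;
    the remaining tail of the window is silent.
    """
    if not (RATE_MIN <= rate <= RATE_MAX):
        raise StreamInfeasibleError(
            f"rate {rate} outside supported range {RATE_MIN}-{RATE_MAX} Hz"
        )
    pauses = np.array([SHORT_PAUSE_MS, LONG_PAUSE_MS])
    for _ in range(_MAX_REJECTIONS):
        gaps = rng.choice(pauses, size=rate - 1)
        lead = 0.0
        if allow_leading_pause and rng.random() < 0.5:
            lead = float(rng.choice(pauses))
        occupied = lead + rate * EVENT_DUR_MS + gaps.sum()
        if occupied <= stream_dur_ms:
            onsets = lead + np.concatenate(
                ([0.0], np.cumsum(gaps + EVENT_DUR_MS))
            )
            return EventStream(tuple(onsets), rate, stream_dur_ms=stream_dur_ms)
    raise StreamInfeasibleError(
        f"no feasible pause sequence for rate {rate} in {stream_dur_ms} ms "
        f"after {_MAX_REJECTIONS} draws (constraint: 12*R + sum(gaps) <= window)"
    )


def feasible_pause_compositions(
    rate: int, stream_dur_ms: int = STREAM_DUR_MS
) -> list[tuple[int, int]]:
    """All (n_short, n_long) internal-pause compositions that fit the window."""
    n_gaps = rate - 1
    out = []
    for n_long in range(n_gaps + 1):
        n_short = n_gaps - n_long
        occ = rate * EVENT_DUR_MS + n_short * SHORT_PAUSE_MS + n_long * LONG_PAUSE_MS
        if occ <= stream_dur_ms:
            out.append((n_short, n_long))
    return out


# ---------------------------------------------------------------------------
# trial tables


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the 9-condition design."""

    name: str          # e.g. "AVH_d+2"
    modality: str      # AUD | VH | VL | AVH | AVL
    reliability: str   # visual reliability: high | low (AUD carries high)
    delta: int         # visual - auditory rate; 0 for unisensory/congruent


def default_conditions() -> tuple[ConditionSpec, ...]:
    """The task's 9 conditions: 3 unisensory, 2 congruent AV, 4 incongruent AV."""
    conds = [
        ConditionSpec("AUD", "AUD", "high", 0),
        ConditionSpec("VH", "VH", "high", 0),
        ConditionSpec("VL", "VL", "low", 0),
    ]
    for rel, mod in (("high", "AVH"), ("low", "AVL")):
        for d in (0, 2, -2):
            suffix = {0: "d0", 2: "d+2", -2: "d-2"}[d]
            conds.append(ConditionSpec(f"{mod}_{suffix}", mod, rel, d))
    return tuple(conds)


@dataclass
class TrialDesign:
    """Counts and rate layout for one block of trials.

    The nominal rate of a trial is the (average) experimental-stream rate
    plotted on the psychometric x-axis; on conflict trials the auditory and
    visual streams carry nominal -/+ delta/2 events.  Equal-rate trials
    (nominal rate = standard 11 Hz) appear at ``equal_rate_fraction`` per
    condition; they have no correct answer and no high/low class label.
    """

    n_trials: int = 510
    equal_rate_fraction: float = 0.02
    conditions: tuple[ConditionSpec, ...] = field(default_factory=default_conditions)
    condition_weights: tuple[float, ...] | None = None
    rates: tuple[int, ...] = tuple(range(RATE_MIN, RATE_MAX + 1))
    standard_rate: int = STANDARD_RATE

    def allowed_rates(self, cond: ConditionSpec) -> list[int]:
        """Nominal non-equal rates usable in a condition (streams stay in 8-14)."""
        half = abs(cond.delta) // 2
        return [
            r for r in self.rates
            if r != self.standard_rate
            and r - half >= RATE_MIN and r + half <= RATE_MAX
        ]

    def condition_counts(self) -> dict[str, int]:
        """Exact per-condition trial counts (largest-remainder apportionment)."""
        k = len(self.conditions)
        w = np.asarray(
            self.condition_weights if self.condition_weights is not None
            else np.ones(k)
        , dtype=float)
        if w.shape != (k,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("condition_weights must be non-negative, one per condition")
        w = w / w.sum()
        return {
            c.name: n
            for c, n in zip(self.conditions, _apportion(self.n_trials, w))
        }


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer counts summing to ``total`` with largest-remainder rounding."""
    quota = total * weights
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:short]] += 1
    return counts


def _rate_counts(n: int, rates: list[int]) -> dict[int, int]:
    counts = _apportion(n, np.full(len(rates), 1 / len(rates)))
    return dict(zip(rates, counts))


def generate_trial_table(
    design: TrialDesign,
    rng: np.random.Generator,
    *,
    subject_id: int = 0,
) -> pd.DataFrame:
    """Generate one pseudo-random block of trials with paired event streams.

    Returns a DataFrame with one row per trial: condition factors, nominal
    and per-modality rates, JSON-encoded onset lists, and a ``label`` column
    (rate above/below the 11 Hz standard; NA on equal-rate trials, which get
    random feedback instead).  The ``choice`` column is left NA for the
    observer model to fill in.
    """
    frac = design.equal_rate_fraction
    if not 0 <= frac <= 1:
        raise ValueError("equal_rate_fraction must be in [0, 1]")
    rows = []
    for cond in design.conditions:
        n_cond = design.condition_counts()[cond.name]
        if n_cond == 0:
            continue
        allowed = design.allowed_rates(cond)
        if not allowed:
            raise ValueError(
                f"condition {cond.name}: delta {cond.delta} incompatible with "
                f"rate bounds {RATE_MIN}-{RATE_MAX}"
            )
        n_equal = int(round(frac * n_cond))
        per_rate = _rate_counts(n_cond - n_equal, allowed)
        per_rate[design.standard_rate] = per_rate.get(design.standard_rate, 0) + n_equal
        for rate, n in per_rate.items():
            for _ in range(n):
                rows.append(_make_trial(cond, rate, design, rng))
    df = pd.DataFrame(rows)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "trial_id", np.arange(len(df)))
    df.insert(1, "subject_id", subject_id)
    df["choice"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


def _make_trial(
    cond: ConditionSpec, rate: int, design: TrialDesign, rng: np.random.Generator
) -> dict:
    half = cond.delta // 2
    rate_aud = rate - half if cond.modality in MULTISENSORY else rate
    rate_vis = rate + half if cond.modality in MULTISENSORY else rate
    onsets_aud: list[float] = []
    onsets_vis: list[float] = []
    if cond.modality in ("AUD",) + MULTISENSORY:
        onsets_aud = list(generate_event_stream(rate_aud, rng).onsets)
    if cond.modality in ("VH", "VL") + MULTISENSORY:
        onsets_vis = list(generate_event_stream(rate_vis, rng).onsets)
    is_equal = rate == design.standard_rate
    return {
        "condition": cond.name,
        "modality": cond.modality,
        "reliability": cond.reliability,
        "rate": rate,
        "rate_aud": rate_aud if onsets_aud else pd.NA,
        "rate_vis": rate_vis if onsets_vis else pd.NA,
        "delta": cond.delta,
        "is_equal_rate": is_equal,
        # class label for the decoder: 1 if above standard, random feedback if equal
        "label": pd.NA if is_equal else int(rate > design.standard_rate),
        "feedback": int(rng.integers(2)) if is_equal else int(rate > design.standard_rate),
        "onsets_aud": json.dumps(onsets_aud),
        "onsets_vis": json.dumps(onsets_vis),
    }


# ---------------------------------------------------------------------------
# accumulated rate


@dataclass(frozen=True)
class AccumulatedRate:
    """Cumulative event count on the 12 ms bin grid."""

    counts: np.ndarray          # one value per bin, non-decreasing
    bin_ms: int = EVENT_DUR_MS

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def times(self) -> np.ndarray:
        """Bin-end times in ms: counts[k] counts onsets before times[k]."""
        return self.bin_ms * (np.arange(self.n_bins) + 1.0)


def accumulated_counts(onsets, times) -> np.ndarray:
    """Number of event onsets strictly before each time in ``times`` (ms)."""
    on = np.sort(np.asarray(onsets, dtype=float))
    return np.searchsorted(on, np.asarray(times, dtype=float), side="left").astype(float)


def accumulated_rate(stream: EventStream, t_end: int = STREAM_DUR_MS) -> AccumulatedRate:
    """Accumulated rate in 12 ms bins: counts[k] = #onsets < 12*(k+1).

    The full 900 ms stream yields 75 time points.
    """
    if t_end % EVENT_DUR_MS != 0:
        raise ValueError(f"t_end={t_end} not aligned to the {EVENT_DUR_MS} ms bin grid")
    if not 0 < t_end <= stream.stream_dur_ms:
        raise ValueError("t_end outside the stream window")
    edges = EVENT_DUR_MS * (np.arange(t_end // EVENT_DUR_MS) + 1)
    return AccumulatedRate(accumulated_counts(stream.onsets, edges))


def onsets_from_json(s: str) -> np.ndarray:
    """Decode a JSON onset list column value."""
    return np.asarray(json.loads(s), dtype=float)
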