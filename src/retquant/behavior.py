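"""Behavioral scoring: optomotor response and conditioned freezing.

The optomotor response (OMR) score is the ratio of time spent in head/body
movements concordant with a drifting grating to time spent in discordant
movements; a score of 1.0 marks indifference to the stimulus and is the
perception threshold. Classical-conditioning sessions are scored as the
percentage of time spent freezing, per CS-US pairing (learning curve),
per cue sub-period (dark vs light CS) and in the context test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OMR_STATES = ("concordant", "discordant", "neither")
FREEZING_STATES = ("freezing", "active")

CONDITIONING_PHASES = tuple(f"pairing_{i}" for i in range(1, 8)) + (
    "cue_dark",
    "cue_cs",
    "context",
)


class UndefinedScoreError(ValueError):
    """No discordant movement: the OMR ratio is censored high."""


class MissingPhaseError(ValueError):
    def __init__(self, phase: str):
        super().__init__(f"conditioning session is missing phase {phase!r}")
        self.phase = phase


@dataclass
class OMRScore:
    score: float
    concordant_s: float
    discordant_s: float
    censored_high: bool = False


def state_durations(trace: pd.DataFrame) -> pd.Series:
    """Total duration per state of a regularly sampled (t_s, state) trace.

    Each sample is taken to represent one sample period (the trace's
    median timestamp increment).
    """
    t = np.asarray(trace["t_s"], dtype=float)
    if len(t) == 0:
        return pd.Series(dtype=float)
    if len(t) > 1:
        dt_all = np.diff(t)
        if (dt_all <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        dt = float(np.median(dt_all))
    else:
        dt = 1.0
    return trace.groupby("state", observed=True).size() * dt


def omr_score(trace: pd.DataFrame) -> OMRScore:
    """Concordance/discordance ratio at one spatial frequency.

    Time with no tracked movement ("neither") enters neither numerator nor
    denominator. Zero discordant time with some concordant time makes the
    ratio undefined; it is reported censored-high via UndefinedScoreError.
    """
    dur = state_durations(trace)
    unknown = set(dur.index) - set(OMR_STATES)
    if unknown:
        raise ValueError(f"states outside the OMR alphabet: {sorted(unknown)}")
    conc = float(dur.get("concordant", 0.0))
    disc = float(dur.get("discordant", 0.0))
    if disc == 0.0:
        raise UndefinedScoreError(
            f"no discordant movement (concordant {conc:.3g} s): score censored high"
        )
    return OMRScore(conc / disc, conc, disc)


def aggregate_omr(scores, min_repeats: int = 4, pooled: bool = False) -> float:
    """Mean OMR score over repeats of one spatial frequency.

    Scores are averaged per repeat (the default); ``pooled`` instead sums
    durations across repeats before taking one ratio.
    """
    scores = list(scores)
    if len(scores) < min_repeats:
        raise ValueError(f"need at least {min_repeats} repeats, got {len(scores)}")
    if pooled:
        conc = sum(s.concordant_s for s in scores)
        disc = sum(s.discordant_s for s in scores)
        if disc == 0:
            raise UndefinedScoreError("no discordant movement across repeats")
        return conc / disc
    return float(np.mean([s.score for s in scores]))


def freezing_percentage(trace: pd.DataFrame, session_s: float) -> float:
    """Freezing time as a percentage of total session time."""
    if session_s <= 0:
        raise ValueError("session duration must be positive")
    dur = state_durations(trace)
    total = float(dur.sum())
    if total > session_s * 1.001:
        raise ValueError("trace duration exceeds the stated session duration")
    # clamp float round-off when the trace spans the whole session
    return min(100.0 * float(dur.get("freezing", 0.0)) / session_s, 100.0)


def conditioning_summary(phase_traces: dict[str, pd.DataFrame],
                         phase_durations_s: dict[str, float] | None = None) -> pd.DataFrame:
    """Freezing percentages over a full conditioning protocol.

    Expects one trace per phase: seven CS-US pairings (``pairing_1`` ..
    ``pairing_7``, the learning curve), the cue test sub-periods
    (``cue_dark``: 2 min dark; ``cue_cs``: 3 min light CS) and the
    ``context`` test (5 min). Emits freezing % per phase plus the paired
    dark-vs-CS difference (``cue_cs_minus_dark``).
    """
    defaults = {p: None for p in CONDITIONING_PHASES}
    defaults.update({"cue_dark": 120.0, "cue_cs": 180.0, "context": 300.0})
    rows = []
    for phase in CONDITIONING_PHASES:
        if phase not in phase_traces:
            raise MissingPhaseError(phase)
        trace = phase_traces[phase]
        if phase_durations_s and phase in phase_durations_s:
            dur = phase_durations_s[phase]
        elif defaults[phase] is not None:
            dur = defaults[phase]
        else:
            dur = float(state_durations(trace).sum())
        rows.append({"phase": phase, "freezing_pct": freezing_percentage(trace, dur)})
    out = pd.DataFrame(rows)
    cs = float(out.loc[out["phase"] == "cue_cs", "freezing_pct"].iloc[0])
    dark = float(out.loc[out["phase"] == "cue_dark", "freezing_pct"].iloc[0])
    diff = pd.DataFrame([{"phase": "cue_cs_minus_dark", "freezing_pct": cs - dark}])
    return pd.concat([out, diff], ignore_index=True)
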