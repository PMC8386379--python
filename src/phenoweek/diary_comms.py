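"""Voice-diary, text-message and phone-call features.

Sentiment is scored by a deterministic lexicon scorer returning values in
[-1, 1] (the mean lexicon score of in-lexicon tokens, 0 when none match).
The scorer sits behind a small callable interface so a model-based
classifier can be swapped in; the packaged lexicon is the reference
implementation.  Text features use outgoing messages only; emoji are
counted as Unicode code points in the standard emoji blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "load_lexicon",
    "sentiment_score",
    "count_emoji",
    "DiaryFeatures",
    "diary_features",
    "text_features",
    "call_features",
]

# Unicode emoji blocks: emoticons, pictographs (incl. supplement),
# transport & map, misc symbols, dingbats, supplemental symbols.
_EMOJI_RANGES = (
    (0x1F300, 0x1F5FF),
    (0x1F600, 0x1F64F),
    (0x1F680, 0x1F6FF),
    (0x1F900, 0x1F9FF),
    (0x2600, 0x26FF),
    (0x2700, 0x27BF),
)


def load_lexicon() -> dict[str, float]:
    """Packaged token -> score sentiment lexicon (scores in [-1, 1])."""
    with resources.files("phenoweek.data").joinpath("sentiment_lexicon.csv").open() as fh:
        df = pd.read_csv(fh)
    lex = dict(zip(df["token"].astype(str), df["score"].astype(float)))
    bad = [t for t, s in lex.items() if not -1.0 <= s <= 1.0]
    if bad:
        raise ValueError(f"lexicon scores outside [-1, 1] for {bad}")
    return lex


def sentiment_score(tokens: Iterable[str], lexicon: Mapping[str, float]) -> float:
    """Mean lexicon score over in-lexicon tokens; 0 if none match."""
    scores = [lexicon[t] for t in tokens if t in lexicon]
    if not scores:
        return 0.0
    return float(np.mean(scores))


def count_emoji(text: str) -> int:
    """Number of emoji code points in ``text``."""
    return sum(1 for ch in text if any(lo <= ord(ch) <= hi for lo, hi in _EMOJI_RANGES))


@dataclass
class DiaryFeatures:
    sentiment: float
    words_per_minute: float
    duration_s: float
    mean_pause_s: float


def diary_features(
    transcript: Sequence[str],
    duration_s: float,
    pause_durations_s: Sequence[float],
    lexicon: Mapping[str, float],
) -> DiaryFeatures:
    """Weekly voice-diary features from transcript and timing metadata."""
    if duration_s <= 0:
        raise ValueError("diary duration must be positive")
    pauses = np.asarray(list(pause_durations_s), dtype=float)
    if (pauses < 0).any():
        raise ValueError("pause durations must be nonnegative")
    return DiaryFeatures(
        sentiment=sentiment_score(transcript, lexicon),
        words_per_minute=len(transcript) / (duration_s / 60.0),
        duration_s=float(duration_s),
        mean_pause_s=float(pauses.mean()) if pauses.size else 0.0,
    )


def text_features(messages: pd.DataFrame, lexicon: Mapping[str, float]) -> dict[str, float]:
    """Daily outgoing-text features.

    ``messages`` holds one row per message that day with columns
    ``direction`` ("outgoing"/"incoming") and ``body``.  Incoming messages
    are dropped before anything is computed; sentiment is scored on the
    concatenation of all outgoing tokens for the day.
    """
    if len(messages):
        out = messages[messages["direction"] == "outgoing"]
    else:
        out = messages
    bodies = [str(b) for b in out["body"]] if len(out) else []
    tokens: list[str] = []
    for b in bodies:
        tokens.extend(b.split())
    return {
        "text_message_count": float(len(bodies)),
        "text_message_emoji_count": float(sum(count_emoji(b) for b in bodies)),
        "text_message_body_size": float(sum(len(b) for b in bodies)),
        "outgoing_text_sentiment": sentiment_score(tokens, lexicon),
    }


def call_features(calls: pd.DataFrame) -> dict[str, float]:
    """Daily phone-call metadata features.

    ``calls`` holds one row per call with columns ``direction``,
    ``outcome`` ("answered"/"missed"), ``ring_s`` and ``duration_s``
    (connected seconds, 0 for missed).  The call count includes missed
    calls; ring-until-missed sums ring time of missed incoming calls, in
    minutes.
    """
    if len(calls):
        ring = np.asarray(calls["ring_s"], dtype=float)
        dur = np.asarray(calls["duration_s"], dtype=float)
        if (ring < 0).any() or (dur < 0).any():
            raise ValueError("call intervals must be nonnegative")
        incoming = calls["direction"].to_numpy() == "incoming"
        missed = calls["outcome"].to_numpy() == "missed"
        return {
            "phone_call_count": float(len(calls)),
            "incoming_phone_call_duration": float(dur[incoming & ~missed].sum()),
            "outgoing_phone_call_duration": float(dur[~incoming & ~missed].sum()),
            "ring_until_missed_minutes": float(ring[incoming & missed].sum() / 60.0),
        }
    return {
        "phone_call_count": 0.0,
        "incoming_phone_call_duration": 0.0,
        "outgoing_phone_call_duration": 0.0,
        "ring_until_missed_minutes": 0.0,
    }
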