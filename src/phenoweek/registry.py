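"""Canonical registry of the 34 weekly behavioral features.

The analysis uses a fixed, a-priori set of 34 features spanning four
families: location (GPS-derived mobility), voice diary, communication
(texts and calls) and device state / activity.  The registry pins the
canonical machine names, the human-readable labels, the source stream and
the daily-to-weekly aggregation rule for each feature, and is the single
authority on feature order for every downstream table.

Two of the 34 features are *missingness indicators* ("App usage missing",
"Reported sleep duration missing"): permission-gated streams whose absence
is itself informative, encoded as the weekly fraction of days on which the
stream produced no data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "FeatureSpec",
    "FEATURES",
    "FEATURE_NAMES",
    "FEATURE_LABELS",
    "N_FEATURES",
    "reference_table",
    "default_effect_sizes",
    "registry_yaml",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One registered weekly behavioral feature."""

    name: str
    label: str
    source: str  # raw stream(s) the feature is derived from
    aggregation: str  # how daily values become the weekly value


def _load_reference() -> pd.DataFrame:
    with resources.files("phenoweek.data").joinpath("table2_reference.csv").open() as fh:
        return pd.read_csv(fh)


_REFERENCE = _load_reference()

# source stream and weekly aggregation per feature, in registry order
_SOURCES = {
    "voice_diary_sentiment": ("diary", "weekly diary, lexicon sentiment of transcript"),
    "reported_sleep_duration": ("sleep_report", "mean of daily self-reported hours"),
    "ambient_audio_level": ("ambient_audio", "mean of daily means of minutely level"),
    "ring_until_missed_minutes": ("calls", "mean of daily summed ring-to-miss minutes"),
    "unique_location_clusters": ("location", "distinct non-noise clusters visited in week"),
    "voice_diary_words_per_minute": ("diary", "weekly diary, tokens per minute"),
    "voice_diary_duration": ("diary", "weekly diary duration in seconds"),
    "battery_percentage": ("battery", "mean of daily mean charge percentage"),
    "text_message_emoji_count": ("texts", "mean of daily outgoing emoji counts"),
    "phone_call_count": ("calls", "mean of daily call counts (all calls)"),
    "voice_diary_pauses_duration": ("diary", "weekly diary, mean pause seconds"),
    "location_entropy": ("location", "Shannon entropy of weekly cluster minutes (nats)"),
    "ambient_light_level": ("ambient_light", "mean of daily means of minutely level"),
    "outgoing_text_sentiment": ("texts", "mean of daily sentiment of concatenated outgoing tokens"),
    "location_variance": ("location", "var(lat)+var(lon) of weekly points (deg^2)"),
    "phone_screen_on_minutes": ("screen", "mean of daily screen-on minutes"),
    "audio_system_volume": ("volume", "mean of daily system-channel level"),
    "charging_minutes": ("battery", "mean of daily minutes with charging flag"),
    "social_apps_usage": ("app_usage", "mean of daily foreground minutes, social apps"),
    "time_spent_at_home": ("location", "mean of daily minutes in home cluster"),
    "app_usage_missing": ("app_usage", "weekly fraction of days with no app-usage data"),
    "outgoing_phone_call_duration": ("calls", "mean of daily summed outgoing connected seconds"),
    "wellness_apps_usage": ("app_usage", "mean of daily foreground minutes, wellness apps"),
    "time_spent_at_hospital": ("location", "mean of daily minutes in hospital-tagged clusters"),
    "n_wifi_networks": ("wifi", "mean of daily distinct networks seen"),
    "reported_sleep_duration_missing": ("sleep_report", "weekly fraction of days with no sleep report"),
    "communication_apps_usage": ("app_usage", "mean of daily foreground minutes, communication apps"),
    "text_message_body_size": ("texts", "mean of daily total outgoing characters"),
    "ring_volume": ("volume", "mean of daily ring-channel level"),
    "physically_active_minutes": ("activity", "mean of daily minutes labeled active"),
    "audio_notification_volume": ("volume", "mean of daily notification-channel level"),
    "text_message_count": ("texts", "mean of daily outgoing message counts"),
    "nearby_wifi_count": ("wifi", "mean of per-scan visible network counts"),
    "incoming_phone_call_duration": ("calls", "mean of daily summed incoming connected seconds"),
}

FEATURES: tuple[FeatureSpec, ...] = tuple(
    FeatureSpec(
        name=row.feature,
        label=row.label,
        source=_SOURCES[row.feature][0],
        aggregation=_SOURCES[row.feature][1],
    )
    for row in _REFERENCE.itertuples()
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES)
FEATURE_LABELS: tuple[str, ...] = tuple(f.label for f in FEATURES)
N_FEATURES = len(FEATURES)

# The registry is exactly the 34-feature analysis set; fail loudly at import
# if the packaged reference and the source table ever drift apart.
if N_FEATURES != 34 or len(set(FEATURE_NAMES)) != 34:
    raise RuntimeError("feature registry must contain exactly 34 unique features")

# the two permission-gated missing-data indicator features
INDICATOR_FEATURES = ("app_usage_missing", "reported_sleep_duration_missing")


def reference_table() -> pd.DataFrame:
    """Printed univariate reference table (labels, r, P labels, counts)."""
    return _REFERENCE.copy()


def default_effect_sizes(strength: float = 2.5, cap: float = 0.6) -> dict[str, float]:
    """Default signed standardized effects of latent severity per feature.

    The convention is ``effect = strength * reported_r`` capped at ``cap`` in
    magnitude, so the injected ordering and signs follow the reported
    univariate structure while staying in a moderate range.  The two
    missingness indicator features get 0 (their association is a device /
    permission property, not a behavioral response).
    """
    effects: dict[str, float] = {}
    for row in _REFERENCE.itertuples():
        if row.feature in INDICATOR_FEATURES:
            effects[row.feature] = 0.0
            continue
        e = strength * float(row.spearman_r)
        effects[row.feature] = max(-cap, min(cap, e))
    return effects


def registry_yaml() -> str:
    """Registry as a YAML document (for the exported features file)."""
    import yaml

    doc = [
        {
            "name": f.name,
            "label": f.label,
            "source": f.source,
            "aggregation": f.aggregation,
        }
        for f in FEATURES
    ]
    return yaml.safe_dump({"features": doc}, sort_keys=False)
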