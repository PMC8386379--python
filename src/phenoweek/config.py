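"""Configuration objects for cohort simulation and analysis.

All knobs that the science depends on live here: cohort design (size, the
80:20 depressed:nondepressed recruitment ratio, 12 study weeks), the latent
severity process, per-feature effect sizes, missingness regimes, GPS
clustering parameters and the penalized-regression specification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import yaml

from .registry import FEATURE_NAMES, default_effect_sizes

__all__ = [
    "ConfigError",
    "MINUTELY_SENSORS",
    "EVENT_STREAMS",
    "MissingnessConfig",
    "CohortConfig",
    "LocationConfig",
    "ElasticNetSpec",
]


class ConfigError(ValueError):
    """Invalid configuration value."""


#: The seven sensor streams sampled at a regular 1-minute cadence.  A day's
#: data sufficiency is judged on these (plus app activity measured by ping).
MINUTELY_SENSORS = (
    "ambient_audio",
    "ambient_light",
    "activity",
    "location",
    "pressure",
    "ping",
    "proximity",
)

#: Event-driven and periodic streams.
EVENT_STREAMS = (
    "battery",
    "screen",
    "volume",
    "app_usage",
    "wifi",
    "calls",
    "texts",
    "sleep_report",
    "diary",
)

_ALL_STREAMS = set(MINUTELY_SENSORS) | set(EVENT_STREAMS)


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {p!r}")


@dataclass
class MissingnessConfig:
    """Missing-data regimes for the synthetic cohort.

    Two passive regimes mirror the patterns seen in real bring-your-own-
    device cohorts: whole-sensor absence (a device simply lacks the sensor
    or the permission was never granted; sampled once per participant) and
    speckled loss (independent per-day dropout of the whole app and per-
    minute sample loss).  Survey tasks have their own completion
    probabilities since participants skip surveys for reasons unrelated to
    passive collection.
    """

    p_sensor_absent: dict[str, float] = field(
        default_factory=lambda: {
            "ambient_audio": 0.04,
            "ambient_light": 0.15,
            "location": 0.01,
            "app_usage": 0.10,
            "wifi": 0.05,
            "calls": 0.04,
            "texts": 0.04,
            "sleep_report": 0.06,
        }
    )
    p_day_dropout: float = 0.08
    p_minute_gap: float = 0.05
    p_phq9_missing: float = 0.17
    p_diary_missing: float = 0.20
    p_sleep_missing: float = 0.25

    def validate(self) -> None:
        for sensor, p in self.p_sensor_absent.items():
            if sensor not in _ALL_STREAMS:
                raise ConfigError(f"unknown stream in p_sensor_absent: {sensor!r}")
            _check_prob(f"p_sensor_absent[{sensor}]", p)
        for name in (
            "p_day_dropout",
            "p_minute_gap",
            "p_phq9_missing",
            "p_diary_missing",
            "p_sleep_missing",
        ):
            _check_prob(name, getattr(self, name))

    @staticmethod
    def none() -> "MissingnessConfig":
        """A zero-missingness regime (every stream fully observed)."""
        return MissingnessConfig(
            p_sensor_absent={},
            p_day_dropout=0.0,
            p_minute_gap=0.0,
            p_phq9_missing=0.0,
            p_diary_missing=0.0,
            p_sleep_missing=0.0,
        )


@dataclass
class CohortConfig:
    """Design of one synthetic study cohort.

    ``frac_depressed`` encodes the 80:20 recruitment ratio of the emulated
    design.  Latent weekly severity is an AR(1) process per participant
    (see :mod:`phenoweek.simulate`); ``effect_sizes`` maps feature names to
    signed standardized effects of severity on that feature's weekly mean.
    """

    n_participants: int
    frac_depressed: float = 0.8
    n_weeks: int = 12
    seed: int = 0
    effect_sizes: dict[str, float] = field(default_factory=default_effect_sizes)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    timezone_offset_hours: int = -5
    # latent severity process (logit units of the item-response model)
    persistence: float = 0.8
    innovation_sd: float = 0.3
    between_sd: float = 0.5
    # GPS jitter around anchors, meters
    jitter_m: float = 10.0
    start_date: str = "2018-01-01"

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        _check_prob("frac_depressed", self.frac_depressed)
        if self.n_weeks < 1:
            raise ConfigError("n_weeks must be >= 1")
        if not (0.0 <= self.persistence < 1.0):
            raise ConfigError("persistence must be in [0, 1)")
        if self.innovation_sd < 0 or self.between_sd < 0 or self.jitter_m < 0:
            raise ConfigError("standard deviations must be nonnegative")
        for name in self.effect_sizes:
            if name not in FEATURE_NAMES:
                raise ConfigError(f"effect_sizes key is not a registered feature: {name!r}")
        self.missingness.validate()

    @property
    def n_depressed(self) -> int:
        return round(self.n_participants * self.frac_depressed)

    @property
    def n_days(self) -> int:
        return self.n_weeks * 7

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        miss = doc.pop("missingness", None)
        cfg = cls(**doc) if miss is None else cls(missingness=MissingnessConfig(**miss), **doc)
        return cfg


@dataclass
class LocationConfig:
    """GPS clustering and place-labeling parameters.

    ``eps_m``/``min_samples`` parametrize density clustering under haversine
    distance; defaults (30 m, 5 minutely points) sit between typical GPS
    jitter and building scale.  The work heuristic labels any non-home
    cluster holding at least ``work_share_threshold`` of the 10 AM-3 PM
    clustered minutes.
    """

    eps_m: float = 30.0
    min_samples: int = 5
    grid_m: float | None = 3.0  # spatial binning used by the pipeline path
    work_share_threshold: float = 0.15

    def validate(self) -> None:
        if self.eps_m <= 0:
            raise ConfigError("eps_m must be > 0")
        if self.min_samples < 1:
            raise ConfigError("min_samples must be >= 1")
        _check_prob("work_share_threshold", self.work_share_threshold)


@dataclass
class ElasticNetSpec:
    """Penalized logistic regression specification.

    ``C`` is the inverse regularization strength and ``l1_ratio`` the
    elastic-net mixing parameter rho; the study-fidelity values are C=1.0,
    rho=0.5.
    """

    C: float = 1.0
    l1_ratio: float = 0.5
    max_iter: int = 5000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigError("C must be > 0")
        if not (0.0 <= self.l1_ratio <= 1.0):
            raise ConfigError("l1_ratio must be in [0, 1]")


def severity_mixture_stats(cfg: CohortConfig, mu_depressed: float, mu_control: float) -> tuple[float, float]:
    """Population mean and SD of weekly severity under the cohort mixture.

    Used to standardize severity before applying feature effects, so a
    configured effect is on a population-z scale regardless of cohort
    composition.
    """
    import math

    f = cfg.frac_depressed
    within_var = cfg.between_sd**2 + cfg.innovation_sd**2 / (1.0 - cfg.persistence**2)
    mean = f * mu_depressed + (1.0 - f) * mu_control
    between_arm = f * (mu_depressed - mean) ** 2 + (1.0 - f) * (mu_control - mean) ** 2
    return mean, math.sqrt(within_var + between_arm)
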