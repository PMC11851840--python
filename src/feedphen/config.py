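"""Configuration objects for the simulator and the end-to-end pipeline.

Defaults encode the herd conditions the package is calibrated to: Yorkshire
boars entering an automatic feeding station at ~28.3 kg and measured daily
until they approach market weight, with average daily gain around
1.02 kg/day, feed conversion ratio around 2.31 kg feed per kg gain, about
8 feeder visits per day, and a feed intake rate near 46 g/min.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: Anomaly classes understood by the simulator; keys are the indices of the
#: eight visit-level quality-control rules (see :mod:`feedphen.qc`).
ANOMALY_CLASSES = tuple(range(1, 9))

# Per-class injection probability per visit.  The combined default rate
# (8 x 0.0015 = 1.2% of visits) mirrors the fraction of records a typical
# feeder-station campaign loses to the eight QC rules.
_DEFAULT_ANOMALY_RATE = 0.0015


def default_anomaly_rates() -> dict[int, float]:
    return {c: _DEFAULT_ANOMALY_RATE for c in ANOMALY_CLASSES}


@dataclass
class SimConfig:
    """Parameters of the synthetic automatic-feeder herd.

    Growth follows a per-animal three-parameter logistic curve
    ``BW(d) = bw_max / (1 + exp((xmid - d) / scal))``.  Each animal draws an
    asymptotic weight ``bw_max`` and a target average daily gain over the
    30-120 kg range; the curve steepness ``scal`` is solved from those two so
    that the realized 30-120 kg ADG equals the drawn value exactly on the
    noise-free trajectory.  Daily feed is tied to daily gain through the
    animal's feed conversion ratio.
    """

    n_pigs: int = 100
    seed: int = 0
    days: int = 100

    # Body weight at test entry (kg).
    bw_entry_mean: float = 28.30
    bw_entry_sd: float = 1.02

    # Asymptotic (mature) body weight of the logistic curve (kg).
    bw_max_mean: float = 160.0
    bw_max_sd: float = 10.0
    bw_max_min: float = 135.0  # resample below this; animals must clear 120 kg

    # Average daily gain over 30-120 kg (kg/day).
    adg_mean: float = 1.02
    adg_sd: float = 0.12

    # Feed conversion ratio (kg feed per kg gain).
    fcr_mean: float = 2.31
    fcr_sd: float = 0.27

    # Feeder-visit structure.
    visits_per_day_mean: float = 7.93
    feed_rate_mean: float = 45.65  # g/min
    feed_rate_sd: float = 23.94
    feed_rate_min: float = 20.0  # g/min; keeps clean visits under the FRV caps
    feed_rate_max: float = 300.0

    # Observation noise.
    bw_noise_sd: float = 1.0  # kg, day-level weighing noise
    bw_visit_jitter_sd: float = 0.2  # kg, within-day platform jitter
    dfi_noise_sd: float = 0.25  # kg, day-level feed noise
    # Optional weight-dependent noise profile: both day-level noise SDs are
    # multiplied by a factor that is `early_noise_scale` at and below 30 kg
    # and tapers linearly to 1 at `noise_taper_bw`.  The default (1.0) is
    # homoscedastic; values > 1 emulate the noisier records young animals
    # produce while adapting to the feeder.
    early_noise_scale: float = 1.0
    noise_taper_bw: float = 80.0  # kg

    # Per-visit probability of each of the eight QC-rule anomaly classes.
    anomaly_rates: dict[int, float] = field(default_factory=default_anomaly_rates)
    # Per-visit probability of an incomplete record (a field left missing).
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pigs < 1:
            raise ValueError("n_pigs must be >= 1")
        if self.days < 3:
            raise ValueError("days must be >= 3")
        if self.early_noise_scale <= 0:
            raise ValueError("early_noise_scale must be positive")
        for name in ("bw_entry_sd", "adg_sd", "fcr_sd", "feed_rate_sd",
                     "bw_max_sd", "bw_noise_sd", "bw_visit_jitter_sd",
                     "dfi_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        rates = {int(k): float(v) for k, v in self.anomaly_rates.items()}
        unknown = set(rates) - set(ANOMALY_CLASSES)
        if unknown:
            raise ValueError(f"unknown anomaly classes: {sorted(unknown)}")
        for c in ANOMALY_CLASSES:
            rates.setdefault(c, 0.0)
        if any(not 0.0 <= r <= 1.0 for r in rates.values()):
            raise ValueError("anomaly rates must lie in [0, 1]")
        if sum(rates.values()) + self.missing_rate > 1.0:
            raise ValueError("combined anomaly + missing rates exceed 1")
        self.anomaly_rates = rates

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: a training herd, an independently
    seeded validation herd (a different batch on the same farm), and the
    thresholds of every processing stage."""

    sim: SimConfig = field(default_factory=SimConfig)

    # Validation batch: distinct seed, slightly perturbed herd means.
    n_validation: int = 150
    validation_seed: int = 1
    validation_bw_entry_shift: float = 0.3  # kg
    validation_adg_scale: float = 0.98

    # Stage thresholds.
    growth_r2_threshold: float = 0.8
    cfi_r2_threshold: float = 0.9
    cfi_start_window: tuple[float, float] = (25.0, 50.0)
    cfi_end_window: tuple[float, float] = (100.0, 140.0)

    # Sliding-window grid (kg) and the prediction window.
    window_sizes: tuple[int, ...] = tuple(range(10, 90, 10))
    weight_range: tuple[float, float] = (30.0, 120.0)
    prediction_window: tuple[float, float] = (80.0, 110.0)

    # Cross-validation.
    k_folds: tuple[int, ...] = (5, 10)
    cv_seed: int = 2024

    def __post_init__(self) -> None:
        if self.validation_seed == self.sim.seed:
            raise ValueError("training and validation seeds must differ")

    def validation_sim(self) -> SimConfig:
        return self.sim.replace(
            n_pigs=self.n_validation,
            seed=self.validation_seed,
            bw_entry_mean=self.sim.bw_entry_mean + self.validation_bw_entry_shift,
            adg_mean=self.sim.adg_mean * self.validation_adg_scale,
        )


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: PipelineConfig | SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig(**data)


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "sim" in data:
        data["sim"] = SimConfig(**data["sim"])
    _tupled(data, ("cfi_start_window", "cfi_end_window", "window_sizes",
                   "weight_range", "prediction_window", "k_folds"))
    return PipelineConfig(**data)
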