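"""Configuration objects for the synthetic woodland and the analysis pipeline.

``SimulationConfig`` holds every knob of the synthetic-data generator. Its
defaults describe the study system the package targets: a ~385 ha
mixed-deciduous woodland observed at 240 m resolution over 13 springs, with
~1200 nestboxes monitored for great tit and blue tit breeding. Units are
stated per field; days are day-of-year unless noted as day-of-April
(1 = 1 April), the scale on which tit laying dates are conventionally
reported.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import ConfigError

SPECIES = ("great_tit", "blue_tit")

#: canopy species and their woodland-wide mean shares of canopy cover
CANOPY_SHARES = {"oak": 0.27, "ash": 0.31, "beech": 0.14, "sycamore": 0.11, "other": 0.17}
#: understory species and their mean shares
UNDERSTORY_SHARES = {"hazel": 0.44, "hawthorn": 0.33, "elder": 0.07, "field_maple": 0.06, "other": 0.10}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic landscape, satellite and breeding generators."""

    # landscape
    grid_rows: int = 11
    grid_cols: int = 11
    pixel_size: float = 240.0  # m
    n_years: int = 13
    start_year: int = 2001
    n_nestboxes: int = 1200

    # vegetation green-up truth (day-of-year)
    mean_greenup: float = 110.0
    year_sd: float = 6.0          # sd of annual site-mean green-up, days
    spatial_sd: float = 3.0       # sd of the static spatial field, days
    spatial_range: float = 400.0  # Gaussian smoothing bandwidth, m
    greenup_noise_sd: float = 5.0  # independent pixel-by-year deviation, days

    # EVI2 seasonal curve and observation process
    evi_base: float = 0.2        # winter EVI2 level, index units
    evi_amplitude: float = 0.4   # summer increment, index units
    logistic_rate: float = 0.1   # per day
    senescence_day: float = 280.0
    obs_noise_sd: float = 0.02   # per-look EVI2 noise, index units
    looks_per_period: int = 16   # potential looks per pixel per 8-day period

    # cloudiness (% of looks obscured)
    cloud_winter: float = 79.0
    cloud_summer: float = 55.0
    cloud_year_sd: float = 8.0
    cloud_period_sd: float = 10.0

    # breeding generative model (laying on day-of-April scale)
    beta_within: float = 0.02    # d laying per d within-year green-up deviation
    beta_between: float = 0.315  # d laying per d annual mean green-up
    beta_altitude: float = 0.028  # d per m
    beta_edge: float = 0.003      # d per m from woodland edge
    beta_oak: float = -0.043      # d per oak tree within 75 m
    oak_coupling_gain: float = 25.0  # dimensionless; scales beta_within with oak density
    residual_sd: float = 4.0
    year_re_sd: float = 2.0
    box_re_sd: float = 1.5
    mean_laying: float = 21.0     # target mean great tit laying date, day-of-April
    blue_tit_offset: float = -1.5  # blue tits lay slightly earlier
    occupancy: float = 0.35       # P(box occupied) per species per year
    female_known_prob: float = 0.8
    female_return_prob: float = 0.5
    mean_clutch: float = 8.5
    incubation_days: int = 13

    # caterpillar half-fall (day-of-year)
    halffall_mean: float = 146.0
    halffall_slope: float = 0.8   # d half-fall per d annual mean green-up
    halffall_noise_sd: float = 4.4

    # oak trees within a 75 m buffer at oak canopy proportion 1
    oak_density_scale: float = 110.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ConfigError("grid dimensions must be >= 2")
        if self.pixel_size <= 0 or self.n_years < 1 or self.n_nestboxes < 1:
            raise ConfigError("pixel_size, n_years and n_nestboxes must be positive")
        for name in ("year_sd", "spatial_sd", "greenup_noise_sd", "obs_noise_sd",
                     "cloud_year_sd", "cloud_period_sd", "residual_sd", "year_re_sd",
                     "box_re_sd", "halffall_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.evi_base < self.evi_base + self.evi_amplitude:
            raise ConfigError("require 0 < evi_base < evi_base + evi_amplitude")
        if self.senescence_day <= self.mean_greenup:
            raise ConfigError("senescence_day must exceed mean_greenup")
        if not 0 < self.occupancy <= 1:
            raise ConfigError("occupancy must be in (0, 1]")
        if self.looks_per_period < 1:
            raise ConfigError("looks_per_period must be >= 1")

    @property
    def n_pixels(self) -> int:
        return self.grid_rows * self.grid_cols

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineConfig:
    """Run-level configuration: paths, thresholds and switches for the CLI pipeline."""

    outdir: str = "phenosync_run"
    seed: int = 0
    species: tuple = SPECIES
    woodland_threshold: float = 0.5
    min_periods: int = 20     # non-missing 8-day periods required per pixel-year curve fit
    min_years: int = 6        # year-points required for a pixel synchrony coefficient
    window_min_len: int = 3   # cloud-window scan bounds, in 8-day periods
    window_max_len: int = 15
    window_horizon: int = 15
    brood_window_days: int = 30
    female_re: bool = False
    ci_bootstrap: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if isinstance(self.species, str):
            self.species = (self.species,)
        self.species = tuple(self.species)
        for sp in self.species:
            if sp not in SPECIES:
                raise ConfigError(f"unknown species {sp!r}; expected one of {SPECIES}")
        if not 0 <= self.woodland_threshold < 1:
            raise ConfigError("woodland_threshold must be in [0, 1)")
        if self.min_periods < 4:
            raise ConfigError("min_periods must be >= 4")
        if self.min_years < 3:
            raise ConfigError("min_years must be >= 3")
        if not 1 <= self.window_min_len <= self.window_max_len <= self.window_horizon:
            raise ConfigError("require 1 <= window_min_len <= window_max_len <= window_horizon")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = list(self.species)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
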