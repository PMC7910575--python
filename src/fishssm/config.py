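"""Run configuration: schema-validated YAML/JSON with no unknown keys."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .behaviour import TransitionParams
from .errors import ConfigurationError
from .inference import MCMCConfig, Priors
from .movement import MovementParams
from .noise import Calibration
from .observation import DetectionParams

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MovementSection(_Strict):
    hr_x: float = 0.0
    hr_y: float = 0.0
    k: float = 0.001
    radius: float = 100.0
    dt: float = 720.0

    def build(self) -> MovementParams:
        return MovementParams(**self.model_dump())


class TransitionSection(_Strict):
    p_day_noise: float = 0.5
    q_day_noise: float = 0.5
    p_day_silence: float = 0.5
    q_day_silence: float = 0.5
    p_night_noise: float = 0.5
    q_night_noise: float = 0.5
    p_night_silence: float = 0.5
    q_night_silence: float = 0.5

    def build(self) -> TransitionParams:
        return TransitionParams.from_probs(self.model_dump())


class DetectionSection(_Strict):
    d50: float = 150.0
    slope: float = -0.02
    emissions_per_step: int = 6

    def build(self) -> DetectionParams:
        return DetectionParams(**self.model_dump())


class NoiseSection(_Strict):
    sensitivity_db: float | None = None
    gain_db: float = 0.0
    full_scale_volts: float = 1.0
    threshold_factor: float = 1.8
    threshold_scale: str = "linear"
    basal_quantile: float = 0.25
    basal_spl: float | None = None  # manual override of the basal estimate

    def build_calibration(self) -> Calibration:
        if self.sensitivity_db is None:
            raise ConfigurationError(
                "noise.sensitivity_db is required for audio processing"
            )
        return Calibration(
            sensitivity_db=self.sensitivity_db,
            gain_db=self.gain_db,
            full_scale_volts=self.full_scale_volts,
        )


class PriorSection(_Strict):
    logit_mean: float = 0.0
    logit_sd: float = 10.0
    logit_bound: float = 20.0
    radius_low: float = 50.0
    radius_high: float = 1000.0
    k_shape: float = 0.1
    k_scale: float = 0.1
    d50_low: float = -1000.0
    d50_high: float = 200.0
    log_neg_slope_mean: float = float(np.log(0.02))
    log_neg_slope_sd: float = 1.0
    centre_radius: float = 1000.0

    def build(self, centre_x: float = 0.0, centre_y: float = 0.0) -> Priors:
        return Priors(centre_x=centre_x, centre_y=centre_y, **self.model_dump())


class MCMCSection(_Strict):
    n_chains: int = 3
    n_keep: int = 10000
    burn_in: int = 1000
    thin: int = 10

    def build(self, seed: int) -> MCMCConfig:
        return MCMCConfig(seed=seed, **self.model_dump())


class SimulationSection(_Strict):
    scenario: str = "custom"  # shy | intermediate | bold | custom
    n_steps: int = 1000
    n_receivers: int = 14
    receiver_spacing: float = 150.0
    day_block: int = 60
    noise_prob: float = 0.085


class RunConfig(_Strict):
    seed: int = 0
    movement: MovementSection = MovementSection()
    transition: TransitionSection = TransitionSection()
    detection: DetectionSection = DetectionSection()
    noise: NoiseSection = NoiseSection()
    priors: PriorSection = PriorSection()
    mcmc: MCMCSection = MCMCSection()
    simulation: SimulationSection = SimulationSection()


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
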