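"""Schema-validated YAML run configuration.

Every physical quantity carries its unit in the key name (``pitch_m``,
``center_frequency_hz``, ...).  Unknown keys are rejected and all defaults
are materialized, so an echoed config is fully self-describing.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .exceptions import ConfigError
from .geometry import ReconGrid, make_grid, make_linear_probe
from .signals import PA, US_PLANEWAVE, make_pulse
from .simstudy import StudySetup, SweepConfig, five_channel_scene

__all__ = ["RunConfig", "load_config", "save_config", "default_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ProbeSection(_Section):
    n_elements: int = 128
    pitch_m: float = 100e-6
    center_x_m: float = 0.0

    @field_validator("pitch_m")
    @classmethod
    def _pitch_positive(cls, v):
        if v <= 0:
            raise ValueError("pitch_m must be positive")
        return v

    @field_validator("n_elements")
    @classmethod
    def _enough_elements(cls, v):
        if v < 2:
            raise ValueError("n_elements must be at least 2")
        return v


class GridSection(_Section):
    x_min_m: float = -375e-6
    x_max_m: float = 375e-6
    z_min_m: float = 14.925e-3
    z_max_m: float = 15.075e-3
    step_m: float = 12.5e-6

    @field_validator("step_m")
    @classmethod
    def _step_positive(cls, v):
        if v <= 0:
            raise ValueError("step_m must be positive")
        return v


class PulseSection(_Section):
    center_frequency_hz: float = 15e6
    fractional_bandwidth: float = 0.93
    sampling_rate_hz: float = 62.5e6


class SceneSection(_Section):
    n_sources: int = 5
    spacing_m: float = 125e-6
    depth_m: float = 15e-3
    modality: str = PA

    @field_validator("modality")
    @classmethod
    def _known_modality(cls, v):
        if v not in (PA, US_PLANEWAVE):
            raise ValueError(f"modality must be {PA!r} or {US_PLANEWAVE!r}")
        return v


class NoiseSection(_Section):
    sigma_n: float = 30.0

    @field_validator("sigma_n")
    @classmethod
    def _nonnegative(cls, v):
        if v < 0:
            raise ValueError("sigma_n must be nonnegative")
        return v


class SolverSection(_Section):
    alpha: float | None = None        # None: choose heuristically per run
    max_iters: int = 12000
    tolerance: float = 1e-10
    step_rule: str = "fixed_1_over_L"
    nonnegativity: bool = False
    support_budget: int = 8
    alpha_fractions: list[float] | None = None


class PostprocessSection(_Section):
    smooth_sigma_m: float = 12.5e-6
    fine_step_m: float = 3.125e-6
    peak_prominence_fraction: float = 0.05


class ForwardSection(_Section):
    c_m_per_s: float = 1500.0
    n_window_samples: int = 36
    t_start_s: float = 9.4e-6
    n_record_samples: int = 132


class SweepSection(_Section):
    N_values: list[int] = [2, 3, 4, 8, 16, 32, 64, 128]
    snr_values: list[float] = [0.5, 1.25, 3.1, 7.8, 19.4, 48.3, 120.5, 300.0]
    n_realizations: int = 100
    base_seed: int = 0


class RunConfig(_Section):
    probe: ProbeSection = ProbeSection()
    grid: GridSection = GridSection()
    pulse: PulseSection = PulseSection()
    scene: SceneSection = SceneSection()
    noise: NoiseSection = NoiseSection()
    solver: SolverSection = SolverSection()
    postprocess: PostprocessSection = PostprocessSection()
    forward: ForwardSection = ForwardSection()
    sweep: SweepSection = SweepSection()

    # -- object builders ---------------------------------------------------

    def make_probe(self):
        return make_linear_probe(
            self.probe.n_elements, self.probe.pitch_m, self.probe.center_x_m
        )

    def make_grid(self) -> ReconGrid:
        g = self.grid
        return make_grid(g.x_min_m, g.x_max_m, g.z_min_m, g.z_max_m, g.step_m)

    def make_pulse(self):
        p = self.pulse
        return make_pulse(
            p.center_frequency_hz, p.fractional_bandwidth, p.sampling_rate_hz
        )

    def make_scene(self):
        s = self.scene
        return five_channel_scene(
            spacing=s.spacing_m, depth=s.depth_m, n_sources=s.n_sources
        )

    def make_setup(self) -> StudySetup:
        return StudySetup(
            probe=self.make_probe(),
            grid=self.make_grid(),
            pulse=self.make_pulse(),
            scene=self.make_scene(),
            psf_position=(0.0, self.scene.depth_m),
            modality=self.scene.modality,
            c=self.forward.c_m_per_s,
            n_window_samples=self.forward.n_window_samples,
            t_start=self.forward.t_start_s,
            n_record_samples=self.forward.n_record_samples,
            smooth_sigma=self.postprocess.smooth_sigma_m,
            fine_step=self.postprocess.fine_step_m,
        )

    def make_sweep_config(self) -> SweepConfig:
        w = self.sweep
        return SweepConfig(
            N_values=tuple(w.N_values),
            snr_values=tuple(w.snr_values),
            n_realizations=w.n_realizations,
            base_seed=w.base_seed,
            sigma_n=self.noise.sigma_n,
            support_budget=self.solver.support_budget,
        )


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; schema violations raise
    :class:`ConfigError` naming the offending key."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"config key '{loc}': {first['msg']}") from exc


def save_config(path, cfg: RunConfig) -> None:
    """Write the fully-materialized, canonically-ordered config (so
    save → load → save round-trips byte-identically)."""
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(), sort_keys=True, default_flow_style=False)
    )
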