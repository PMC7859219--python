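"""Run configuration: strict YAML schema with centralized shipped defaults."""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .system import GhostMDError

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ToySection(_Strict):
    n_molecules: int = 32
    density: float = 1.3
    temperature: float = 300.0
    k_bond: float = 25.0
    r0: float = 0.9572
    k_angle: float = 2.4
    theta0: float = 1.82421813
    lj_epsilon: float = 0.025
    lj_sigma: float = 3.1507
    q_O: float = -0.834
    q_H: float = 0.417
    r_cut: float = 4.5
    ghost_A_H: float = 1.0
    ghost_sigma_H: float = 1.8
    ghost_A_O: float = 18.0
    ghost_sigma_O: float = 1.65

    def params(self):
        from .toy import ToyModelParams
        keys = ("k_bond", "r0", "k_angle", "theta0", "lj_epsilon", "lj_sigma",
                "q_O", "q_H", "r_cut", "ghost_A_H", "ghost_sigma_H",
                "ghost_A_O", "ghost_sigma_O")
        return ToyModelParams(**{k: getattr(self, k) for k in keys})


class ModelSection(_Strict):
    hidden: list[int] = [24, 24]
    epochs: int = 120
    lr: float = 0.01
    force_weight: float = 0.5
    batch_size: int | None = 32
    val_fraction: float = 0.1
    r_cut: float = 4.0
    r_cut_angular: float = 3.2

    def symmetry_set(self):
        from .descriptors import SymmetryFunctionSet
        return SymmetryFunctionSet(r_cut=self.r_cut,
                                   r_cut_angular=self.r_cut_angular)


class DynamicsSection(_Strict):
    dt: float = 0.5
    steps: int = 2000
    thermostat: str = "langevin"
    friction: float = 0.05
    pile_lambda: float = 0.5
    n_beads: int = 16
    stride: int = 10


class AlchemySection(_Strict):
    md_steps: int = 60
    n_sweeps: int = 200
    equil_sweeps: int = 20
    shell_radius: float = 3.5


class AnalysisSection(_Strict):
    grid_spacing: float = 0.4
    radius_threshold: float = 2.55
    pairing_cutoff: float = 6.0
    r_shell: float = 3.5
    rdf_bins: int = 60


class RunConfig(_Strict):
    toy: ToySection = ToySection()
    model: ModelSection = ModelSection()
    dynamics: DynamicsSection = DynamicsSection()
    alchemy: AlchemySection = AlchemySection()
    analysis: AnalysisSection = AnalysisSection()
    seed: int = 0
    output_dir: str = "runs"
    log_level: str = "INFO"


def default_config() -> RunConfig:
    """The shipped frozen defaults."""
    ref = importlib.resources.files("ghostmd.data") / "defaults.yaml"
    with ref.open() as fh:
        return RunConfig(**yaml.safe_load(fh))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; unknown keys are rejected."""
    if path is None:
        return default_config()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**data)
    except Exception as exc:
        raise GhostMDError(f"invalid configuration {path}: {exc}") from exc


def dump_resolved(config: RunConfig, outdir: str | Path) -> Path:
    """Write the fully resolved configuration next to the run outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
    return path
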