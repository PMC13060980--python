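"""Pipeline configuration: one YAML file with per-stage blocks."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ModelParams, Regimen, default_params, default_ranges
from .synth import SynthConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Settings driving the end-to-end pipeline.

    Every stage draws its randomness from a dedicated seed so reruns
    with an identical config reproduce identical artifacts.
    """

    out_dir: Path = Path("runs/default")
    params: ModelParams = field(default_factory=default_params)
    ranges: dict[str, tuple[float, float]] = field(default_factory=default_ranges)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seeds: dict[str, int] = field(
        default_factory=lambda: {"synth": 10, "fit": 20, "efast": 30, "cohort": 40}
    )
    n_candidates: int = 5000
    threshold_k: float = 2.0
    alpha: float = 0.05
    holdout: Regimen = Regimen.GEM_OT1
    n_lhs: int = 100
    efast_ns: int = 257
    efast_nr: int = 2
    profile_grid: int = 21
    profile_subsets: tuple[tuple[str, ...], ...] = (("nCT", "rCM", "kGM"),)
    run_fit: bool = True
    run_profiles: bool = True
    run_efast: bool = True

    def __post_init__(self) -> None:
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name, value in self.seeds.items():
            if int(value) != value:
                raise ValueError(f"seed {name} must be an integer")

    @property
    def generation_regimens(self) -> tuple[Regimen, ...]:
        return tuple(r for r in Regimen if r is not self.holdout)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "out_dir" in raw:
            kwargs["out_dir"] = Path(raw["out_dir"])
        if "params_file" in raw:
            pfile = Path(raw["params_file"])
            if not pfile.exists():
                raise FileNotFoundError(pfile)
            kwargs["params"] = ModelParams.from_file(pfile)
        elif "params" in raw:
            kwargs["params"] = ModelParams.from_dict(raw["params"])
        if "ranges" in raw:
            kwargs["ranges"] = {
                k: (float(v[0]), float(v[1])) for k, v in raw["ranges"].items()
            }
        if "synth" in raw:
            kwargs["synth"] = SynthConfig(**raw["synth"])
        if "holdout" in raw:
            kwargs["holdout"] = Regimen(raw["holdout"])
        for key in (
            "seeds",
            "n_candidates",
            "threshold_k",
            "alpha",
            "n_lhs",
            "efast_ns",
            "efast_nr",
            "profile_grid",
            "run_fit",
            "run_profiles",
            "run_efast",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "profile_subsets" in raw:
            kwargs["profile_subsets"] = tuple(tuple(s) for s in raw["profile_subsets"])
        return cls(**kwargs)
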