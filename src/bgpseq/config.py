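"""Run configuration: one YAML file describing a full pipeline run.

The effective (merged) configuration is always written back to the output
directory so every artifact records the seeds and settings that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .encoder import EncoderConfig
from .synthetic_ehr import CohortSpec
from .train_infer import HeadConfig, TrainingConfig
from .variational import PriorSpec


@dataclass(frozen=True)
class EvalConfig:
    n_mc_draws: int = 30
    n_bootstrap: int = 50
    n_bins: int = 10
    sample_latent: bool = True   # GP heads: sample inducing posterior per draw
    threshold_start: float = 0.5
    threshold_stop: float = 0.95
    threshold_step: float = 0.05


@dataclass
class RunConfig:
    variant: str = "DBGP"
    seed: int = 0
    out_dir: str = "runs/default"
    cohort_path: str | None = None       # if set, load instead of simulating
    cohort: CohortSpec = field(default_factory=CohortSpec)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    fine_tune_epochs: int = 4
    fine_tune_learning_rate: float = 3e-5
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["risk_tokens"] = {
            str(k): v for k, v in d["cohort"]["risk_tokens"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = dict(d.get("cohort", {}))
        if "risk_tokens" in cohort:
            cohort["risk_tokens"] = {int(k): float(v)
                                     for k, v in cohort["risk_tokens"].items()}
        for key in ("n_visits_range", "codes_per_visit_range"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        enc = dict(d.get("encoder", {}))
        head = dict(d.get("head", {}))
        if "prior" in head:
            head["prior"] = PriorSpec(**head["prior"])
        if "grid_bounds" in head:
            head["grid_bounds"] = tuple(head["grid_bounds"])
        training = dict(d.get("training", {}))
        if "split" in training:
            training["split"] = tuple(training["split"])
        ev = dict(d.get("evaluation", {}))
        return cls(
            variant=d.get("variant", "DBGP"),
            seed=int(d.get("seed", 0)),
            out_dir=d.get("out_dir", "runs/default"),
            cohort_path=d.get("cohort_path"),
            cohort=CohortSpec(**cohort),
            encoder=EncoderConfig(**enc),
            head=HeadConfig(**head),
            training=TrainingConfig(**training),
            fine_tune_epochs=int(d.get("fine_tune_epochs", 4)),
            fine_tune_learning_rate=float(d.get("fine_tune_learning_rate", 3e-5)),
            evaluation=EvalConfig(**ev),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def roundtrip_equal(config: RunConfig, path: str | Path) -> bool:
    config.write(path)
    return RunConfig.read(path).to_dict() == config.to_dict()
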