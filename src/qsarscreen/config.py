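"""Pipeline configuration: validated, YAML round-trippable."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .containers import ValidationError
from .models import ALGORITHMS
from .synthetic_data import SyntheticSpec


@dataclass
class PipelineConfig:
    """Everything a full run needs, from one master seed.

    Either ``synthetic`` drives data generation, or the three input paths
    (compounds/descriptors/fingerprints CSV) must be set.
    """

    out_dir: str = "runs/run"
    master_seed: int = 0

    # inputs: synthetic spec or CSV paths
    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    compounds_csv: str | None = None
    descriptors_csv: str | None = None
    fingerprints_csv: str | None = None

    # curation
    boundary_um: float = 1.0
    exclude_range_um: tuple[float, float] | None = None
    dedup_aggregate: str = "median"

    # feature selection
    correlation_threshold: float = 0.85
    boruta_iterations: int = 100
    boruta_alpha: float = 0.05

    # models
    test_fraction: float = 0.2
    hyperparameters: dict[str, dict] = field(default_factory=dict)

    # validation
    ad_components: int = 2
    ad_margin: float = 0.0
    yrand_runs: int = 100
    yrand_fraction: float = 0.5
    yrand_algorithm: str = "random_forest"

    # screening
    library_size: int = 1000
    library_frac_shifted: float = 0.3
    library_shift: float = 10.0
    probability_threshold: float = 0.5
    novelty_threshold: float = 0.5

    def validate(self) -> None:
        checks = [
            (self.boundary_um > 0, "boundary_um must be positive"),
            (0 < self.correlation_threshold <= 1, "correlation_threshold must be in (0, 1]"),
            (self.boruta_iterations >= 20, "boruta_iterations must be >= 20"),
            (0 < self.boruta_alpha < 1, "boruta_alpha must be in (0, 1)"),
            (0 < self.test_fraction < 1, "test_fraction must be in (0, 1)"),
            (self.ad_components >= 1, "ad_components must be >= 1"),
            (self.ad_margin >= 0, "ad_margin must be >= 0"),
            (self.yrand_runs >= 1, "yrand_runs must be >= 1"),
            (0 < self.yrand_fraction <= 1, "yrand_fraction must be in (0, 1]"),
            (self.yrand_algorithm in ALGORITHMS, f"yrand_algorithm must be one of {ALGORITHMS}"),
            (0 <= self.probability_threshold <= 1, "probability_threshold must be in [0, 1]"),
            (0 <= self.novelty_threshold <= 1, "novelty_threshold must be in [0, 1]"),
            (self.library_size >= 1, "library_size must be >= 1"),
            (0 <= self.library_frac_shifted <= 1, "library_frac_shifted must be in [0, 1]"),
        ]
        errors = [msg for ok, msg in checks if not ok]
        if self.synthetic is None and not (
            self.compounds_csv and self.descriptors_csv and self.fingerprints_csv
        ):
            errors.append("either synthetic spec or all three input CSV paths required")
        unknown = set(self.hyperparameters) - set(ALGORITHMS)
        if unknown:
            errors.append(f"hyperparameters for unknown algorithms: {sorted(unknown)}")
        if errors:
            raise ValidationError("; ".join(errors))

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        if self.exclude_range_um is not None:
            d["exclude_range_um"] = list(self.exclude_range_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticSpec.from_dict(d["synthetic"])
        if d.get("exclude_range_um") is not None:
            d["exclude_range_um"] = tuple(d["exclude_range_um"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
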