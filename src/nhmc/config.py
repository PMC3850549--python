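"""Run configuration with the standard experimental defaults.

Defaults reproduce the canonical experimental protocol for this family of
learners: minimum of 5 examples per leaf, F-test significance candidates
{0.001, 0.005, 0.01, 0.05, 0.1, 0.125} selected by internal 3-fold
cross-validation, precision–recall thresholds from 0 to 1 in steps of 0.02,
uniform 1/|C| AUPRC weighting, and binary edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

__all__ = ["RunConfig", "DEFAULT_SIGNIFICANCE_LEVELS"]

DEFAULT_SIGNIFICANCE_LEVELS: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05, 0.1, 0.125)


@dataclass
class RunConfig:
    """All knobs of a training/evaluation run."""

    alpha: float = 0.5
    w0: float = 0.75
    min_leaf: int = 5
    significance_levels: tuple[float, ...] = DEFAULT_SIGNIFICANCE_LEVELS
    tau_step: float = 0.02
    aupr_weighting: str = "uniform"  # "uniform" (1/|C|) or "frequency"
    edge_mode: str = "binary"        # "binary" or "weighted"
    min_degree: int = 15             # highly-connected threshold for degree filtering
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 < self.w0 < 1.0:
            raise ValueError(f"w0 must lie in (0, 1), got {self.w0}")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if isinstance(self.significance_levels, (int, float)):
            self.significance_levels = (float(self.significance_levels),)
        self.significance_levels = tuple(float(s) for s in self.significance_levels)
        if not self.significance_levels or not all(
            0.0 < s < 1.0 for s in self.significance_levels
        ):
            raise ValueError("significance levels must lie in (0, 1)")
        if not 0.0 < self.tau_step <= 1.0:
            raise ValueError("tau_step must lie in (0, 1]")
        if self.aupr_weighting not in ("uniform", "frequency"):
            raise ValueError("aupr_weighting must be 'uniform' or 'frequency'")
        if self.edge_mode not in ("binary", "weighted"):
            raise ValueError("edge_mode must be 'binary' or 'weighted'")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    @classmethod
    def from_sources(cls, config_file=None, **overrides) -> "RunConfig":
        """Build from an optional YAML file plus explicit overrides.

        Overrides with value ``None`` are ignored, so command-line flags can
        be layered over the file and the file over the defaults.
        """
        values: dict = {}
        if config_file is not None:
            with open(config_file) as fh:
                loaded = yaml.safe_load(fh) or {}
            unknown = set(loaded) - set(cls.field_names())
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def estimator_params(self) -> dict:
        """Keyword arguments for :class:`~nhmc.induction.NetworkHMCClassifier`."""
        sig = (
            self.significance_levels[0]
            if len(self.significance_levels) == 1
            else list(self.significance_levels)
        )
        return {
            "alpha": self.alpha,
            "w0": self.w0,
            "min_leaf": self.min_leaf,
            "significance": sig,
            "random_state": self.seed,
        }
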