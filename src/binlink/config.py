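"""Linkage project configuration: one structured file for the whole run.

Covers the Bloom parameters, blocking strategies, field comparison specs,
classification thresholds, bin planning, de-duplication policy, and the
retry policy of the matching jobs.  Serialized as YAML; the secret key is
held as hex and should be supplied per project.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .blocking import BlockingStrategy, default_strategies
from .encoding import BloomParams
from .matching import (ClassificationThresholds, FieldComparisonSpec,
                       default_field_specs, default_thresholds)

__all__ = ["RetryPolicy", "LinkageConfig", "default_config"]


@dataclass(frozen=True)
class RetryPolicy:
    """Matching-job retry policy: five attempts by default; timed-out jobs
    are not retried — they fail the run with a resumable state file."""

    max_attempts: int = 5
    timeout_seconds: float = 600.0

    def __post_init__(self) -> None:
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.timeout_seconds <= 0:
            raise ValueError("timeout_seconds must be positive")


@dataclass(frozen=True)
class LinkageConfig:
    secret_key: bytes
    filter_length_bits: int = 512
    num_hashes: int = 30
    strategies: tuple[BlockingStrategy, ...] = field(
        default_factory=default_strategies)
    field_specs: tuple[FieldComparisonSpec, ...] = field(
        default_factory=default_field_specs)
    thresholds: ClassificationThresholds = field(
        default_factory=default_thresholds)
    max_bin_space: int = 5000
    discard_rule: str = "space"          # or "frequency"
    dedupe_keep: str = "max_score"       # or "first"
    estimate_u_from_data: bool = True
    retry: RetryPolicy = field(default_factory=RetryPolicy)

    @property
    def bloom_params(self) -> BloomParams:
        return BloomParams(self.secret_key, self.filter_length_bits,
                           self.num_hashes)

    @property
    def strategy_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.strategies)

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(s.field for s in self.field_specs)

    def with_field_u(self, u_by_field: dict[str, float]) -> "LinkageConfig":
        """Return a copy whose field specs use the given u estimates."""
        specs = tuple(
            replace(s, u=u_by_field.get(s.field, s.u)) for s in self.field_specs
        )
        return replace(self, field_specs=specs)

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "secret_key_hex": self.secret_key.hex(),
            "bloom": {"filter_length_bits": self.filter_length_bits,
                      "num_hashes": self.num_hashes},
            "strategies": [
                {"name": s.name,
                 "components": [list(c) for c in s.components]}
                for s in self.strategies
            ],
            "fields": [
                {"field": s.field, "comparator": s.comparator, "m": s.m,
                 "u": s.u, "t_low": s.t_low, "t_high": s.t_high}
                for s in self.field_specs
            ],
            "thresholds": {"match": self.thresholds.match,
                           "potential": self.thresholds.potential},
            "binning": {"max_bin_space": self.max_bin_space,
                        "discard_rule": self.discard_rule},
            "pairs": {"dedupe_keep": self.dedupe_keep},
            "estimate_u_from_data": self.estimate_u_from_data,
            "retry": {"max_attempts": self.retry.max_attempts,
                      "timeout_seconds": self.retry.timeout_seconds},
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "LinkageConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            secret_key=bytes.fromhex(doc["secret_key_hex"]),
            filter_length_bits=doc["bloom"]["filter_length_bits"],
            num_hashes=doc["bloom"]["num_hashes"],
            strategies=tuple(
                BlockingStrategy(s["name"],
                                 tuple(tuple(c) for c in s["components"]))
                for s in doc["strategies"]
            ),
            field_specs=tuple(
                FieldComparisonSpec(f["field"], f["comparator"], f["m"],
                                    f["u"], f["t_low"], f["t_high"])
                for f in doc["fields"]
            ),
            thresholds=ClassificationThresholds(
                doc["thresholds"]["match"], doc["thresholds"]["potential"]),
            max_bin_space=doc["binning"]["max_bin_space"],
            discard_rule=doc["binning"]["discard_rule"],
            dedupe_keep=doc["pairs"]["dedupe_keep"],
            estimate_u_from_data=doc["estimate_u_from_data"],
            retry=RetryPolicy(doc["retry"]["max_attempts"],
                              doc["retry"]["timeout_seconds"]),
        )


def default_config(secret_key: bytes = b"binlink-demo-key") -> LinkageConfig:
    return LinkageConfig(secret_key=secret_key)
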