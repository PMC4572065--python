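"""Run configuration: one YAML file carrying every analysis threshold.

The zero-config run uses the defaults below, which are the thresholds of
the validated-assay protocol (coverage 50, SNP quality 30, neighbourhood
quality 20, 25% minor-variant frequency, polymorphism in >=2 sources,
50 bp spacing, 50-60 bp flanks, designability 0.6, R mean 0.2, cluster
separation 0.3-0.45, 10% missingness, 4 trio errors, 5% MAF, 0.5
heterozygote-excess probability).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .probes import ProbeDesignConfig
from .qc import QcThresholds

__all__ = ["RunConfig", "Violation", "validate_config", "THRESHOLD_REGISTRY"]

#: the canonical defaults, in one place so docs and tests can cross-check
THRESHOLD_REGISTRY: dict[str, float | int | str] = {
    "probe.min_coverage": 50,
    "probe.min_snp_quality": 30,
    "probe.min_neighbourhood_quality": 20,
    "probe.min_variant_freq": 25,
    "probe.min_sources": 2,
    "probe.min_gap": 50,
    "probe.min_flank": 50,
    "probe.preferred_flank": 60,
    "probe.min_designability": 0.6,
    "qc.fail_rmean": 0.2,
    "qc.fail_separation": 0.3,
    "qc.review_separation_hi": 0.45,
    "qc.max_missing": 0.10,
    "qc.max_trio_errors": 4,
    "qc.min_maf": 0.05,
    "qc.het_excess_p": 0.5,
}

_STAGES = ("simulate", "design", "qc", "diversity", "amova")


@dataclass
class Violation:
    field: str
    value: object
    allowed: str

    def __str__(self) -> str:
        return f"{self.field}={self.value!r} (allowed: {self.allowed})"


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    stages: tuple[str, ...] = _STAGES
    seed: int = 0
    out_dir: str = "ecotype_out"
    # input paths (unused by stages that consume upstream outputs)
    genotypes: str | None = None
    accessions: str | None = None
    variants: str | None = None
    contigs: str | None = None
    blast: str | None = None
    cluster_stats: str | None = None
    probe: ProbeDesignConfig = field(default_factory=ProbeDesignConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    simulation: dict = field(default_factory=dict)
    n_permutations: int = 999
    n_components: int = 5
    top_k: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        probe = ProbeDesignConfig(**raw.pop("probe", {}))
        qc_cfg = QcThresholds(**raw.pop("qc", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = [k for k in raw if k not in known]
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        cfg = cls(probe=probe, qc=qc_cfg, **raw)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def validate_config(config: RunConfig) -> list[Violation]:
    """Return all violations (empty list means the config is usable)."""
    v: list[Violation] = []
    for stage in config.stages:
        if stage not in _STAGES:
            v.append(Violation("stages", stage, "/".join(_STAGES)))
    ranges = {
        "probe.min_coverage": (config.probe.min_coverage, 0, float("inf")),
        "probe.min_snp_quality": (config.probe.min_snp_quality, 0, float("inf")),
        "probe.min_neighbourhood_quality": (
            config.probe.min_neighbourhood_quality, 0, float("inf")),
        "probe.min_variant_freq": (config.probe.min_variant_freq, 0, 100),
        "probe.min_designability": (config.probe.min_designability, 0, 1),
        "qc.fail_rmean": (config.qc.fail_rmean, 0, float("inf")),
        "qc.fail_separation": (config.qc.fail_separation, 0, 1),
        "qc.review_separation_hi": (config.qc.review_separation_hi, 0, 1),
        "qc.max_missing": (config.qc.max_missing, 0, 1),
        "qc.min_maf": (config.qc.min_maf, 0, 0.5),
        "qc.het_excess_p": (config.qc.het_excess_p, 0, 1),
    }
    for name, (value, lo, hi) in ranges.items():
        if not (lo <= value <= hi):
            v.append(Violation(name, value, f"[{lo}, {hi}]"))
    if config.qc.max_trio_errors < 0:
        v.append(Violation("qc.max_trio_errors", config.qc.max_trio_errors, ">= 0"))
    if config.n_permutations < 1:
        v.append(Violation("n_permutations", config.n_permutations, ">= 1"))

    needs_inputs = {
        "design": ("variants", "contigs", "blast"),
        "qc": ("genotypes",),
        "diversity": ("genotypes", "accessions"),
        "amova": ("genotypes", "accessions"),
    }
    simulated = "simulate" in config.stages
    for stage, fields in needs_inputs.items():
        if stage not in config.stages or simulated:
            continue  # simulate feeds downstream stages in-memory
        for name in fields:
            path = getattr(config, name)
            if path is None:
                v.append(Violation(name, None, f"path required for stage {stage!r}"))
            elif not Path(path).exists():
                v.append(Violation(name, path, "existing file"))
    return v
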