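"""Run-level configuration for the profiling pipeline.

One parameter block per stage; every threshold used downstream is named here
with its analysis-record default, so a run is fully described by a single
:class:`PipelineConfig` plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class ApmsParams:
    """Interactor filtering, imputation and quantification settings.

    ``impute_percentile`` is 5 for the phosphatase-inhibitor workflow and 1
    for the mutant/DIA workflows; both are percentiles of the observed
    log-intensity distribution used to center left-censored imputation.
    """

    saint_threshold: float = 0.90
    impute_percentile: float = 5.0
    max_single_missing_per_condition: int = 1
    top_n_peptides: int = 2
    equal_var: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.saint_threshold <= 1.0:
            raise ValidationError("saint_threshold must lie in [0, 1]")
        if not 0.0 < self.impute_percentile < 100.0:
            raise ValidationError("impute_percentile must lie in (0, 100)")
        if self.top_n_peptides < 1:
            raise ValidationError("top_n_peptides must be >= 1")


@dataclass
class KineticsParams:
    """Fuzzy c-means settings for treatment time-course profiles."""

    n_clusters: int = 3
    fuzzifier: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    restarts: int = 10

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if self.fuzzifier <= 1.0:
            raise ValidationError("fuzzifier must be > 1")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")


@dataclass
class PeakParams:
    """Migration-peak detection thresholds.

    ``width`` is the FWHM (in fractions) of the Gaussian smoothing kernel and
    also the merge radius for nearby maxima.  ``loc_any_fraction`` /
    ``loc_per_fraction`` implement the two-level phosphosite localization
    filter (score > 0.8 in at least one fraction; per-fraction score > 0.5).
    """

    min_norm_intensity_protein: float = 0.2
    min_norm_intensity_phospho: float = 0.3
    width: float = 2.0
    loc_any_fraction: float = 0.8
    loc_per_fraction: float = 0.5

    def validate(self) -> None:
        for name in ("min_norm_intensity_protein", "min_norm_intensity_phospho"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.width <= 0:
            raise ValidationError("width must be > 0")
        for name in ("loc_any_fraction", "loc_per_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass
class ClusterParams:
    """Hierarchical clustering of split traces into co-migration modules."""

    k_min: int = 2
    k_max: int = 15
    linkage: str = "average"
    silhouette_metric: str = "correlation-distance"  # or "euclidean"

    def validate(self) -> None:
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValidationError("require 1 <= k_min <= k_max")
        if self.linkage not in {"average", "complete", "single"}:
            raise ValidationError(f"unknown linkage {self.linkage!r}")
        if self.silhouette_metric not in {"correlation-distance", "euclidean"}:
            raise ValidationError(f"unknown silhouette metric {self.silhouette_metric!r}")


@dataclass
class IntegrationParams:
    """Association-classification thresholds (strict inequalities)."""

    fc_down: float = -1.0
    fc_up: float = 1.0
    p_max: float = 0.05
    use_q: bool = False

    def validate(self) -> None:
        if not self.fc_down < 0 < self.fc_up:
            raise ValidationError("require fc_down < 0 < fc_up")
        if not 0.0 < self.p_max < 1.0:
            raise ValidationError("p_max must lie in (0, 1)")


@dataclass
class PrmParams:
    """Targeted-PRM peak-group acceptance and quantification rules."""

    rt_tolerance_fraction: float = 0.05
    min_dotp: float = 0.75
    min_sn: float = 5.0
    quant_top_fragments: int = 3
    normalization_mode: str = "bait_peptides"  # or "housekeeping_irt", "tag_peptide"

    def validate(self) -> None:
        if self.rt_tolerance_fraction <= 0:
            raise ValidationError("rt_tolerance_fraction must be > 0")
        if not 0.0 < self.min_dotp <= 1.0:
            raise ValidationError("min_dotp must lie in (0, 1]")
        if self.min_sn < 0:
            raise ValidationError("min_sn must be >= 0")
        if self.quant_top_fragments < 1:
            raise ValidationError("quant_top_fragments must be >= 1")
        if self.normalization_mode not in {"bait_peptides", "housekeeping_irt", "tag_peptide"}:
            raise ValidationError(f"unknown normalization mode {self.normalization_mode!r}")


@dataclass
class PipelineConfig:
    """Full run description: stage parameters, seed, paths, fraction count."""

    seed: int = 0
    fraction_count: int = 64
    bait_id: str = "BAIT"
    input_dir: str | None = None
    output_dir: str = "phoscomplex_run"
    apms: ApmsParams = field(default_factory=ApmsParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    prm: PrmParams = field(default_factory=PrmParams)

    def validate(self) -> None:
        if self.fraction_count < 2:
            raise ValidationError("fraction_count must be >= 2")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        for block in (self.apms, self.kinetics, self.peaks, self.clustering,
                      self.integration, self.prm):
            block.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable short hash of the full configuration, for provenance headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        blocks = {
            "apms": ApmsParams, "kinetics": KineticsParams, "peaks": PeakParams,
            "clustering": ClusterParams, "integration": IntegrationParams, "prm": PrmParams,
        }
        kwargs = {}
        for key, value in d.items():
            if key in blocks:
                kwargs[key] = blocks[key](**value)
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
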