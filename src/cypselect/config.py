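"""Pipeline configuration: every numeric threshold in one serializable place.

All decision thresholds used downstream (plate QC, hit calling, inhibitor
selectivity, substrate classification) live in small frozen dataclasses that
round-trip losslessly through JSON.  ``PipelineConfig.config_hash()`` gives a
stable digest that is stamped into every output file header so results can be
traced to the exact configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

logger = logging.getLogger("cypselect")

ENZYMES = ("CYP3A7", "CYP3A4")


class ConfigurationError(ValueError):
    """Raised for inconsistent generator or pipeline configuration."""


class DegenerateControlsError(ValueError):
    """Raised when plate controls cannot anchor normalization (V_DMSO == V_pos)."""


class CorrectionUnavailableWarning(UserWarning):
    """Warned when a plate stack has no all-DMSO plates to correct against."""


@dataclass(frozen=True)
class QCThresholds:
    """Plate acceptance thresholds: S/B >= 3.0, CV <= 10.0 %, Z' >= 0.5."""

    min_signal_to_background: float = 3.0
    max_cv_pct: float = 10.0
    min_z_prime: float = 0.5


@dataclass(frozen=True)
class HitThresholds:
    """Curve-class and hit-calling knobs.

    ``efficacy_pct`` is the strict ``>50 %`` bound that promotes a partial
    (class 2.2) curve to a hit.  ``noise_band_pct`` is the activity noise
    floor below which a series is flat (class 4); the effective band is the
    larger of this and ``noise_band_sd_mult`` times the DMSO-well SD when one
    is available.  ``full_efficacy_pct`` splits high- from low-efficacy
    classes (1.1 vs 1.2, 2.1 vs 2.2); ``plateau_tol_frac`` is the fraction of
    the fitted span within which a data point counts as supporting an
    asymptote; ``min_r2`` gates partial curves.
    """

    efficacy_pct: float = 50.0
    noise_band_pct: float = 20.0
    noise_band_sd_mult: float = 3.0
    full_efficacy_pct: float = 80.0
    plateau_tol_frac: float = 0.05
    min_r2: float = 0.9


@dataclass(frozen=True)
class SelectivityThresholds:
    """Inhibitor selectivity rule: potency <= 1 µM, |efficacy| >= 65 %, >= 10-fold."""

    max_potency_um: float = 1.0
    min_efficacy_pct: float = 65.0
    min_fold_ratio: float = 10.0
    #: IC50 assigned to an inactive counterpart (pIC50 4.0 sentinel).
    inactive_sentinel_um: float = 100.0


@dataclass(frozen=True)
class SubstrateThresholds:
    """Substrate classification: fast if t1/2 <= 30 min, selective if the
    counterpart exceeds the 120-min censoring horizon."""

    fast_t_half_min: float = 30.0
    censor_t_half_min: float = 120.0
    #: points below this % remaining are below the limit of quantification
    loq_pct: float = 1.0
    #: one-sided p-value above which a negative slope is not credible
    max_slope_p: float = 0.05
    #: t1/2 <= 30 counts as fast (set False for the strict "<" reading)
    boundary_inclusive: bool = True


@dataclass(frozen=True)
class DepletionAssay:
    """Incubation constants for intrinsic clearance scaling."""

    volume_ul: float = 110.0
    cyp_amount_pmol: float = 3.0
    time_points_min: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 30.0, 60.0)


@dataclass(frozen=True)
class TitrationSpec:
    """11-point log-spaced titration spanning 3.5 nM – 58 µM."""

    n_points: int = 11
    min_um: float = 0.0035
    max_um: float = 58.0

    def concentrations(self) -> np.ndarray:
        if self.n_points < 2 or self.min_um <= 0 or self.max_um <= self.min_um:
            raise ConfigurationError("titration must be >=2 increasing positive points")
        return np.geomspace(self.min_um, self.max_um, self.n_points)


@dataclass(frozen=True)
class SOMSpec:
    """Self-organizing-map grid configuration.

    ``rows``/``cols`` of 0 means size the grid at train time so the expected
    occupancy is ~``target_occupancy`` compounds per node (the published
    5,000-compound / 508-cluster ratio).
    """

    rows: int = 0
    cols: int = 0
    topology: str = "hex"  # "hex" | "rect"
    epochs: int = 10
    target_occupancy: float = 10.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Synthetic-study scale used by the demo pipeline."""

    n_compounds: int = 500
    n_clusters: int = 10
    n_fingerprint_bits: int = 1024
    noise_cv: float = 0.10
    wells_per_plate_rows: int = 16
    wells_per_plate_cols: int = 24
    mu_dmso: float = 3000.0
    mu_pos: float = 100.0
    n_dmso_plates_leading: int = 2
    n_dmso_plates_trailing: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    qc: QCThresholds = field(default_factory=QCThresholds)
    hit: HitThresholds = field(default_factory=HitThresholds)
    selectivity: SelectivityThresholds = field(default_factory=SelectivityThresholds)
    substrate: SubstrateThresholds = field(default_factory=SubstrateThresholds)
    depletion: DepletionAssay = field(default_factory=DepletionAssay)
    titration: TitrationSpec = field(default_factory=TitrationSpec)
    som: SOMSpec = field(default_factory=SOMSpec)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    seed: int = 0

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in _SUBCONFIGS:
                sub = _SUBCONFIGS[f.name]
                sub_kwargs = dict(v)
                for sf in dataclasses.fields(sub):
                    if sf.name in sub_kwargs and isinstance(sub_kwargs[sf.name], list):
                        sub_kwargs[sf.name] = tuple(sub_kwargs[sf.name])
                kwargs[f.name] = sub(**sub_kwargs)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_json(cls, s: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(s))

    def config_hash(self) -> str:
        """12-hex-digit digest of the canonical JSON form."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


_SUBCONFIGS = {
    "qc": QCThresholds,
    "hit": HitThresholds,
    "selectivity": SelectivityThresholds,
    "substrate": SubstrateThresholds,
    "depletion": DepletionAssay,
    "titration": TitrationSpec,
    "som": SOMSpec,
    "synthetic": SyntheticSpec,
}
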