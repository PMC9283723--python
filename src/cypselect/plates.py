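"""Plate QC, stack correction, control normalization and series assembly.

Normalization follows the inhibition-assay convention:

    % Activity = (V_compound - V_DMSO) / (V_DMSO - V_pos) * 100

with ``V_DMSO``/``V_pos`` the per-plate *medians* of the DMSO and positive
(ketoconazole-level) control wells, so a read at the DMSO median is 0 % and a
read at the positive-control median is −100 %.  QC statistics (Z', S/B, CV)
use means and population SDs, the conventional estimator set for plate
quality metrics.

The stack correction is a documented substitute for unpublished proprietary
plate-correction algorithms: per-well background profiles are taken from the
all-DMSO plates that bracket the compound stack (each DMSO plate's reads
divided by its own median, so profiles are scale-free), linearly interpolated
across stack position, and divided out of every compound plate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    CorrectionUnavailableWarning,
    DegenerateControlsError,
    QCThresholds,
)
from .synthetic import RawPlate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ControlStats:
    """Per-plate control aggregates (medians anchor normalization)."""

    v_dmso: float
    v_pos: float
    sd_dmso: float
    sd_pos: float

    def __post_init__(self) -> None:
        if self.v_dmso == self.v_pos:
            raise DegenerateControlsError("V_DMSO equals V_pos; cannot normalize")


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    s_b: float
    cv_pct: float
    z_prime: float
    pass_s_b: bool
    pass_cv: bool
    pass_z_prime: bool

    @property
    def passed(self) -> bool:
        return self.pass_s_b and self.pass_cv and self.pass_z_prime


def control_stats(plate: RawPlate) -> ControlStats:
    dmso = plate.role_reads("dmso")
    pos = plate.role_reads("positive")
    if len(dmso) < 2 or len(pos) < 2:
        raise DegenerateControlsError("need >= 2 wells of each control role")
    return ControlStats(
        v_dmso=float(np.median(dmso)),
        v_pos=float(np.median(pos)),
        sd_dmso=float(np.std(dmso)),
        sd_pos=float(np.std(pos)),
    )


def compute_plate_qc(plate: RawPlate, thresholds: QCThresholds = QCThresholds()) -> PlateQC:
    """Z' = 1 - 3(sd_pos + sd_dmso)/|mean_dmso - mean_pos|; CV on DMSO wells;
    S/B = mean_dmso / mean_pos."""
    dmso = plate.role_reads("dmso")
    pos = plate.role_reads("positive")
    if len(dmso) < 2 or len(pos) < 2:
        raise DegenerateControlsError("need >= 2 wells of each control role")
    mean_dmso, mean_pos = float(np.mean(dmso)), float(np.mean(pos))
    sd_dmso, sd_pos = float(np.std(dmso)), float(np.std(pos))
    sep = abs(mean_dmso - mean_pos)
    if sep == 0:
        raise DegenerateControlsError("control means coincide; Z' undefined")
    if mean_pos == 0:
        raise DegenerateControlsError("zero positive-control mean; S/B undefined")
    z_prime = 1.0 - 3.0 * (sd_pos + sd_dmso) / sep
    cv = 100.0 * sd_dmso / mean_dmso
    s_b = mean_dmso / mean_pos
    return PlateQC(
        plate_id=plate.plate_id,
        s_b=s_b,
        cv_pct=cv,
        z_prime=z_prime,
        pass_s_b=s_b >= thresholds.min_signal_to_background,
        pass_cv=cv <= thresholds.max_cv_pct,
        pass_z_prime=z_prime >= thresholds.min_z_prime,
    )


def qc_report(stack: list[RawPlate], thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """One QC row per plate (all-DMSO plates are skipped: no positive wells differ)."""
    rows = []
    for plate in stack:
        if plate.concentration_index is None:
            continue
        qc = compute_plate_qc(plate, thresholds)
        rows.append(
            {
                "plate_id": qc.plate_id,
                "enzyme": plate.enzyme,
                "s_b": qc.s_b,
                "cv_pct": qc.cv_pct,
                "z_prime": qc.z_prime,
                "pass_s_b": qc.pass_s_b,
                "pass_cv": qc.pass_cv,
                "pass_z_prime": qc.pass_z_prime,
                "passed": qc.passed,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        # per-run aggregate CV is also of interest (run-level CV can exceed the
        # per-plate bound); report it in the log rather than failing the run
        logger.info(
            "QC: %d/%d plates pass; mean CV %.2f%%",
            int(df["passed"].sum()),
            len(df),
            float(df["cv_pct"].mean()),
        )
    return df


def percent_activity(read, controls: ControlStats):
    """Signed % activity of a read (scalar or array) against plate controls."""
    return 100.0 * (np.asarray(read, dtype=float) - controls.v_dmso) / (
        controls.v_dmso - controls.v_pos
    )


# ---------------------------------------------------------------------------
# stack correction
# ---------------------------------------------------------------------------

def correct_plate_stack(stack: list[RawPlate]) -> list[RawPlate]:
    """Remove per-well spatial background using the bracketing DMSO plates.

    Each all-DMSO plate yields a scale-free per-well profile (reads divided
    by the plate median); profiles are linearly interpolated across stack
    position and divided out of every compound plate.  DMSO plates pass
    through unchanged.  Without any all-DMSO plate the stack is returned
    uncorrected with a :class:`CorrectionUnavailableWarning`.
    """
    dmso_plates = [p for p in stack if p.concentration_index is None]
    if not dmso_plates:
        warnings.warn(
            "no all-DMSO plates in stack; returning uncorrected reads",
            CorrectionUnavailableWarning,
        )
        return stack
    positions = np.array([p.stack_position for p in dmso_plates], dtype=float)
    order = np.argsort(positions)
    positions = positions[order]
    profiles = np.stack(
        [dmso_plates[i].reads / np.median(dmso_plates[i].reads) for i in order]
    )  # (n_dmso, R, C)

    out: list[RawPlate] = []
    for plate in stack:
        if plate.concentration_index is None:
            out.append(plate)
            continue
        pos = float(plate.stack_position)
        if pos <= positions[0]:
            profile = profiles[0]
        elif pos >= positions[-1]:
            profile = profiles[-1]
        else:
            j = int(np.searchsorted(positions, pos) - 1)
            w = (pos - positions[j]) / (positions[j + 1] - positions[j])
            profile = (1.0 - w) * profiles[j] + w * profiles[j + 1]
        corrected = RawPlate(
            plate_id=plate.plate_id,
            enzyme=plate.enzyme,
            reads=plate.reads / profile,
            roles=plate.roles,
            compound_ids=plate.compound_ids,
            concentration_index=plate.concentration_index,
            concentration_um=plate.concentration_um,
            stack_position=plate.stack_position,
            corrected=True,
        )
        out.append(corrected)
    return out


# ---------------------------------------------------------------------------
# normalization and series assembly
# ---------------------------------------------------------------------------

def normalize_stack(stack: list[RawPlate]) -> pd.DataFrame:
    """Normalize every compound well against its own plate's control medians.

    Returns a long DataFrame (compound_id, enzyme, concentration_um,
    activity_pct)."""
    rows = []
    for plate in stack:
        if plate.concentration_index is None:
            continue
        ctrl = control_stats(plate)
        mask = (plate.roles == "compound") & (plate.compound_ids != None)  # noqa: E711
        acts = percent_activity(plate.reads[mask], ctrl)
        for cid, a in zip(plate.compound_ids[mask], acts):
            rows.append(
                {
                    "compound_id": cid,
                    "enzyme": plate.enzyme,
                    "concentration_um": plate.concentration_um,
                    "activity_pct": float(a),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ConcentrationResponse:
    """Per compound-enzyme titration, sorted ascending, duplicates averaged."""

    compound_id: str
    enzyme: str
    concentrations_um: np.ndarray
    activities_pct: np.ndarray
    fittable: bool = True

    def __len__(self) -> int:
        return len(self.concentrations_um)


def assemble_concentration_series(
    wells: pd.DataFrame, min_points: int = 4
) -> list[ConcentrationResponse]:
    """Group normalized wells into per compound-enzyme series.

    Series with fewer than ``min_points`` distinct concentrations are flagged
    unfittable (they fall through to curve class 4 downstream).
    """
    series: list[ConcentrationResponse] = []
    for (cid, enzyme), grp in wells.groupby(["compound_id", "enzyme"], sort=True):
        agg = (
            grp.groupby("concentration_um", sort=True)["activity_pct"]
            .mean()
            .reset_index()
        )
        series.append(
            ConcentrationResponse(
                compound_id=str(cid),
                enzyme=str(enzyme),
                concentrations_um=agg["concentration_um"].to_numpy(dtype=float),
                activities_pct=agg["activity_pct"].to_numpy(dtype=float),
                fittable=len(agg) >= min_points,
            )
        )
    return series
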