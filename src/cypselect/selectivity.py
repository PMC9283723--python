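"""Cross-enzyme inhibitor selectivity and the signed-potency scatter encoding.

A compound is CYP3A7-selective when its CYP3A7 IC50 is at most 1 µM, its
absolute CYP3A7 efficacy at least 65 %, and its CYP3A4 IC50 at least 10-fold
higher (or CYP3A4 is inactive, in which case the fold ratio is computed
against the 100 µM inactive sentinel); the mirror-image rule defines
CYP3A4-selectivity.  The scatter encoding maps inhibitors to +pIC50
(−log10 of IC50 in molar), activators to −pIC50, and inactives to exactly
4.0 (the 100 µM sentinel); inconclusive calls are not plotted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .config import SelectivityThresholds
from .crc import ActivityCall, HillFit

logger = logging.getLogger(__name__)

INACTIVE_SENTINEL_PIC50 = 4.0

CATEGORIES = (
    "CYP3A7_selective",
    "CYP3A4_selective",
    "common_inhibitor",
    "common_activator",
    "mixed_direction",
    "one_enzyme_only",
    "not_classified",
)


@dataclass(frozen=True)
class SelectivityCall:
    category: str
    fold_ratio: float | None   # IC50(counterpart)/IC50(target); None when undefined


@dataclass(frozen=True)
class EnzymeResult:
    """Minimal per-enzyme summary the selectivity stage needs."""

    activity: str        # active | inactive | inconclusive
    direction: str       # inhibitor | activator | none
    ic50_um: float | None
    efficacy_pct: float | None

    @classmethod
    def from_fit(cls, call: ActivityCall, fit: HillFit) -> "EnzymeResult":
        return cls(call.value, call.direction, fit.ac50_um, fit.efficacy_pct)


def encode_signed_potency(result: EnzymeResult) -> float | None:
    """Signed pIC50 encoding; None (absent from the plot) for inconclusive."""
    if result.activity == "inactive":
        return INACTIVE_SENTINEL_PIC50
    if result.activity == "inconclusive":
        return None
    pic50 = -math.log10(result.ic50_um * 1e-6)
    return pic50 if result.direction == "inhibitor" else -pic50


def _meets_target_criteria(
    r: EnzymeResult, thresholds: SelectivityThresholds
) -> bool:
    return (
        r.ic50_um is not None
        and r.ic50_um <= thresholds.max_potency_um
        and r.efficacy_pct is not None
        and abs(r.efficacy_pct) >= thresholds.min_efficacy_pct
    )


def classify_inhibitor_selectivity(
    result_3a7: EnzymeResult,
    result_3a4: EnzymeResult,
    thresholds: SelectivityThresholds = SelectivityThresholds(),
) -> SelectivityCall:
    """Assign the cross-enzyme inhibitor category for one compound.

    Inactive counterparts contribute the 100 µM sentinel IC50 to the fold
    ratio, so a potent single-enzyme inhibitor remains eligible for the
    selective category.  Inconclusive calls on either enzyme propagate to
    ``not_classified``.
    """
    a7, a4 = result_3a7, result_3a4
    if a7.activity == "inconclusive" or a4.activity == "inconclusive":
        return SelectivityCall("not_classified", None)
    if a7.activity == "inactive" and a4.activity == "inactive":
        return SelectivityCall("not_classified", None)

    sentinel = thresholds.inactive_sentinel_um

    def effective_ic50(r: EnzymeResult) -> float:
        return sentinel if r.activity == "inactive" else float(r.ic50_um)

    # single-direction bookkeeping
    d7 = a7.direction if a7.activity == "active" else "none"
    d4 = a4.direction if a4.activity == "active" else "none"

    if d7 == "activator" and d4 == "activator":
        return SelectivityCall("common_activator", None)
    if {d7, d4} == {"activator", "inhibitor"}:
        return SelectivityCall("mixed_direction", None)

    # at least one inhibitor from here on
    ic7, ic4 = effective_ic50(a7), effective_ic50(a4)
    if d7 == "inhibitor":
        fold_for_3a7 = ic4 / ic7
        if (
            _meets_target_criteria(a7, thresholds)
            and fold_for_3a7 >= thresholds.min_fold_ratio
        ):
            return SelectivityCall("CYP3A7_selective", fold_for_3a7)
    if d4 == "inhibitor":
        fold_for_3a4 = ic7 / ic4
        if (
            _meets_target_criteria(a4, thresholds)
            and fold_for_3a4 >= thresholds.min_fold_ratio
        ):
            return SelectivityCall("CYP3A4_selective", fold_for_3a4)

    if d7 == "inhibitor" and d4 == "inhibitor":
        return SelectivityCall("common_inhibitor", ic4 / ic7)
    # exactly one enzyme shows any activity but the selective bar is not met
    fold = ic4 / ic7 if d7 != "none" else ic7 / ic4
    return SelectivityCall("one_enzyme_only", fold if "inhibitor" in (d7, d4) else None)


def assign_quadrant(p_3a7: float, p_3a4: float) -> tuple[str, str]:
    """Quadrant label and boundary-box flag for the signed-potency scatter.

    Quadrants are taken relative to the 4.0 inactive sentinel on each axis
    (values above 4 = inhibition, negative values = activation).  The
    boundary flag marks points sitting exactly on one sentinel axis, i.e.
    compounds active on exactly one enzyme.
    """
    x, y = p_3a7, p_3a4  # plotting convention: CYP3A7 on x, CYP3A4 on y
    vert = "top" if y >= INACTIVE_SENTINEL_PIC50 else "bottom"
    horiz = "right" if x >= INACTIVE_SENTINEL_PIC50 else "left"
    quadrant = f"{vert}_{horiz}"
    on7 = p_3a7 == INACTIVE_SENTINEL_PIC50
    on4 = p_3a4 == INACTIVE_SENTINEL_PIC50
    if on7 and not on4:
        flag = "CYP3A4_specific"
    elif on4 and not on7:
        flag = "CYP3A7_specific"
    else:
        flag = "none"
    return quadrant, flag


def selectivity_table(
    crc_results: pd.DataFrame,
    thresholds: SelectivityThresholds = SelectivityThresholds(),
) -> pd.DataFrame:
    """Combine per-enzyme fit results into the per-compound selectivity table.

    ``crc_results`` is the output of :func:`cypselect.crc.analyze_series`
    covering both enzymes.  Compounds evaluated on only one enzyme are
    skipped.
    """
    rows = []
    by_enzyme = {
        enz: grp.set_index("compound_id")
        for enz, grp in crc_results.groupby("enzyme")
    }
    if "CYP3A7" not in by_enzyme or "CYP3A4" not in by_enzyme:
        return pd.DataFrame()
    common_ids = by_enzyme["CYP3A7"].index.intersection(by_enzyme["CYP3A4"].index)
    for cid in common_ids:
        res = {}
        for enz in ("CYP3A7", "CYP3A4"):
            r = by_enzyme[enz].loc[cid]
            res[enz] = EnzymeResult(
                activity=r["activity"],
                direction=r["direction"],
                ic50_um=None if pd.isna(r["ac50_um"]) else float(r["ac50_um"]),
                efficacy_pct=float(r["efficacy_pct"]),
            )
        call = classify_inhibitor_selectivity(res["CYP3A7"], res["CYP3A4"], thresholds)
        p7 = encode_signed_potency(res["CYP3A7"])
        p4 = encode_signed_potency(res["CYP3A4"])
        quadrant, flag = (
            assign_quadrant(p7, p4) if p7 is not None and p4 is not None else (None, None)
        )
        rows.append(
            {
                "compound_id": cid,
                "ic50_3a7_um": res["CYP3A7"].ic50_um,
                "efficacy_3a7_pct": res["CYP3A7"].efficacy_pct,
                "activity_3a7": res["CYP3A7"].activity,
                "ic50_3a4_um": res["CYP3A4"].ic50_um,
                "efficacy_3a4_pct": res["CYP3A4"].efficacy_pct,
                "activity_3a4": res["CYP3A4"].activity,
                "signed_potency_3a7": p7,
                "signed_potency_3a4": p4,
                "category": call.category,
                "fold_ratio": call.fold_ratio,
                "quadrant": quadrant,
                "boundary_flag": flag,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        logger.info(
            "selectivity: %s",
            df["category"].value_counts().to_dict(),
        )
    return df
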