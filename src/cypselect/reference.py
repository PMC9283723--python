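"""Published reference measurements used as worked examples.

Two small panels of literature-reported dual-enzyme (CYP3A7 vs CYP3A4)
measurements ship with the package so that the classification rules can be
exercised on real printed numbers without any external files:

* :func:`inhibitor_reference_panel` — five confirmed CYP3A7-selective
  inhibitors with mean IC50 (µM) and efficacy (%) against both enzymes.
* :func:`substrate_reference_panel` — twenty-two CYP3A7-selective substrates
  with supersome half-lives (min); the CYP3A4 half-life is censored at the
  120-min reporting horizon for every row.

``SCREEN_COUNTS`` holds the published bookkeeping counts of the 1,000-compound
metabolic-stability follow-up (number of compounds with usable MS data,
per-enzyme substrate counts, overlap, and CYP3A4-selective count), from which
the headline substrate percentages are recomputed.

``DESCRIPTOR_GROUP_PROFILES`` are published group-level descriptor statistics
(mean, SD) for common / CYP3A4-selective / CYP3A7-selective inhibitor hits;
the synthetic generator uses them as default per-group sampling profiles.
A ``None`` SD marks a binary indicator sampled as Bernoulli(mean).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "inhibitor_reference_panel",
    "substrate_reference_panel",
    "SCREEN_COUNTS",
    "DESCRIPTOR_GROUP_PROFILES",
]

_INHIBITOR_ROWS = [
    # compound, IC50_3A7 (µM), efficacy_3A7 (%), IC50_3A4 (µM), efficacy_3A4 (%)
    ("Halometasone", 0.43, -91.0, 14.9, -71.0),
    ("AIM-100", 0.45, -98.0, 17.2, -65.0),
    ("Gestodene", 0.61, -65.0, 13.1, -71.0),
    ("C891-1,173", 0.77, -89.0, 15.3, -48.0),
    ("Furazabol", 0.97, -68.0, 19.3, -42.0),
]

_SUBSTRATE_ROWS = [
    # compound, t1/2 CYP3A7 (min); CYP3A4 t1/2 is ">120" (censored) for all rows
    ("Asparagine Monohydrate", 5.6),
    ("Fenoldopam", 9.0),
    ("Eucalyptol", 9.2),
    ("Etofylline", 11.0),
    ("DB-07268", 11.6),
    ("Famciclovir", 13.8),
    ("Glutamine", 14.3),
    ("Todralazine", 15.4),
    ("Clevudine", 15.4),
    ("Cotinine", 15.9),
    ("Idasanutlin", 18.0),
    ("AZD-1283", 18.1),
    ("Tylosin", 18.2),
    ("MK-8245", 18.9),
    ("Piconol", 19.4),
    ("TC-G 1006", 19.9),
    ("Nicoboxil", 24.4),
    ("Tandutinib", 24.5),
    ("Levocarnitine", 25.5),
    ("Alisertib", 27.3),
    ("AP-768", 28.7),
    ("Iopromide", 29.2),
]

#: Published metabolic-stability bookkeeping counts.
SCREEN_COUNTS = {
    "ms_measured": 1015,          # compounds with usable MS data
    "cyp3a7_substrates": 223,     # t1/2 <= 30 min in CYP3A7
    "cyp3a4_substrates": 452,     # t1/2 <= 30 min in CYP3A4
    "overlap_substrates": 159,    # substrates of both enzymes
    "cyp3a4_selective": 293,      # CYP3A4 substrates not shared with CYP3A7
}


def inhibitor_reference_panel() -> pd.DataFrame:
    """Return the five-row reference inhibitor panel as a DataFrame."""
    return pd.DataFrame(
        _INHIBITOR_ROWS,
        columns=[
            "compound_id",
            "ic50_3a7_um",
            "efficacy_3a7_pct",
            "ic50_3a4_um",
            "efficacy_3a4_pct",
        ],
    )


def substrate_reference_panel() -> pd.DataFrame:
    """Return the 22-row reference substrate panel.

    ``t_half_3a4_min`` is ``inf`` with ``censored_3a4=True`` for every row,
    mirroring the ">120 min" reporting convention.
    """
    df = pd.DataFrame(_SUBSTRATE_ROWS, columns=["compound_id", "t_half_3a7_min"])
    df["t_half_3a4_min"] = float("inf")
    df["censored_3a4"] = True
    return df


#: Default descriptor sampling profiles per inhibitor-selectivity group.
#: Values are (mean, sd); sd=None means a Bernoulli binary indicator.
DESCRIPTOR_GROUP_PROFILES: dict[str, dict[str, tuple[float, float | None]]] = {
    "common": {
        "slogp": (4.0, 2.0),
        "mol_weight": (406.0, 117.0),
        "tpsa": (83.0, 41.0),
        "hbd": (2.0, 1.0),
        "hba": (4.0, 3.0),
        "frac_aromatic_bonds": (0.5, 0.2),
        "n_aromatic_rings": (3.0, 1.0),
        "steroid_indicator": (0.002, None),
    },
    "CYP3A4": {
        "slogp": (4.0, 2.0),
        "mol_weight": (411.0, 137.0),
        "tpsa": (83.0, 45.0),
        "hbd": (2.0, 2.0),
        "hba": (5.0, 3.0),
        "frac_aromatic_bonds": (0.5, 0.2),
        "n_aromatic_rings": (3.0, 1.0),
        "steroid_indicator": (0.002, None),
    },
    "CYP3A7": {
        "slogp": (3.0, 2.0),
        "mol_weight": (355.0, 102.0),
        "tpsa": (76.0, 41.0),
        "hbd": (1.0, 1.0),
        "hba": (4.0, 2.0),
        "frac_aromatic_bonds": (0.4, 0.2),
        "n_aromatic_rings": (2.0, 1.0),
        "steroid_indicator": (0.012, None),
    },
    # compounds outside the three published hit groups reuse the common profile
    "other": {
        "slogp": (4.0, 2.0),
        "mol_weight": (400.0, 120.0),
        "tpsa": (82.0, 42.0),
        "hbd": (2.0, 1.5),
        "hba": (4.0, 3.0),
        "frac_aromatic_bonds": (0.5, 0.2),
        "n_aromatic_rings": (3.0, 1.0),
        "steroid_indicator": (0.003, None),
    },
}
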