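"""CSV interchange schemas.

All tabular artifacts move as plain CSV.  Every file written by the pipeline
starts with a single comment header line ``# cypselect config=<hash> seed=<n>``
so results are traceable to the configuration that produced them; readers
skip ``#`` lines.  Concentrations are serialized in µM, times in minutes,
and censored half-lives as the literal string ``">120"``.

Plate stacks use a long per-well schema: plate_id, enzyme, stack_position,
concentration_index, concentration_um, row, col, role, compound_id, read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import RawPlate

logger = logging.getLogger(__name__)

PLATE_COLUMNS = [
    "plate_id",
    "enzyme",
    "stack_position",
    "concentration_index",
    "concentration_um",
    "row",
    "col",
    "role",
    "compound_id",
    "read",
]


def write_csv(df: pd.DataFrame, path: str | Path, config_hash: str = "", seed: int | None = None) -> Path:
    """Write a DataFrame with the traceability header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# cypselect config={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping ``#`` header lines."""
    return pd.read_csv(path, comment="#")


def plates_to_frame(stack: list[RawPlate]) -> pd.DataFrame:
    cols: dict[str, list] = {c: [] for c in PLATE_COLUMNS}
    for plate in stack:
        n_rows, n_cols = plate.reads.shape
        n = n_rows * n_cols
        rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
        cols["plate_id"].extend([plate.plate_id] * n)
        cols["enzyme"].extend([plate.enzyme] * n)
        cols["stack_position"].extend([plate.stack_position] * n)
        ci = np.nan if plate.concentration_index is None else plate.concentration_index
        cum = np.nan if plate.concentration_um is None else plate.concentration_um
        cols["concentration_index"].extend([ci] * n)
        cols["concentration_um"].extend([cum] * n)
        cols["row"].extend(rr.ravel().tolist())
        cols["col"].extend(cc.ravel().tolist())
        cols["role"].extend(plate.roles.ravel().tolist())
        cols["compound_id"].extend(plate.compound_ids.ravel().tolist())
        cols["read"].extend(plate.reads.ravel().tolist())
    return pd.DataFrame(cols)


def frame_to_plates(df: pd.DataFrame) -> list[RawPlate]:
    """Rebuild RawPlate objects from the long per-well schema.

    Schema violations raise ``ValueError`` naming the offending column.
    """
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV is missing columns: {missing}")
    plates = []
    for plate_id, grp in df.groupby("plate_id", sort=False):
        n_rows = int(grp["row"].max()) + 1
        n_cols = int(grp["col"].max()) + 1
        reads = np.zeros((n_rows, n_cols))
        roles = np.full((n_rows, n_cols), "compound", dtype=object)
        ids = np.full((n_rows, n_cols), None, dtype=object)
        r = grp["row"].to_numpy(dtype=int)
        c = grp["col"].to_numpy(dtype=int)
        reads[r, c] = grp["read"].to_numpy(dtype=float)
        roles[r, c] = grp["role"].to_numpy()
        cid = grp["compound_id"].to_numpy(dtype=object)
        cid = np.where(pd.isna(cid), None, cid)
        ids[r, c] = cid
        ci = grp["concentration_index"].iloc[0]
        cum = grp["concentration_um"].iloc[0]
        plates.append(
            RawPlate(
                plate_id=str(plate_id),
                enzyme=str(grp["enzyme"].iloc[0]),
                reads=reads,
                roles=roles,
                compound_ids=ids,
                concentration_index=None if pd.isna(ci) else int(ci),
                concentration_um=None if pd.isna(cum) else float(cum),
                stack_position=int(grp["stack_position"].iloc[0]),
            )
        )
    plates.sort(key=lambda p: p.stack_position)
    return plates


def read_smiles_file(path: str | Path) -> pd.DataFrame:
    """Read a .smi file (SMILES [whitespace] id per line)."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        rows.append(
            {"smiles": parts[0], "compound_id": parts[1] if len(parts) > 1 else f"CPD-{i}"}
        )
    return pd.DataFrame(rows)


def read_sdf_file(path: str | Path) -> pd.DataFrame:
    """Read an SDF via RDKit, returning compound_id + SMILES."""
    from rdkit import Chem  # noqa: PLC0415

    rows = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"CPD-{i}"
        rows.append({"compound_id": cid, "smiles": Chem.MolToSmiles(mol)})
    return pd.DataFrame(rows)
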