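"""Chemical-space clustering and activity enrichment.

Compounds are clustered by binary structural fingerprint with a
self-organizing map (SOM): a grid of prototype vectors trained with online
Kohonen updates (Gaussian neighborhood, linearly decaying radius and
learning rate, Euclidean distance on the bit vectors).  Each occupied node
is then tested for enrichment or depletion of active compounds with one-sided
Fisher exact (hypergeometric) tests, and the results are summarized as a
signed heat value, ``sign * -log10(min p)``, positive for enrichment —
the standard coloring for hexagonal cluster heat maps.

Descriptor distributions across selectivity groups are compared with one-way
ANOVA followed by Tukey HSD; binary indicator descriptors are additionally
summarized as per-group frequencies.

The SOM is implemented here because no pre-installed library provides one;
it is deliberately the plain online algorithm, deterministic under a fixed
seed and presentation order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .config import ConfigurationError, SOMSpec

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# self-organizing map
# ---------------------------------------------------------------------------

@dataclass
class SOMGrid:
    rows: int
    cols: int
    topology: str              # "hex" | "rect"
    codebook: np.ndarray       # (rows*cols, n_bits)
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_positions(self) -> np.ndarray:
        """(n_nodes, 2) planar coordinates used for neighborhood distances."""
        rr, cc = np.divmod(np.arange(self.n_nodes), self.cols)
        x = cc.astype(float)
        y = rr.astype(float)
        if self.topology == "hex":
            x = x + 0.5 * (rr % 2)       # offset alternate rows
            y = y * (math.sqrt(3.0) / 2.0)
        return np.column_stack([x, y])


def grid_shape_for(n_compounds: int, spec: SOMSpec) -> tuple[int, int]:
    """Resolve the grid shape; auto-size for ~target_occupancy per node."""
    if spec.rows > 0 and spec.cols > 0:
        return spec.rows, spec.cols
    n_nodes = max(1, round(n_compounds / spec.target_occupancy))
    rows = max(1, int(math.sqrt(n_nodes)))
    cols = max(1, int(math.ceil(n_nodes / rows)))
    return rows, cols


def train_som(
    fingerprints: np.ndarray,
    rows: int,
    cols: int,
    topology: str = "hex",
    epochs: int = 10,
    seed: int = 0,
    lr_start: float = 0.5,
    lr_end: float = 0.01,
) -> SOMGrid:
    """Train a SOM on a (n, n_bits) binary fingerprint matrix.

    Online Kohonen updates over ``epochs`` shuffled passes; the neighborhood
    radius decays linearly from half the larger grid dimension to 0.5 and
    the learning rate from ``lr_start`` to ``lr_end``.  Deterministic for a
    fixed seed.
    """
    X = np.asarray(fingerprints, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ConfigurationError("fingerprint matrix is empty")
    if rows < 1 or cols < 1 or epochs < 1:
        raise ConfigurationError("grid dimensions and epochs must be >= 1")
    n, n_bits = X.shape
    n_nodes = rows * cols
    rng = np.random.default_rng(seed)

    if n >= n_nodes:
        codebook = X[rng.choice(n, n_nodes, replace=False)].copy()
    else:
        codebook = rng.random((n_nodes, n_bits))

    grid = SOMGrid(rows, cols, topology, codebook, seed)
    pos = grid.node_positions()
    grid_d2 = cdist(pos, pos) ** 2

    sigma_start = max(rows, cols) / 2.0
    sigma_end = 0.5
    total = epochs * n
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / max(total - 1, 1)
            lr = lr_start + (lr_end - lr_start) * frac
            sigma = sigma_start + (sigma_end - sigma_start) * frac
            x = X[i]
            bmu = int(np.argmin(np.einsum("ij,ij->i", codebook - x, codebook - x)))
            h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
            codebook += (lr * h)[:, None] * (x - codebook)
            step += 1
    logger.info("trained %dx%d %s SOM on %d compounds", rows, cols, topology, n)
    return grid


def assign_clusters(fingerprints: np.ndarray, grid: SOMGrid) -> np.ndarray:
    """Best-matching node per compound; ties break to the lowest node index."""
    X = np.asarray(fingerprints, dtype=float)
    if X.shape[1] != grid.codebook.shape[1]:
        raise ConfigurationError("fingerprint dimension does not match codebook")
    d = cdist(X, grid.codebook)
    return np.argmin(d, axis=1)  # argmin returns the first (lowest) index on ties


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    assignment: np.ndarray,
    active: np.ndarray,
    grid: SOMGrid | None = None,
) -> pd.DataFrame:
    """Per-cluster one-sided Fisher exact enrichment/depletion tests.

    For each occupied node the 2x2 table (in/out of cluster x active/
    inactive) is tested hypergeometrically in both directions:
    ``p_enrich = P(X >= k_in)`` and ``p_deplete = P(X <= k_in)``.  The heat
    value is ``-log10`` of the smaller p, signed positive for enrichment.
    A Benjamini-Hochberg column over ``2 * min(p)`` is provided for users;
    the heat coloring itself uses the raw p-values.
    """
    assignment = np.asarray(assignment)
    active = np.asarray(active, dtype=bool)
    if assignment.shape != active.shape:
        raise ConfigurationError("assignment and activity flags differ in length")
    N = len(assignment)
    K = int(active.sum())
    rows = []
    for node in np.unique(assignment):
        in_cluster = assignment == node
        n_in = int(in_cluster.sum())
        k_in = int((in_cluster & active).sum())
        n_out = N - n_in
        k_out = K - k_in
        p_enrich = float(stats.hypergeom.sf(k_in - 1, N, K, n_in))
        p_deplete = float(stats.hypergeom.cdf(k_in, N, K, n_in))
        num = k_in * (n_out - k_out)
        den = (n_in - k_in) * k_out
        if den == 0:
            odds = math.inf if num > 0 else math.nan
        else:
            odds = num / den
        if p_enrich <= p_deplete:
            heat = -math.log10(p_enrich)
        else:
            heat = math.log10(p_deplete)
        row = {"cluster": int(node), "n_in": n_in, "k_in": k_in,
               "n_out": n_out, "k_out": k_out,
               "odds_ratio": float(odds),
               "p_enrich": p_enrich, "p_deplete": p_deplete, "heat": heat}
        if grid is not None:
            row["grid_row"], row["grid_col"] = divmod(int(node), grid.cols)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        p_two = np.clip(2.0 * df[["p_enrich", "p_deplete"]].min(axis=1), 0.0, 1.0)
        df["p_bh"] = multipletests(p_two, method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# descriptor-group comparison
# ---------------------------------------------------------------------------

def compare_descriptor_groups(
    table: pd.DataFrame,
    group_col: str = "group",
    descriptors: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-descriptor group means ± SD, one-way ANOVA and Tukey HSD.

    Returns ``(summary, pairwise)``: one summary row per descriptor x group
    (with the shared ANOVA F and p), and one pairwise row per descriptor x
    group pair with the Tukey-adjusted p.  A descriptor constant across all
    groups is reported with p = 1 and ``degenerate=True``.  Binary (0/1)
    descriptors also get a per-group frequency column.
    """
    if descriptors is None:
        descriptors = [
            c
            for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    groups = [g for g, grp in table.groupby(group_col) if len(grp) >= 2]
    if len(groups) < 2:
        raise ConfigurationError("need >= 2 groups with >= 2 members each")
    sub = table[table[group_col].isin(groups)]

    summary_rows, pairwise_rows = [], []
    for desc in descriptors:
        samples = [sub.loc[sub[group_col] == g, desc].to_numpy(dtype=float) for g in groups]
        values = np.concatenate(samples)
        is_binary = set(np.unique(values)).issubset({0.0, 1.0})
        degenerate = np.all(values == values[0])
        if degenerate:
            f_stat, p_val = np.nan, 1.0
        else:
            f_stat, p_val = stats.f_oneway(*samples)
        for g, s in zip(groups, samples):
            row = {
                "descriptor": desc,
                "group": g,
                "n": len(s),
                "mean": float(np.mean(s)),
                "sd": float(np.std(s, ddof=1)),
                "anova_f": float(f_stat) if np.isfinite(f_stat) else np.nan,
                "anova_p": float(p_val),
                "degenerate": bool(degenerate),
            }
            if is_binary:
                row["frequency"] = float(np.mean(s))
            summary_rows.append(row)
        if not degenerate:
            tk = pairwise_tukeyhsd(
                values, sub[group_col].to_numpy(), alpha=0.05
            )
            res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
            for _, r in res.iterrows():
                pairwise_rows.append(
                    {
                        "descriptor": desc,
                        "group1": r["group1"],
                        "group2": r["group2"],
                        "p_adj": float(r["p-adj"]),
                    }
                )
        else:
            for i, g1 in enumerate(groups):
                for g2 in groups[i + 1 :]:
                    pairwise_rows.append(
                        {"descriptor": desc, "group1": g1, "group2": g2, "p_adj": 1.0}
                    )
    return pd.DataFrame(summary_rows), pd.DataFrame(pairwise_rows)


# ---------------------------------------------------------------------------
# structure mode
# ---------------------------------------------------------------------------

def fingerprints_from_smiles(smiles: list[str], n_bits: int = 1024) -> np.ndarray:
    """1024-bit hashed path fingerprints from SMILES (structure mode).

    Requires RDKit; unparseable SMILES raise ``ValueError``.
    """
    try:
        from rdkit import Chem  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover
        raise ImportError("structure mode requires rdkit") from exc
    out = np.zeros((len(smiles), n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES at row {i}: {smi!r}")
        fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
        out[i, list(fp.GetOnBits())] = 1
    return out
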