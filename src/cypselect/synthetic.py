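"""Synthetic qHTS study generator with a ground-truth registry.

Emulates an inhibition-format P450-Glo luminescence screen run against two
recombinant CYP enzymes (CYP3A7 and CYP3A4): compound wells report a signal
between the DMSO negative-control level (0 % activity) and the ketoconazole
positive-control level (−100 % activity, fully inhibited), a substrate
depletion panel sampled at the standard 0/5/10/15/30/60 min time points, a
fingerprint library organised into structural clusters with planted activity
enrichment, and per-group physicochemical descriptor tables.

Every latent parameter (true AC50, Hill slope, efficacy, depletion rate,
cluster label) is recorded per compound so downstream stages can be tested
as round trips against known truth.  All draws flow from one
``numpy.random.Generator`` seeded explicitly: identical seeds give
byte-identical outputs.

Signal model
------------
A compound well's mean read is ``V = mu_dmso + (a/100) * (mu_dmso - mu_pos)``
where ``a`` is the noise-free % activity from the compound's Hill curve at
that well's concentration (negative for inhibition, positive for
activation).  Noise is multiplicative Gaussian with a fixed CV, because
luminescence noise scales with intensity.  An optional separable row x column
gradient, optionally drifting linearly across the plate stack, models the
spatial artifacts the correction stage must remove.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, ENZYMES
from .reference import DESCRIPTOR_GROUP_PROFILES

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class EnzymeTruth:
    """Latent concentration-response and depletion truth for one enzyme."""

    direction: str = "inactive"          # inhibitor | activator | inactive
    ac50_um: float | None = None
    hill: float | None = None
    efficacy_pct: float | None = None    # signed; negative = inhibition
    k_per_min: float = 0.0               # first-order depletion rate; 0 = stable

    def __post_init__(self) -> None:
        if self.direction != "inactive":
            if self.ac50_um is None or self.ac50_um <= 0:
                raise ConfigurationError("active compound needs ac50 > 0")
            if self.hill is None or self.hill <= 0:
                raise ConfigurationError("active compound needs hill > 0")
            if self.efficacy_pct is None or abs(self.efficacy_pct) > 120:
                raise ConfigurationError("|efficacy| must be <= 120")
        if self.k_per_min < 0:
            raise ConfigurationError("depletion rate must be >= 0")

    def activity_at(self, conc_um: np.ndarray | float) -> np.ndarray | float:
        """Noise-free % activity at the given concentration(s)."""
        if self.direction == "inactive":
            return np.zeros_like(np.asarray(conc_um, dtype=float))
        x = np.asarray(conc_um, dtype=float)
        return self.efficacy_pct / (1.0 + (self.ac50_um / x) ** self.hill)


@dataclass
class GroundTruthCompound:
    compound_id: str
    cluster_label: int
    fingerprint: np.ndarray                      # uint8 bit vector
    truth: dict[str, EnzymeTruth]                # enzyme -> truth
    descriptors: dict[str, float] = field(default_factory=dict)

    def inhibitor_group(self) -> str:
        """Ground-truth inhibitor-selectivity group label.

        ``common`` if active on both enzymes, ``CYP3A7``/``CYP3A4`` if active
        on exactly one, ``other`` if inactive on both.  (Activity here means
        any non-inactive direction; used for descriptor-profile assignment.)
        """
        a7 = self.truth["CYP3A7"].direction != "inactive"
        a4 = self.truth["CYP3A4"].direction != "inactive"
        if a7 and a4:
            return "common"
        if a7:
            return "CYP3A7"
        if a4:
            return "CYP3A4"
        return "other"


@dataclass(frozen=True)
class ArtifactModel:
    """Separable row x column multiplicative gradient, optionally drifting
    linearly across the stack.

    ``row_amp``/``col_amp`` are full-span fractional amplitudes (0.2 means
    ±10 % from centre to edge along that axis); ``drift`` scales the gradient
    amplitude linearly from ``1 - drift/2`` at the first stack position to
    ``1 + drift/2`` at the last.
    """

    row_amp: float = 0.0
    col_amp: float = 0.0
    drift: float = 0.0

    def gradient(self, n_rows: int, n_cols: int, stack_frac: float) -> np.ndarray:
        r = np.linspace(-0.5, 0.5, n_rows)[:, None]
        c = np.linspace(-0.5, 0.5, n_cols)[None, :]
        base = (1.0 + self.row_amp * r) * (1.0 + self.col_amp * c)
        scale = 1.0 + self.drift * (stack_frac - 0.5)
        return 1.0 + (base - 1.0) * scale


@dataclass
class PlateSpec:
    """Plate geometry, control layout and noise for the simulated stack."""

    n_rows: int = 32
    n_cols: int = 48
    concentration_series: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.0035, 58.0, 11)
    )
    n_dmso_cols: int = 2          # leftmost columns carry DMSO controls
    n_pos_cols: int = 2           # next columns carry the positive control
    n_dmso_plates_leading: int = 2
    n_dmso_plates_trailing: int = 2
    noise_cv: float = 0.10
    artifact: ArtifactModel | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentration_series, dtype=float)
        if conc.ndim != 1 or len(conc) < 2:
            raise ConfigurationError("concentration series must be a 1-d list")
        if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ConfigurationError("concentrations must be strictly increasing and > 0")
        self.concentration_series = conc
        if self.n_rows * self.n_dmso_cols < 16 or self.n_rows * self.n_pos_cols < 16:
            raise ConfigurationError("need >= 16 DMSO and >= 16 positive-control wells")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")

    @property
    def wells_per_plate(self) -> int:
        return self.n_rows * self.n_cols

    def roles(self) -> np.ndarray:
        roles = np.full((self.n_rows, self.n_cols), "compound", dtype=object)
        roles[:, : self.n_dmso_cols] = "dmso"
        roles[:, self.n_dmso_cols : self.n_dmso_cols + self.n_pos_cols] = "positive"
        return roles

    @property
    def compound_capacity(self) -> int:
        return self.n_rows * (self.n_cols - self.n_dmso_cols - self.n_pos_cols)


@dataclass
class RawPlate:
    """One plate of raw luminescence reads.

    ``reads``/``roles``/``compound_ids`` are (n_rows, n_cols) arrays;
    ``concentration_index`` is None for all-DMSO plates.
    """

    plate_id: str
    enzyme: str
    reads: np.ndarray
    roles: np.ndarray
    compound_ids: np.ndarray
    concentration_index: int | None
    concentration_um: float | None
    stack_position: int
    corrected: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.reads)) or np.any(self.reads < 0):
            raise ConfigurationError("reads must be finite and >= 0")

    def role_reads(self, role: str) -> np.ndarray:
        return self.reads[self.roles == role]


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityPlan:
    """Marginal rates for the latent activity draws.

    Defaults reproduce the published screen's bookkeeping at scale: ~60 % of
    the library interacts with CYP3A7, of which ~74 % also interact with
    CYP3A4; ~29 % of CYP3A7-inactives interact with CYP3A4 alone; ~10 % of
    actives behave as activators rather than inhibitors.
    """

    cross_active_given_active: float = 0.74
    cross_active_given_inactive: float = 0.29
    activator_fraction: float = 0.10
    ac50_range_um: tuple[float, float] = (0.01, 30.0)
    hill_range: tuple[float, float] = (0.8, 2.5)
    abs_efficacy_range: tuple[float, float] = (40.0, 110.0)


@dataclass(frozen=True)
class SubstratePlan:
    """Joint substrate-status probabilities for the depletion panel.

    Defaults mirror the published follow-up rates: 22 % CYP3A7 substrates,
    45 % CYP3A4 substrates, with 71 % of CYP3A7 substrates shared.  Substrate
    half-lives are drawn log-uniformly (rate constants span orders of
    magnitude); a small "weak" fraction sits between the 30-min fast bound
    and the 120-min censor horizon; the rest are stable (k = 0).
    """

    p_both: float = 0.157
    p_3a7_only: float = 0.063
    p_3a4_only: float = 0.293
    weak_fraction_of_rest: float = 0.15
    fast_t_half_range_min: tuple[float, float] = (5.0, 30.0)
    weak_t_half_range_min: tuple[float, float] = (30.0, 120.0)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_library(
    n_compounds: int,
    n_clusters: int,
    enrichment_plan: dict[int, float] | float | None = None,
    seed: int = 0,
    *,
    n_bits: int = 1024,
    bit_flip_prob: float = 0.05,
    activity: ActivityPlan = ActivityPlan(),
    substrates: SubstratePlan = SubstratePlan(),
) -> list[GroundTruthCompound]:
    """Generate a compound library with planted cluster structure.

    ``enrichment_plan`` maps cluster label -> fraction of members active
    against CYP3A7 (a bare float applies uniformly; default 0.6).  Cluster
    fingerprints are random bit templates; members flip each template bit
    independently with probability ``bit_flip_prob``.
    """
    if n_compounds < n_clusters or n_clusters < 1:
        raise ConfigurationError("need n_compounds >= n_clusters >= 1")
    if enrichment_plan is None:
        enrichment_plan = 0.6
    if isinstance(enrichment_plan, (int, float)):
        enrichment_plan = {c: float(enrichment_plan) for c in range(n_clusters)}
    for c, frac in enrichment_plan.items():
        if not (0 <= c < n_clusters):
            raise ConfigurationError(f"enrichment plan cluster {c} out of range")
        if not (0.0 <= frac <= 1.0):
            raise ConfigurationError("active fractions must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    templates = rng.integers(0, 2, size=(n_clusters, n_bits), dtype=np.uint8)
    # round-robin assignment keeps every cluster populated, then shuffle
    labels = np.arange(n_compounds) % n_clusters
    rng.shuffle(labels)

    library: list[GroundTruthCompound] = []
    for i in range(n_compounds):
        cl = int(labels[i])
        flips = rng.random(n_bits) < bit_flip_prob
        fp = templates[cl] ^ flips.astype(np.uint8)

        frac = enrichment_plan.get(cl, 0.0)
        active7 = rng.random() < frac
        p4 = (
            activity.cross_active_given_active
            if active7
            else activity.cross_active_given_inactive
        )
        active4 = rng.random() < p4

        truth: dict[str, EnzymeTruth] = {}
        for enzyme, is_active in (("CYP3A7", active7), ("CYP3A4", active4)):
            if is_active:
                direction = (
                    "activator"
                    if rng.random() < activity.activator_fraction
                    else "inhibitor"
                )
                eff = rng.uniform(*activity.abs_efficacy_range)
                truth[enzyme] = EnzymeTruth(
                    direction=direction,
                    ac50_um=float(_log_uniform(rng, *activity.ac50_range_um)),
                    hill=float(rng.uniform(*activity.hill_range)),
                    efficacy_pct=float(eff if direction == "activator" else -eff),
                )
            else:
                truth[enzyme] = EnzymeTruth()

        # joint substrate status, independent of the inhibition truth
        u = rng.random()
        sub7 = u < substrates.p_both + substrates.p_3a7_only
        sub4 = (u < substrates.p_both) or (
            substrates.p_both + substrates.p_3a7_only
            <= u
            < substrates.p_both + substrates.p_3a7_only + substrates.p_3a4_only
        )
        for enzyme, is_sub in (("CYP3A7", sub7), ("CYP3A4", sub4)):
            if is_sub:
                t_half = _log_uniform(rng, *substrates.fast_t_half_range_min)
                truth[enzyme].k_per_min = float(LN2 / t_half)
            elif rng.random() < substrates.weak_fraction_of_rest:
                t_half = _log_uniform(rng, *substrates.weak_t_half_range_min)
                truth[enzyme].k_per_min = float(LN2 / t_half)

        library.append(
            GroundTruthCompound(
                compound_id=f"CPD-{i:05d}",
                cluster_label=cl,
                fingerprint=fp,
                truth=truth,
            )
        )
    logger.info("generated library of %d compounds in %d clusters", n_compounds, n_clusters)
    return library


def ground_truth_table(library: list[GroundTruthCompound]) -> pd.DataFrame:
    """Flatten the latent registry to one row per compound-enzyme."""
    rows = []
    for cpd in library:
        for enzyme in ENZYMES:
            t = cpd.truth[enzyme]
            rows.append(
                {
                    "compound_id": cpd.compound_id,
                    "enzyme": enzyme,
                    "cluster_label": cpd.cluster_label,
                    "direction": t.direction,
                    "true_ac50_um": t.ac50_um,
                    "true_hill": t.hill,
                    "true_efficacy_pct": t.efficacy_pct,
                    "true_k_per_min": t.k_per_min,
                    "true_t_half_min": (LN2 / t.k_per_min) if t.k_per_min > 0 else np.inf,
                }
            )
    return pd.DataFrame(rows)


def fingerprint_matrix(library: list[GroundTruthCompound]) -> tuple[list[str], np.ndarray]:
    ids = [c.compound_id for c in library]
    return ids, np.vstack([c.fingerprint for c in library])


# ---------------------------------------------------------------------------
# plate stack generation
# ---------------------------------------------------------------------------

def generate_plate_stack(
    library: list[GroundTruthCompound],
    spec: PlateSpec,
    enzyme: str,
    mu_dmso: float = 3000.0,
    mu_pos: float = 100.0,
    seed: int = 0,
) -> list[RawPlate]:
    """Simulate the full plate stack for one enzyme.

    Compounds are chunked into plate groups of ``spec.compound_capacity``;
    each group gets one plate per titration point.  Leading and trailing
    all-DMSO plates bracket the stack for artifact-correction testing.
    """
    if not library:
        raise ConfigurationError("library is empty")
    if not (mu_dmso > mu_pos > 0):
        raise ConfigurationError("need mu_dmso > mu_pos > 0")
    rng = np.random.default_rng(seed)
    roles = spec.roles()
    conc = spec.concentration_series
    cap = spec.compound_capacity
    n_groups = int(np.ceil(len(library) / cap))
    n_total = (
        spec.n_dmso_plates_leading
        + n_groups * len(conc)
        + spec.n_dmso_plates_trailing
    )
    span = max(n_total - 1, 1)

    compound_mask = roles == "compound"

    def _noise(shape) -> np.ndarray:
        if spec.noise_cv == 0:
            return np.ones(shape)
        return 1.0 + spec.noise_cv * rng.standard_normal(shape)

    def _make_plate(pos: int, plate_id: str, mean: np.ndarray,
                    ids: np.ndarray, ci, cum) -> RawPlate:
        reads = mean * _noise(mean.shape)
        if spec.artifact is not None:
            reads = reads * spec.artifact.gradient(spec.n_rows, spec.n_cols, pos / span)
        return RawPlate(
            plate_id=plate_id,
            enzyme=enzyme,
            reads=np.clip(reads, 0.0, None),
            roles=roles.copy(),
            compound_ids=ids,
            concentration_index=ci,
            concentration_um=cum,
            stack_position=pos,
        )

    stack: list[RawPlate] = []
    pos = 0
    empty_ids = np.full((spec.n_rows, spec.n_cols), None, dtype=object)
    flat_dmso = np.full((spec.n_rows, spec.n_cols), mu_dmso)
    for j in range(spec.n_dmso_plates_leading):
        stack.append(_make_plate(pos, f"{enzyme}-DMSO-L{j}", flat_dmso, empty_ids, None, None))
        pos += 1

    for g in range(n_groups):
        members = library[g * cap : (g + 1) * cap]
        ids = empty_ids.copy()
        rr, cc = np.where(compound_mask)
        for m, cpd in enumerate(members):
            ids[rr[m], cc[m]] = cpd.compound_id
        for ci, x in enumerate(conc):
            mean = np.full((spec.n_rows, spec.n_cols), float(mu_dmso))
            mean[roles == "positive"] = mu_pos
            for m, cpd in enumerate(members):
                a = float(cpd.truth[enzyme].activity_at(x))
                mean[rr[m], cc[m]] = mu_dmso + (a / 100.0) * (mu_dmso - mu_pos)
            # unused compound wells behave as DMSO-filled
            stack.append(
                _make_plate(pos, f"{enzyme}-G{g}-C{ci:02d}", mean, ids, ci, float(x))
            )
            pos += 1

    for j in range(spec.n_dmso_plates_trailing):
        stack.append(_make_plate(pos, f"{enzyme}-DMSO-T{j}", flat_dmso, empty_ids, None, None))
        pos += 1
    logger.info("generated %d plates for %s", len(stack), enzyme)
    return stack


# ---------------------------------------------------------------------------
# depletion panel
# ---------------------------------------------------------------------------

def generate_depletion_panel(
    library: list[GroundTruthCompound],
    time_points_min=(0.0, 5.0, 10.0, 15.0, 30.0, 60.0),
    noise_cv: float = 0.10,
    seed: int = 0,
    enzymes=ENZYMES,
) -> pd.DataFrame:
    """Simulate parent-remaining time courses: 100*exp(-k*t) with
    multiplicative noise.  The t=0 point is the normalization anchor and is
    exactly 100 %.  Returns a long DataFrame (compound_id, enzyme, time_min,
    pct_remaining)."""
    t = np.asarray(time_points_min, dtype=float)
    if len(t) < 2 or t[0] != 0 or np.any(t < 0):
        raise ConfigurationError("time points must start at 0 and be non-negative")
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for cpd in library:
        for enzyme in enzymes:
            k = cpd.truth[enzyme].k_per_min
            remaining = 100.0 * np.exp(-k * t)
            if noise_cv > 0:
                remaining = remaining * (1.0 + noise_cv * rng.standard_normal(len(t)))
            remaining[0] = 100.0
            remaining = np.clip(remaining, 1e-6, None)
            for ti, ri in zip(t, remaining):
                rows.append(
                    {
                        "compound_id": cpd.compound_id,
                        "enzyme": enzyme,
                        "time_min": float(ti),
                        "pct_remaining": float(ri),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptor table
# ---------------------------------------------------------------------------

def generate_descriptor_table(
    library: list[GroundTruthCompound],
    group_profiles: dict[str, dict[str, tuple[float, float | None]]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-compound descriptors from the compound's group profile.

    Groups come from each compound's ground-truth inhibitor group
    (common / CYP3A4 / CYP3A7 / other).  Profile entries are
    ``descriptor -> (mean, sd)``; an ``sd`` of None marks a binary indicator
    drawn Bernoulli(mean).  Continuous draws are independent normals
    (diagonal covariance).  The drawn values are also written back onto each
    compound's ``descriptors`` dict.
    """
    if group_profiles is None:
        group_profiles = DESCRIPTOR_GROUP_PROFILES
    names = None
    for g, prof in group_profiles.items():
        if names is None:
            names = list(prof)
        elif list(prof) != names:
            raise ConfigurationError("group profiles are dimensionally inconsistent")
        for desc, (_, sd) in prof.items():
            if sd is not None and sd < 0:
                raise ConfigurationError(f"negative SD for {desc} in group {g}")
    rng = np.random.default_rng(seed)
    rows = []
    for cpd in library:
        group = cpd.inhibitor_group()
        prof = group_profiles.get(group) or group_profiles.get("other")
        if prof is None:
            raise ConfigurationError(f"no descriptor profile for group {group}")
        vals: dict[str, float] = {}
        for desc, (mean, sd) in prof.items():
            if sd is None:
                vals[desc] = float(rng.random() < mean)
            else:
                vals[desc] = float(mean + sd * rng.standard_normal())
        cpd.descriptors = vals
        rows.append({"compound_id": cpd.compound_id, "group": group, **vals})
    return pd.DataFrame(rows)
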