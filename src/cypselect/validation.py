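"""Seeded recovery experiments against the generator's ground truth.

Each function runs a self-contained synthetic experiment — plant known
truth, run the corresponding analysis stage, measure how well the truth is
recovered — and returns summary numbers.  They back both the validation
test-suite and the reproducibility script, so the measured conditions are
identical in both places.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import chemspace, crc, depletion
from .config import TitrationSpec
from .plates import ConcentrationResponse
from .synthetic import generate_library, fingerprint_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CRCRecovery:
    median_rel_ac50_error: float
    active_recall: float
    n: int


def ac50_recovery_experiment(
    n_compounds: int = 500,
    noise_cv: float = 0.10,
    seed: int = 1,
    titration: TitrationSpec = TitrationSpec(),
    ac50_range_um: tuple[float, float] = (0.01, 10.0),
    hill_range: tuple[float, float] = (0.8, 2.5),
    abs_efficacy_range: tuple[float, float] = (40.0, 110.0),
) -> CRCRecovery:
    """Plant Hill curves, add multiplicative response noise, refit and call.

    Every planted compound is a true active (inhibitor); recall is the
    fraction called active after curve classification, and the potency
    error is |fitted - true| / true AC50.
    """
    rng = np.random.default_rng(seed)
    conc = titration.concentrations()
    ac50 = np.exp(rng.uniform(*np.log(ac50_range_um), n_compounds))
    hill = rng.uniform(*hill_range, n_compounds)
    eff = -rng.uniform(*abs_efficacy_range, n_compounds)
    errors = np.empty(n_compounds)
    active = np.zeros(n_compounds, dtype=bool)
    for i in range(n_compounds):
        a = eff[i] / (1.0 + (ac50[i] / conc) ** hill[i])
        a = a * (1.0 + noise_cv * rng.standard_normal(len(conc)))
        s = ConcentrationResponse(f"c{i}", "CYP3A7", conc, a)
        fit = crc.fit_hill(s)
        call = crc.call_activity(crc.classify_curve(fit, s), fit)
        errors[i] = (
            abs(fit.ac50_um - ac50[i]) / ac50[i] if fit.converged else np.inf
        )
        active[i] = call.value == "active"
    return CRCRecovery(
        median_rel_ac50_error=float(np.median(errors)),
        active_recall=float(np.mean(active)),
        n=n_compounds,
    )


def depletion_recovery_experiment(
    n_trials: int = 1000,
    noise_cv: float = 0.10,
    seed: int = 1,
    t_half_range_min: tuple[float, float] = (5.0, 60.0),
    time_points_min=(0.0, 5.0, 10.0, 15.0, 30.0, 60.0),
    rel_tol: float = 0.20,
) -> tuple[float, int]:
    """Fraction of planted first-order time courses whose fitted half-life
    lands within ``rel_tol`` of truth.  Half-lives are drawn log-uniformly
    (rate constants span orders of magnitude)."""
    rng = np.random.default_rng(seed)
    t = np.asarray(time_points_min, dtype=float)
    t_half = np.exp(rng.uniform(*np.log(t_half_range_min), n_trials))
    k = np.log(2.0) / t_half
    ok = 0
    for i in range(n_trials):
        rem = 100.0 * np.exp(-k[i] * t) * (1.0 + noise_cv * rng.standard_normal(len(t)))
        rem[0] = 100.0
        rem = np.clip(rem, 1e-6, None)
        fit = depletion.fit_depletion(
            depletion.DepletionSeries(f"c{i}", "CYP3A7", t, rem)
        )
        if (
            fit.quantified
            and not fit.censored
            and abs(fit.t_half_min - t_half[i]) / t_half[i] <= rel_tol
        ):
            ok += 1
    return ok / n_trials, n_trials


def planted_enrichment_experiment(
    n_seeds: int = 100,
    n_compounds: int = 500,
    n_clusters: int = 10,
    planted_fraction: float = 0.9,
    background_fraction: float = 0.1,
    grid_rows: int = 4,
    grid_cols: int = 3,
    epochs: int = 5,
    seed: int = 1,
) -> tuple[float, int]:
    """Fraction of seeds in which the planted high-activity cluster attains
    the extreme (maximum) heat value after SOM clustering + Fisher testing.

    Success means the hottest node is the modal SOM node of the planted
    cluster's members.
    """
    base = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    hits = 0
    for s in base:
        plan = {c: background_fraction for c in range(n_clusters)}
        plan[0] = planted_fraction
        lib = generate_library(
            n_compounds, n_clusters, enrichment_plan=plan, seed=int(s)
        )
        ids, fp = fingerprint_matrix(lib)
        active = np.array(
            [c.truth["CYP3A7"].direction != "inactive" for c in lib]
        )
        grid = chemspace.train_som(
            fp, grid_rows, grid_cols, epochs=epochs, seed=int(s) + 1
        )
        assignment = chemspace.assign_clusters(fp, grid)
        res = chemspace.fisher_enrichment(assignment, active, grid)
        hottest = int(res.loc[res["heat"].idxmax(), "cluster"])
        planted_nodes = assignment[np.array([c.cluster_label == 0 for c in lib])]
        modal = int(np.bincount(planted_nodes).argmax())
        if hottest == modal:
            hits += 1
    return hits / n_seeds, n_seeds
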