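"""End-to-end pipeline: corpora -> networks -> measures/mocks -> cohort table.

Ties the estimator, measure, and statistics modules together so that the
CLI, the examples, and simulation studies all run the same code path:
estimate a network per participant, compute its measures and small-world
coefficient, build the mock ensemble and deltas, and assemble one table row
per participant x diagnosis for the logistic diagnosis models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus import FluencyCorpus
from .errors import UndefinedMeasureError
from .estimator import EstimationResult, estimate_network
from .generator import CohortSpec, SyntheticCohort, simulate_cohort
from .measures import (
    MockEnsemble,
    compute_measures,
    delta_measures,
    mock_ensemble,
    smallworld_coefficient,
)
from .prior import EdgePrior
from .stats import corpus_perseveration_rate

__all__ = [
    "BASELINE_FACTORS",
    "NETWORK_FACTORS",
    "MAXIMAL_FACTORS",
    "summarize_participant",
    "PipelineResult",
    "run_cohort_pipeline",
]

#: Traditional fluency scoring factors (the clinical baseline model).
BASELINE_FACTORS = ["mean_responses", "perseveration_rate", "education"]

#: Network-derived factors added by the maximal model.
NETWORK_FACTORS = [
    "smallworld",
    "n_nodes",
    "density",
    "mean_degree",
    "delta_mean_degree",
    "aspl",
    "delta_aspl",
    "p_emit",
    "diameter",
    "delta_diameter",
]

MAXIMAL_FACTORS = BASELINE_FACTORS + NETWORK_FACTORS


def summarize_participant(
    corpus: FluencyCorpus,
    result: EstimationResult,
    *,
    prior: EdgePrior | None = None,
    diagnosis: str = "",
    education: float = math.nan,
    k_mocks: int = 0,
    rng: np.random.Generator | None = None,
    n_random_smallworld: int = 100,
    estimator_config: dict | None = None,
) -> dict[str, float]:
    """One cohort-table row for a participant's estimated network.

    With ``k_mocks > 0`` the row also carries the mock-ensemble deltas and
    the count of failed mock replicates.
    """
    rng = np.random.default_rng() if rng is None else rng
    ms = compute_measures(result.network)
    try:
        sw = smallworld_coefficient(result.network, n_random_smallworld, rng)
    except UndefinedMeasureError:
        sw = math.nan
    row: dict[str, float] = {
        "participant_id": corpus.participant_id,  # type: ignore[dict-item]
        "diagnosis": diagnosis,  # type: ignore[dict-item]
        "n_lists": float(len(corpus)),
        "mean_responses": float(np.mean([len(fl) for fl in corpus.lists])),
        "perseveration_rate": corpus_perseveration_rate(corpus),
        "education": education,
        "p_emit": result.p_emit,
        "smallworld": sw,
        "log_posterior": result.log_posterior,
        "converged": float(result.converged),
    }
    row.update(ms.as_dict())
    if k_mocks > 0:
        ens = mock_ensemble(
            corpus, prior, k=k_mocks, rng=rng, estimator_config=estimator_config
        )
        for name, value in delta_measures(ms, ens).items():
            row[f"delta_{name}"] = value
        row["mock_failures"] = float(ens.n_failed)
        row["mock_mean_p_emit"] = ens.mean_p_emit
    return row


@dataclass(frozen=True)
class PipelineResult:
    """Everything the synthetic cohort pipeline produced."""

    table: pd.DataFrame
    cohort: SyntheticCohort
    estimates: Mapping[str, EstimationResult]
    ensembles: Mapping[str, MockEnsemble] = field(default_factory=dict)


def run_cohort_pipeline(
    spec: CohortSpec | None = None,
    *,
    seed: int = 0,
    prior: EdgePrior | None = None,
    k_mocks: int = 50,
    n_random_smallworld: int = 100,
    estimator_config: dict | None = None,
) -> PipelineResult:
    """Simulate a cohort, estimate every participant, and assemble the table.

    A single master seed drives the simulation, the estimation searches, the
    mock ensembles and the random small-world baselines, so two runs with
    the same seed produce identical tables.
    """
    spec = spec if spec is not None else CohortSpec()
    cohort = simulate_cohort(spec, seed=seed)
    cfg = dict(estimator_config or {})
    cfg.pop("seed", None)
    rows = []
    estimates: dict[str, EstimationResult] = {}
    for ci, corpus in enumerate(cohort.corpora):
        truth = cohort.truth[corpus.participant_id]
        rng = np.random.default_rng([seed, 7, ci])
        est_seed = int(rng.integers(2**31 - 1))
        result = estimate_network(corpus, prior, seed=est_seed, **cfg)
        estimates[corpus.participant_id] = result
        rows.append(
            summarize_participant(
                corpus,
                result,
                prior=prior,
                diagnosis=truth.group,
                education=truth.education,
                k_mocks=k_mocks,
                rng=rng,
                n_random_smallworld=n_random_smallworld,
                estimator_config=cfg,
            )
        )
    table = pd.DataFrame(rows)
    return PipelineResult(table=table, cohort=cohort, estimates=estimates)
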