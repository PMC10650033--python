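"""Calibration of the nine sensitization probabilities to cohort frequencies.

The observable is the per-gene percentage of patients whose tumor, at
diagnosis, carries the sensitizing mutation in at least the signature
threshold fraction of cells.  That percentage increases monotonically in
the gene's per-division sensitization probability mu_g, but the genes are
coupled: the XOR gate makes sensitizing clones compete, so raising one
gene's rate weakly lowers the others' frequencies and the fit must be
joint.

The fitter iterates damped multiplicative updates in log space:

    mu_g  <-  mu_g * (target_g / max(obs_g, eps)) ** alpha

with alpha = 0.5 and eps = half a patient's worth of frequency, clipped to
[1e-9, 1e-3].  Each iteration re-simulates a fresh virtual cohort, so the
observed frequencies are noisy; the damping keeps the iteration stable
under that noise.  Convergence is declared when every gene is within the
absolute tolerance of its target or when no gene shows a significant
model-data difference in a two-proportion z-test.

``generate_target_fixture`` emits a synthetic set of target percentages
for end-to-end runs when no reference cohort table is at hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import compare_frequencies, simulate_cohort
from .model import Gene, ModelParams, SENSITIZING_GENES
from .patients import StageDistribution

MU_LOWER = 1e-9
MU_UPPER = 1e-3


@dataclass
class CalibrationTargets:
    """Target per-gene mutation percentages and fitting configuration.

    ``n_data`` is the size of the reference cohort the percentages came
    from (it sets the power of the significance check); ``tolerance`` is
    the absolute convergence band in percentage points.
    """

    percentages: Mapping[Gene, float]
    n_data: int = 950
    tolerance: float = 1.5
    max_iterations: int = 15
    cohort_size: int = 500

    def __post_init__(self) -> None:
        for g, pct in self.percentages.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"target for {g} outside [0, 100]: {pct}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.n_data <= 0 or self.cohort_size <= 0 or self.max_iterations <= 0:
            raise ValueError("n_data, cohort_size, max_iterations must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CalibrationTargets":
        """Read a (gene, target_pct) CSV; gene names in lower case."""
        df = pd.read_csv(path)
        by_name = {g.value: g for g in SENSITIZING_GENES}
        pct = {
            by_name[str(row["gene"]).lower()]: float(row["target_pct"])
            for _, row in df.iterrows()
        }
        return cls(percentages=pct, **kwargs)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"gene": g.value, "target_pct": self.percentages.get(g, 0.0)}
                for g in SENSITIZING_GENES
            ]
        ).to_csv(path, index=False)


@dataclass
class CalibrationResult:
    """Fitted sensitization probabilities plus the iteration trace."""

    mu_sens: dict[Gene, float]
    converged: bool
    trace: pd.DataFrame
    p_values: dict[Gene, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mu_sens": {g.value: mu for g, mu in self.mu_sens.items()},
            "converged": self.converged,
            "p_values": {g.value: p for g, p in self.p_values.items()},
            "trace": self.trace.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def calibrate(
    targets: CalibrationTargets,
    init: ModelParams | None = None,
    dist: StageDistribution | None = None,
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
    alpha: float = 0.5,
    significance: float = 0.05,
) -> CalibrationResult:
    """Fit the nine sensitization probabilities to the target percentages.

    Every iteration simulates a fresh cohort of ``targets.cohort_size``
    virtual patients under the current rates, compares the observed
    per-gene percentages with the targets and applies the damped
    multiplicative update.  Non-convergence within ``max_iterations`` is
    reported via ``converged=False``, not raised.
    """
    init = init or ModelParams.default()
    dist = dist or StageDistribution()
    if rng is None:
        rng = np.random.default_rng(seed)

    genes = list(SENSITIZING_GENES)
    target = np.array([targets.percentages.get(g, 0.0) for g in genes])
    for g in genes:
        if targets.percentages.get(g, 0.0) > 0 and init.mu_sens.get(g, 0.0) <= 0:
            raise ValueError(
                f"gene {g.name} has a positive target but zero initial rate"
            )
    mu = np.array([init.mu_sens.get(g, 0.0) for g in genes], dtype=float)
    eps_pct = 100.0 * 0.5 / targets.cohort_size

    trace_rows = []
    converged = False
    p_values: dict[Gene, float] = {}
    for iteration in range(targets.max_iterations):
        params = ModelParams(
            s=init.s,
            mu_sens={g: float(m) for g, m in zip(genes, mu)},
            mu_res=dict(init.mu_res),
            signature_threshold=init.signature_threshold,
            cells_per_cm3=init.cells_per_cm3,
            days_per_month=init.days_per_month,
        )
        cohort = simulate_cohort(targets.cohort_size, params, dist, rng)
        obs = cohort.frequencies().to_numpy()

        tests = compare_frequencies(
            {g.value: o for g, o in zip(genes, obs)},
            {g.value: t for g, t in zip(genes, target)},
            n_model=targets.cohort_size,
            n_data=targets.n_data,
            alpha=significance,
        )
        p_values = {g: float(p) for g, p in zip(genes, tests["p_value"])}
        row = {"iteration": iteration}
        row.update({f"mu_{g.value}": float(m) for g, m in zip(genes, mu)})
        row.update({f"obs_{g.value}": float(o) for g, o in zip(genes, obs)})
        trace_rows.append(row)

        within_tol = np.all(np.abs(obs - target) <= targets.tolerance)
        if within_tol or bool(tests["passed"].all()):
            converged = True
            break
        factor = (target / np.maximum(obs, eps_pct)) ** alpha
        mu = np.clip(mu * factor, MU_LOWER, MU_UPPER)
        # A gene with target 0 gets factor 0: pin it at the lower bound.
        mu[target == 0.0] = MU_LOWER

    return CalibrationResult(
        mu_sens={g: float(m) for g, m in zip(genes, mu)},
        converged=converged,
        trace=pd.DataFrame(trace_rows),
        p_values=p_values,
    )


def generate_target_fixture(
    seed: int,
    n_genes: int = 9,
    *,
    low: float = 1.0,
    high: float = 12.0,
    max_total: float = 60.0,
    path: str | Path | None = None,
) -> CalibrationTargets:
    """Synthetic per-gene target percentages for end-to-end calibration runs.

    Draws each gene's target uniformly in [low, high] percent and rescales
    if the total exceeds ``max_total`` (the XOR gate caps how much
    signature mass a cohort can carry).  Deterministic per seed.  The
    defaults keep targets within the range the model can actually reach
    with sensitization probabilities below the fitter's upper bound.
    """
    rng = np.random.default_rng(seed)
    genes = SENSITIZING_GENES[:n_genes]
    pct = rng.uniform(low, high, size=len(genes))
    if pct.sum() > max_total:
        # the extra (1 - 1e-12) keeps the rescaled sum at or below the cap
        # despite floating-point rounding
        pct *= max_total / pct.sum() * (1.0 - 1e-12)
    targets = CalibrationTargets(
        percentages={g: float(p) for g, p in zip(genes, pct)}
    )
    if path is not None:
        targets.to_csv(path)
    return targets
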