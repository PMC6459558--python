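"""Stage-to-time maps, cohort likelihood, maximum-likelihood fitting,
parametric-bootstrap intervals and seed-soil ratios.

Each patient contributes the model probability of their observed
metastatic state at the time mapped from their tumour stage; the total
log-likelihood is maximised over log-rates with a derivative-free
Nelder-Mead search (rates stay positive by construction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .dynamics import solve_master_equation
from .network import (
    MetastaticState,
    RateParameters,
    SiteNetwork,
    StateSpace,
    build_generator,
    is_reachable,
)

__all__ = [
    "StageTimeMap",
    "GrowthParams",
    "Cohort",
    "FitResult",
    "stage_to_time",
    "log_likelihood",
    "fit_mle",
    "parametric_bootstrap",
    "seed_soil_ratios",
]

logger = logging.getLogger(__name__)

#: Rates below this floor are clamped when evaluating the likelihood, so a
#: collapsed estimate never produces log(0).
RATE_FLOOR = 1e-12

MICRON = 1e-6
CM = 1e-2


@dataclass(frozen=True)
class GrowthParams:
    """Exponential volumetric growth constants for the stage-to-time map.

    ``r0`` is the initial radius (m; default one-cell, 25 um), ``alpha``
    the volumetric growth rate per year (default a 40-day doubling time),
    ``stage_radii`` the radius reached at each stage (m; defaults 2/4/6/8 cm).
    """

    r0: float = 25 * MICRON
    alpha: float = math.log(2) / 40 * 365
    stage_radii: tuple[float, ...] = (2 * CM, 4 * CM, 6 * CM, 8 * CM)

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.alpha <= 0:
            raise ValueError("r0 and alpha must be positive")
        if any(np.diff(self.stage_radii) <= 0):
            raise ValueError("stage radii must be strictly increasing")
        if self.stage_radii[0] <= self.r0:
            raise ValueError("stage radii must exceed the initial radius")

    def time_of_radius(self, r: float) -> float:
        """Years to grow from ``r0`` to radius ``r``: 3 ln(r/r0) / alpha."""
        return 3.0 * math.log(r / self.r0) / self.alpha


@dataclass(frozen=True)
class StageTimeMap:
    """Ordered stage labels and the time assigned to each."""

    kind: str
    stage_labels: tuple[str, ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.stage_labels) != len(self.times):
            raise ValueError("one time per stage label required")
        if any(np.diff(self.times) <= 0):
            raise ValueError("stage times must be strictly increasing")

    def time_of(self, stage: str) -> float:
        try:
            return self.times[self.stage_labels.index(stage)]
        except ValueError:
            raise KeyError(f"unknown stage label {stage!r}") from None


def stage_to_time(
    kind: str,
    stage_labels: Sequence[str],
    growth: Optional[GrowthParams] = None,
) -> StageTimeMap:
    """Build a stage-to-time map.

    ``linear`` assigns consecutive integers 1..K in stage order (stage is the
    time, on an arbitrary scale).  ``exponential_growth`` inverts the
    exponential-volume model: t_i = 3 ln(R_i / R_0) / alpha, in years.
    """
    labels = tuple(str(s) for s in stage_labels)
    if kind == "linear":
        times = tuple(float(k) for k in range(1, len(labels) + 1))
    elif kind == "exponential_growth":
        growth = growth if growth is not None else GrowthParams()
        if len(growth.stage_radii) != len(labels):
            raise ValueError("need one stage radius per stage label")
        times = tuple(growth.time_of_radius(r) for r in growth.stage_radii)
    else:
        raise ValueError(f"unknown stage-time map kind {kind!r}")
    return StageTimeMap(kind=kind, stage_labels=labels, times=times)


@dataclass(frozen=True)
class Cohort:
    """Cross-sectional patient records: stage label + observed metastatic state."""

    patients: tuple[tuple[str, MetastaticState], ...]
    sites: tuple[str, ...]
    patient_ids: tuple[str, ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        for stage, state in self.patients:
            if state.n_sites != len(self.sites):
                raise ValueError(
                    f"state {state} has {state.n_sites} sites, cohort has {len(self.sites)}"
                )
        if self.patient_ids and len(self.patient_ids) != len(self.patients):
            raise ValueError("one patient id per patient required")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(stage for stage, _ in self.patients)

    def stage_state_counts(self) -> dict[tuple[str, str], int]:
        """Multiplicity of each (stage, state-string) pair."""
        counts: dict[tuple[str, str], int] = {}
        for stage, state in self.patients:
            key = (stage, str(state))
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood estimate with diagnostics and optional intervals."""

    theta_hat: RateParameters
    log_likelihood: float
    converged: bool
    n_patients: int
    n_iterations: int = 0
    n_evaluations: int = 0
    message: str = ""
    bootstrap_intervals: Optional[Mapping[str, tuple[float, float]]] = None
    n_bootstrap_failures: int = 0

    def with_intervals(
        self, intervals: Mapping[str, tuple[float, float]], n_failures: int = 0
    ) -> "FitResult":
        return replace(self, bootstrap_intervals=dict(intervals), n_bootstrap_failures=n_failures)


def _stage_distributions(
    net: SiteNetwork,
    space: StateSpace,
    theta: RateParameters,
    stmap: StageTimeMap,
    stages: Sequence[str],
) -> dict[str, np.ndarray]:
    """Solve the master equation once per distinct stage time."""
    q = build_generator(net, space, theta)
    distinct = sorted(set(stages), key=stmap.time_of)
    times = [stmap.time_of(s) for s in distinct]
    traj = solve_master_equation(q, times, method="expm")
    return {s: traj.distributions[k] for k, s in enumerate(distinct)}


def log_likelihood(
    cohort: Cohort,
    net: SiteNetwork,
    space: StateSpace,
    theta: RateParameters,
    stmap: StageTimeMap,
    on_zero: str = "neginf",
) -> float:
    """Sum over patients of log P(observed state; stage time, theta).

    ``on_zero`` selects what happens when a patient's state has zero model
    probability: ``"neginf"`` returns ``-inf``, ``"error"`` raises.
    """
    if cohort.n_patients == 0:
        raise ValueError("empty cohort")
    for stage, state in cohort.patients:
        if not is_reachable(space, state):
            raise ValueError(
                f"state {state} is unreachable; run the exclusion filter before fitting"
            )
    dists = _stage_distributions(net, space, theta, stmap, cohort.stages)
    total = 0.0
    for (stage, state_str), count in cohort.stage_state_counts().items():
        p = dists[stage][space.index_of[state_str]]
        if p <= 0.0:
            if on_zero == "error":
                raise FloatingPointError(f"state {state_str} has zero probability at stage {stage}")
            return -math.inf
        total += count * math.log(p)
    return total


def _floored(values: np.ndarray) -> np.ndarray:
    return np.maximum(values, RATE_FLOOR)


def fit_mle(
    cohort: Cohort,
    net: SiteNetwork,
    stmap: StageTimeMap,
    space: Optional[StateSpace] = None,
    initial_theta: Optional[RateParameters] = None,
    multistart: int = 0,
    seed: Optional[int] = None,
    xatol: float = 1e-5,
    fatol: float = 1e-8,
    maxiter: Optional[int] = None,
) -> FitResult:
    """Maximum-likelihood rates by Nelder-Mead over log-rates.

    The search is unconstrained in log-space, so rates remain positive;
    estimates collapsing toward zero show up as very negative log-rates.
    ``multistart`` adds extra seeded starting points (log-uniform in
    [1e-3, 1]) and keeps the best optimum.  Deterministic given
    ``initial_theta`` and ``seed``.
    """
    from .network import enumerate_reachable_states

    if cohort.n_patients == 0:
        raise ValueError("empty cohort")
    if space is None:
        space = enumerate_reachable_states(net)
    symbols = net.rate_symbols
    counts = cohort.stage_state_counts()
    state_idx = {s: space.index_of[s] for _, s in counts}
    n_eval = 0

    def negloglik(log_theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        theta = RateParameters.from_vector(symbols, _floored(np.exp(log_theta)))
        dists = _stage_distributions(net, space, theta, stmap, cohort.stages)
        total = 0.0
        for (stage, state_str), count in counts.items():
            p = dists[stage][state_idx[state_str]]
            if p <= 0.0:
                return math.inf
            total += count * math.log(p)
        return -total

    starts = []
    if initial_theta is not None:
        starts.append(np.log(_floored(initial_theta.vector(symbols))))
    else:
        starts.append(np.log(np.full(len(symbols), 0.1)))
    if multistart > 0:
        rng = np.random.default_rng(seed)
        for _ in range(multistart):
            starts.append(np.log(10.0 ** rng.uniform(-3, 0, size=len(symbols))))

    best = None
    options = {"xatol": xatol, "fatol": fatol, "adaptive": False}
    if maxiter is not None:
        options["maxiter"] = maxiter
    for x0 in starts:
        res = minimize(negloglik, x0, method="Nelder-Mead", options=options)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("optimizer failed to find a finite-likelihood optimum")
    theta_hat = RateParameters.from_vector(symbols, _floored(np.exp(best.x)))
    return FitResult(
        theta_hat=theta_hat,
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        n_patients=cohort.n_patients,
        n_iterations=int(best.nit),
        n_evaluations=n_eval,
        message=str(best.message),
    )


def parametric_bootstrap(
    fit: FitResult,
    cohort: Cohort,
    net: SiteNetwork,
    stmap: StageTimeMap,
    space: Optional[StateSpace] = None,
    n_replicates: int = 100,
    quantiles: tuple[float, float] = (0.05, 0.95),
    seed: Optional[int] = None,
) -> dict[str, tuple[float, float]]:
    """Per-symbol empirical quantile intervals by parametric bootstrap.

    Each replicate keeps every patient's stage fixed and redraws their
    state from the model distribution at the fitted rates, then refits
    (warm-started at the fit).  Failed refits are logged and dropped.
    """
    from .network import enumerate_reachable_states

    if n_replicates < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    lo, hi = quantiles
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"invalid quantile pair {quantiles}")
    if space is None:
        space = enumerate_reachable_states(net)
    symbols = net.rate_symbols
    dists = _stage_distributions(net, space, fit.theta_hat, stmap, cohort.stages)
    rng = np.random.default_rng(seed)
    stages = cohort.stages
    stage_positions = {s: np.nonzero([st == s for st in stages])[0] for s in set(stages)}
    estimates, n_failures = [], 0
    for b in range(n_replicates):
        drawn = np.empty(cohort.n_patients, dtype=int)
        for stage, positions in stage_positions.items():
            drawn[positions] = rng.choice(space.n_states, size=positions.size, p=dists[stage])
        replicate = Cohort(
            patients=tuple((stage, space.states[k]) for stage, k in zip(stages, drawn)),
            sites=cohort.sites,
        )
        try:
            refit = fit_mle(
                replicate, net, stmap, space=space, initial_theta=fit.theta_hat
            )
            estimates.append(refit.theta_hat.vector(symbols))
        except (RuntimeError, FloatingPointError) as exc:
            n_failures += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if not estimates:
        raise RuntimeError("all bootstrap replicates failed")
    if n_failures:
        logger.warning("%d/%d bootstrap replicates dropped", n_failures, n_replicates)
    arr = np.array(estimates)
    lower = np.quantile(arr, lo, axis=0)
    upper = np.quantile(arr, hi, axis=0)
    return {sym: (float(lower[k]), float(upper[k])) for k, sym in enumerate(symbols)}


def seed_soil_ratios(
    theta: RateParameters,
    relative_flows: Mapping[str, float],
    net: SiteNetwork,
) -> dict[str, float]:
    """Fitted inflow rate divided by the relative physical flow, per site.

    Isolates how receptive each target site is to colonisation once the
    physical delivery of cells is factored out.  Each site in
    ``relative_flows`` must have exactly one inbound edge.
    """
    ratios = {}
    for site, flow in relative_flows.items():
        if not 0 < flow <= 1:
            raise ValueError(f"relative flow for {site!r} must be in (0, 1], got {flow}")
        symbols = [sym for (u, v), sym in net.secondary_edges.items() if v == site]
        if site in net.primary_edges:
            symbols.append(net.primary_edges[site])
        if len(symbols) != 1:
            raise ValueError(
                f"site {site!r} has {len(symbols)} inbound edges; seed-soil ratio needs exactly one"
            )
        ratios[site] = theta.values[symbols[0]] / flow
    return ratios
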