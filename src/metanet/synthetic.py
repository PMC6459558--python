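"""Synthetic cohort generation.

Cohorts are drawn either exactly from the master-equation distribution at
each patient's stage time, or by Gillespie simulation of the underlying
continuous-time Markov chain -- two independent routes to the same law,
used as a mutual cross-check.  Optional contamination flips one
topologically unfed site per affected patient, producing exactly the kind
of skip-metastasis record the exclusion filter must catch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .dynamics import solve_master_equation
from .inference import Cohort, StageTimeMap
from .network import (
    MetastaticState,
    RateParameters,
    SiteNetwork,
    StateSpace,
    build_generator,
)

__all__ = ["CohortDesign", "sample_cohort", "gillespie_state_at"]


@dataclass(frozen=True)
class CohortDesign:
    """Recipe for a synthetic cohort.

    ``stage_composition`` gives the number of patients per stage label;
    ``sampler`` is ``"exact"`` (categorical from the solved master
    equation) or ``"gillespie"``; ``contamination_rate`` is the per-patient
    probability of flipping one unfed negative site.
    """

    stage_composition: Mapping[str, int]
    theta: RateParameters
    stage_time_map: StageTimeMap
    seed: int = 0
    sampler: str = "exact"
    contamination_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.stage_composition.values()):
            raise ValueError("stage counts must be nonnegative")
        if sum(self.stage_composition.values()) < 1:
            raise ValueError("cohort must contain at least one patient")
        if not 0 <= self.contamination_rate < 1:
            raise ValueError("contamination_rate must be in [0, 1)")
        if self.sampler not in ("exact", "gillespie"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        unknown = set(self.stage_composition) - set(self.stage_time_map.stage_labels)
        if unknown:
            raise ValueError(f"stages {sorted(unknown)} missing from the stage-time map")


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    # Counter-offset substream: patient k is reproducible regardless of
    # how many other patients the cohort contains.
    return np.random.default_rng([seed, patient_index])


def _contaminate(
    net: SiteNetwork, state: MetastaticState, rng: np.random.Generator
) -> MetastaticState:
    """Flip one negative site that has neither a primary edge nor a positive feeder."""
    eligible = [
        v
        for v, site in enumerate(net.sites)
        if state.status[v] == 0
        and site not in net.primary_edges
        and not any(state.status[net.site_index(u)] for u in net.feeders_of(site))
    ]
    if not eligible:
        return state
    return state.activate(int(rng.choice(eligible)))


def sample_cohort(net: SiteNetwork, space: StateSpace, design: CohortDesign) -> Cohort:
    """Draw a cohort per ``design``; deterministic given the design seed."""
    exact_dists: dict[str, np.ndarray] = {}
    if design.sampler == "exact":
        q = build_generator(net, space, design.theta)
        stages = sorted(design.stage_composition, key=design.stage_time_map.time_of)
        times = [design.stage_time_map.time_of(s) for s in stages]
        traj = solve_master_equation(q, times, method="expm")
        exact_dists = {s: traj.distributions[k] for k, s in enumerate(stages)}

    patients: list[tuple[str, MetastaticState]] = []
    ids: list[str] = []
    k = 0
    for stage in design.stage_time_map.stage_labels:
        n = design.stage_composition.get(stage, 0)
        tau = design.stage_time_map.time_of(stage)
        for _ in range(n):
            rng = _patient_rng(design.seed, k)
            if design.sampler == "exact":
                idx = rng.choice(space.n_states, p=exact_dists[stage])
                state = space.states[int(idx)]
            else:
                state = gillespie_state_at(net, design.theta, tau, rng=rng)
            if design.contamination_rate > 0 and rng.random() < design.contamination_rate:
                state = _contaminate(net, state, rng)
            patients.append((stage, state))
            ids.append(f"P{k:06d}")
            k += 1
    return Cohort(
        patients=tuple(patients),
        sites=net.sites,
        patient_ids=tuple(ids),
        provenance=f"synthetic:{design.sampler}:seed={design.seed}",
    )


def gillespie_state_at(
    net: SiteNetwork,
    theta: RateParameters,
    tau: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    return_events: bool = False,
):
    """One stochastic realization of the CTMC, observed at time ``tau``.

    Each negative site fires after an exponential waiting time at its
    current activation rate (primary inflow plus inflows from currently
    positive feeders); rates are refreshed after every activation.  With
    ``return_events`` the (time, site name) activation log up to ``tau``
    is returned alongside the final state.
    """
    if tau < 0:
        raise ValueError("observation time must be nonnegative")
    theta.validate_for(net)
    if rng is None:
        rng = np.random.default_rng(seed)
    state = MetastaticState((0,) * net.n_sites)
    events: list[tuple[float, str]] = []
    t = 0.0
    while True:
        rates = np.array(
            [
                net.activation_rate(site, state.status, theta) if state.status[v] == 0 else 0.0
                for v, site in enumerate(net.sites)
            ]
        )
        total = rates.sum()
        if total == 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > tau:
            break
        v = int(rng.choice(net.n_sites, p=rates / total))
        state = state.activate(v)
        events.append((t, net.sites[v]))
    return (state, tuple(events)) if return_events else state
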