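"""Cohort I/O, exclusion filtering, stage-fraction summaries, predictive
marginals, and the end-to-end fitting pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import site_marginals, solve_master_equation
from .inference import (
    Cohort,
    FitResult,
    GrowthParams,
    StageTimeMap,
    fit_mle,
    parametric_bootstrap,
    stage_to_time,
)
from .network import (
    MetastaticState,
    RateParameters,
    SiteNetwork,
    StateSpace,
    build_generator,
    enumerate_reachable_states,
    is_reachable,
    load_network,
)

__all__ = [
    "CohortFormatError",
    "ExclusionReport",
    "read_cohort",
    "write_cohort",
    "exclude_unreachable",
    "stage_fractions",
    "predict_marginals",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class CohortFormatError(ValueError):
    """Raised when a cohort CSV does not match the expected layout."""


@dataclass(frozen=True)
class ExclusionReport:
    """Patients removed because their observed state is topologically unreachable."""

    n_input: int
    n_excluded: int
    excluded: tuple[tuple[str, str], ...]  # (patient_id, state string)

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "fraction_excluded": self.fraction_excluded,
            "excluded": [{"patient_id": pid, "state": st} for pid, st in self.excluded],
        }


def read_cohort(path, net: SiteNetwork, stage_labels: Optional[Sequence[str]] = None) -> Cohort:
    """Read a cohort CSV (columns: patient_id, stage, one 0/1 column per site).

    Site columns are matched by name in any order; every network site must
    be present.  Rows with non-binary status or (when ``stage_labels`` is
    given) an unknown stage label are reported with their line number.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "stage": str})
    for col in ("patient_id", "stage"):
        if col not in df.columns:
            raise CohortFormatError(f"missing required column {col!r}")
    missing = [s for s in net.sites if s not in df.columns]
    if missing:
        raise CohortFormatError(f"missing site column(s) {missing} for network {net.name!r}")

    known = set(stage_labels) if stage_labels is not None else None
    patients, ids = [], []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        stage = str(rec["stage"])
        if known is not None and stage not in known:
            raise CohortFormatError(f"line {row_num}: unknown stage label {stage!r}")
        status = []
        for site in net.sites:
            val = rec[site]
            if val not in (0, 1, "0", "1"):
                raise CohortFormatError(
                    f"line {row_num}: non-binary status {val!r} in column {site!r}"
                )
            status.append(int(val))
        patients.append((stage, MetastaticState(tuple(status))))
        ids.append(str(rec["patient_id"]))
    return Cohort(
        patients=tuple(patients),
        sites=net.sites,
        patient_ids=tuple(ids),
        provenance=str(path),
    )


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV in the layout :func:`read_cohort` expects."""
    ids = cohort.patient_ids or tuple(f"P{k:06d}" for k in range(cohort.n_patients))
    rows = []
    for pid, (stage, state) in zip(ids, cohort.patients):
        row = {"patient_id": pid, "stage": stage}
        row.update({site: state.status[v] for v, site in enumerate(cohort.sites)})
        rows.append(row)
    pd.DataFrame(rows, columns=["patient_id", "stage", *cohort.sites]).to_csv(path, index=False)


def exclude_unreachable(cohort: Cohort, space: StateSpace) -> tuple[Cohort, ExclusionReport]:
    """Drop patients whose observed state cannot arise under the network topology.

    This generalizes the skip-metastasis rule (a positive site whose
    required upstream feeder is negative) to any unreachable state.
    """
    ids = cohort.patient_ids or tuple(f"P{k:06d}" for k in range(cohort.n_patients))
    kept, kept_ids, dropped = [], [], []
    for pid, (stage, state) in zip(ids, cohort.patients):
        if is_reachable(space, state):
            kept.append((stage, state))
            kept_ids.append(pid)
        else:
            dropped.append((pid, str(state)))
    report = ExclusionReport(
        n_input=cohort.n_patients, n_excluded=len(dropped), excluded=tuple(dropped)
    )
    filtered = Cohort(
        patients=tuple(kept),
        sites=cohort.sites,
        patient_ids=tuple(kept_ids),
        provenance=cohort.provenance,
    )
    return filtered, report


def stage_fractions(cohort: Cohort) -> pd.DataFrame:
    """Observed positive fraction per (stage, site).

    Returns a tidy frame with columns ``stage, site, n_pos, N, fraction``;
    a stage with zero patients is simply absent (never divided by zero).
    """
    if cohort.n_patients == 0:
        raise ValueError("empty cohort")
    records = []
    df = pd.DataFrame(
        [(stage, *state.status) for stage, state in cohort.patients],
        columns=["stage", *cohort.sites],
    )
    for stage, group in df.groupby("stage", sort=False):
        for site in cohort.sites:
            n_pos = int(group[site].sum())
            records.append(
                {
                    "stage": stage,
                    "site": site,
                    "n_pos": n_pos,
                    "N": len(group),
                    "fraction": n_pos / len(group),
                }
            )
    return pd.DataFrame(records)


def predict_marginals(
    fit: FitResult,
    net: SiteNetwork,
    space: StateSpace,
    stmap: StageTimeMap,
    stage: str,
) -> dict[str, float]:
    """Model probability of metastasis per site for a tumour of the given stage."""
    tau = stmap.time_of(stage)
    q = build_generator(net, space, fit.theta_hat)
    traj = solve_master_equation(q, [tau], method="expm")
    marg = site_marginals(space, traj.distributions[0])
    return {site: float(marg[v]) for v, site in enumerate(net.sites)}


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: Mapping | str | Path) -> dict:
    """Run read -> exclude -> fit -> bootstrap -> summaries, writing all artifacts.

    ``config`` is a mapping (or path to a YAML file) with keys: ``network``
    (builtin name or spec path), ``cohort`` (CSV path), ``stage_labels``,
    ``stage_map`` ("linear" or "exponential_growth"), optional ``growth``
    ({r0, alpha, stage_radii}), ``bootstrap`` (B; 0 skips), ``seed``,
    ``out_dir``.  Returns the report bundle as a dict.
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_boot = int(config.get("bootstrap", 0))
    cfg_hash = _config_hash(config)
    logger.info("pipeline start: config hash %s, seed %d", cfg_hash, seed)

    net = load_network(config["network"])
    space = enumerate_reachable_states(net)
    stage_labels = [str(s) for s in config["stage_labels"]]
    growth = None
    if "growth" in config:
        g = config["growth"]
        growth = GrowthParams(
            r0=float(g.get("r0", GrowthParams.r0)),
            alpha=float(g.get("alpha", GrowthParams.alpha)),
            stage_radii=tuple(float(r) for r in g["stage_radii"]),
        )
    stmap = stage_to_time(config.get("stage_map", "linear"), stage_labels, growth=growth)

    cohort = read_cohort(config["cohort"], net, stage_labels=stage_labels)
    logger.info("read %d patients from %s", cohort.n_patients, config["cohort"])
    filtered, exclusion = exclude_unreachable(cohort, space)
    logger.info("excluded %d/%d patients", exclusion.n_excluded, exclusion.n_input)

    fit = fit_mle(
        filtered,
        net,
        stmap,
        space=space,
        multistart=int(config.get("multistart", 0)),
        seed=seed,
    )
    logger.info("fit done: logL=%.4f converged=%s", fit.log_likelihood, fit.converged)
    if n_boot > 0:
        intervals = parametric_bootstrap(
            fit, filtered, net, stmap, space=space, n_replicates=n_boot, seed=seed
        )
        fit = fit.with_intervals(intervals)

    fractions = stage_fractions(filtered)
    marg_rows = []
    for stage in stage_labels:
        for site, p in predict_marginals(fit, net, space, stmap, stage).items():
            marg_rows.append({"stage": stage, "site": site, "probability": p})
    marginals = pd.DataFrame(marg_rows)

    fit_payload = {
        "theta_hat": dict(fit.theta_hat.values),
        "log_likelihood": fit.log_likelihood,
        "converged": fit.converged,
        "n_patients": fit.n_patients,
        "bootstrap_intervals": (
            {k: list(v) for k, v in fit.bootstrap_intervals.items()}
            if fit.bootstrap_intervals
            else None
        ),
        "exclusion": exclusion.to_dict(),
        "config": {**config, "hash": cfg_hash},
    }
    (out_dir / "fit.json").write_text(json.dumps(fit_payload, indent=2, default=str) + "\n")
    fractions.to_csv(out_dir / "fractions.csv", index=False)
    marginals.to_csv(out_dir / "marginals.csv", index=False)
    (out_dir / "exclusions.json").write_text(json.dumps(exclusion.to_dict(), indent=2) + "\n")

    if config.get("plots", False):
        _plot_fractions_vs_model(fractions, marginals, out_dir / "fit_overlay.png")

    return {
        "fit": fit,
        "exclusion": exclusion,
        "fractions": fractions,
        "marginals": marginals,
        "out_dir": out_dir,
    }


def _plot_fractions_vs_model(fractions: pd.DataFrame, marginals: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sites = list(dict.fromkeys(marginals["site"]))
    fig, axes = plt.subplots(1, len(sites), figsize=(3 * len(sites), 3), squeeze=False)
    for ax, site in zip(axes[0], sites):
        emp = fractions[fractions["site"] == site]
        mod = marginals[marginals["site"] == site]
        ax.plot(mod["stage"], mod["probability"], "-", label="model")
        ax.plot(emp["stage"], emp["fraction"], "o", label="data")
        ax.set_title(site)
        ax.set_ylim(0, 1)
        ax.set_xlabel("stage")
    axes[0][0].set_ylabel("P(positive)")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
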