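"""Anatomical dissemination networks and their metastatic state spaces.

A :class:`SiteNetwork` is a small directed graph whose nodes are anatomical
sites (lymph-node stations or organs).  Cells flow from the primary tumour
into directly-fed sites at rates named by ``lambda``-style symbols, and
between sites at rates named by ``phi``-style symbols.  The joint metastatic
status of all sites is a binary vector; only monotone single-site
activations are possible, so most of the ``2**N`` binary states are
unreachable and are pruned by :func:`enumerate_reachable_states`.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SiteNetwork",
    "MetastaticState",
    "StateSpace",
    "RateParameters",
    "NetworkSpecError",
    "load_network",
    "builtin_network_names",
    "enumerate_reachable_states",
    "build_generator",
    "is_reachable",
    "state_is_attainable",
]


class NetworkSpecError(ValueError):
    """Raised when a network description document is invalid."""


@dataclass(frozen=True)
class MetastaticState:
    """Binary metastatic status of every site, in network site order.

    The string rendering concatenates the digits in site order, e.g.
    ``"0100"`` means only the second site is positive.
    """

    status: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s not in (0, 1) for s in self.status):
            raise ValueError(f"state entries must be 0/1, got {self.status}")

    @classmethod
    def from_string(cls, s: str) -> "MetastaticState":
        if not set(s) <= {"0", "1"}:
            raise ValueError(f"state string must contain only 0/1, got {s!r}")
        return cls(tuple(int(c) for c in s))

    @property
    def n_sites(self) -> int:
        return len(self.status)

    @property
    def n_positive(self) -> int:
        return sum(self.status)

    def activate(self, site_index: int) -> "MetastaticState":
        """Return the state with one additional positive site."""
        if self.status[site_index] == 1:
            raise ValueError(f"site {site_index} is already positive")
        new = list(self.status)
        new[site_index] = 1
        return MetastaticState(tuple(new))

    def __str__(self) -> str:
        return "".join(str(s) for s in self.status)


@dataclass(frozen=True)
class SiteNetwork:
    """Directed dissemination network with named rate symbols.

    ``primary_edges`` maps a site to the rate symbol of its primary-tumour
    inflow; ``secondary_edges`` maps an ordered site pair ``(u, v)`` to the
    rate symbol of the ``u -> v`` inflow fed by a metastasis at ``u``.
    """

    sites: tuple[str, ...]
    primary_edges: Mapping[str, str]
    secondary_edges: Mapping[tuple[str, str], str]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise NetworkSpecError(f"duplicate site identifiers in {list(self.sites)}")
        known = set(self.sites)
        for site in self.primary_edges:
            if site not in known:
                raise NetworkSpecError(f"primary edge targets unknown site {site!r}")
        for (u, v) in self.secondary_edges:
            if u not in known:
                raise NetworkSpecError(f"secondary edge from unknown site {u!r}")
            if v not in known:
                raise NetworkSpecError(f"secondary edge to unknown site {v!r}")
            if u == v:
                raise NetworkSpecError(f"self-edge on site {u!r} not allowed")
        if not self.primary_edges:
            raise NetworkSpecError("network needs at least one primary edge")
        symbols = list(self.primary_edges.values()) + list(self.secondary_edges.values())
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise NetworkSpecError(f"duplicate rate symbols: {dupes}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def rate_symbols(self) -> tuple[str, ...]:
        """All rate symbols, primary edges first, in site/edge order."""
        syms = [self.primary_edges[s] for s in self.sites if s in self.primary_edges]
        syms += [self.secondary_edges[e] for e in self.secondary_edges]
        return tuple(syms)

    def site_index(self, site: str) -> int:
        return self.sites.index(site)

    def feeders_of(self, site: str) -> tuple[str, ...]:
        """In-network sites with an edge into ``site``."""
        return tuple(u for (u, v) in self.secondary_edges if v == site)

    def activation_rate(self, site: str, positive: Sequence[int], theta: "RateParameters") -> float:
        """Rate at which a negative ``site`` turns positive.

        Equals the primary inflow (if any) plus the sum of inflows from
        currently positive feeders; the primary tumour always sheds.
        """
        rate = 0.0
        if site in self.primary_edges:
            rate += theta.values[self.primary_edges[site]]
        for u in self.feeders_of(site):
            if positive[self.site_index(u)]:
                rate += theta.values[self.secondary_edges[(u, site)]]
        return rate

    def permuted(self, order: Sequence[int]) -> "SiteNetwork":
        """Return the same network with sites listed in a new order."""
        sites = tuple(self.sites[i] for i in order)
        return SiteNetwork(sites, dict(self.primary_edges), dict(self.secondary_edges), name=self.name)


@dataclass(frozen=True)
class RateParameters:
    """Nonnegative rate value per symbol; units are relative (arbitrary 1/time)."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for sym, val in self.values.items():
            if val < 0:
                raise ValueError(f"rate {sym} is negative: {val}")

    @classmethod
    def from_vector(cls, symbols: Sequence[str], vec: Sequence[float]) -> "RateParameters":
        if len(symbols) != len(vec):
            raise ValueError("symbol/value length mismatch")
        return cls(dict(zip(symbols, (float(v) for v in vec))))

    def vector(self, symbols: Sequence[str]) -> np.ndarray:
        return np.array([self.values[s] for s in symbols], dtype=float)

    def validate_for(self, net: SiteNetwork) -> None:
        missing = [s for s in net.rate_symbols if s not in self.values]
        if missing:
            raise KeyError(f"missing rate symbols: {missing}")


@dataclass(frozen=True)
class StateSpace:
    """Ordered reachable metastatic states; the all-negative state is index 0."""

    states: tuple[MetastaticState, ...]
    index_of: Mapping[str, int] = field(hash=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.index_of is None:
            object.__setattr__(self, "index_of", {str(s): i for i, s in enumerate(self.states)})
        if self.states[0].n_positive != 0:
            raise ValueError("all-negative state must come first")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_sites(self) -> int:
        return self.states[0].n_sites

    def index(self, state: MetastaticState | str) -> int:
        return self.index_of[str(state)]

    def __contains__(self, state: object) -> bool:
        return str(state) in self.index_of

    def __iter__(self):
        return iter(self.states)

    def site_membership_matrix(self) -> np.ndarray:
        """(n_sites, n_states) 0/1 matrix: row v marks states with site v positive."""
        return np.array([[s.status[v] for s in self.states] for v in range(self.n_sites)], dtype=float)


# Built-in network fixtures.  "tongue": four cervical lymph-node stations,
# primary feeds I-III, chain I->II->III->IV.  "ovarian": regional lymph
# nodes and four organs, primary feeds LN and lung, everything distal is
# seeded via the lung.
_BUILTINS: dict[str, dict] = {
    "tongue": {
        "sites": ["I", "II", "III", "IV"],
        "primary_edges": {"I": "lambda_I", "II": "lambda_II", "III": "lambda_III"},
        "secondary_edges": [
            {"from": "I", "to": "II", "symbol": "phi_I"},
            {"from": "II", "to": "III", "symbol": "phi_II"},
            {"from": "III", "to": "IV", "symbol": "phi_III"},
        ],
    },
    "ovarian": {
        "sites": ["LN", "lung", "liver", "bone", "brain"],
        "primary_edges": {"LN": "lambda_1", "lung": "lambda_2"},
        "secondary_edges": [
            {"from": "LN", "to": "lung", "symbol": "phi_1"},
            {"from": "lung", "to": "liver", "symbol": "phi_2"},
            {"from": "lung", "to": "bone", "symbol": "phi_3"},
            {"from": "lung", "to": "brain", "symbol": "phi_4"},
        ],
    },
}


def builtin_network_names() -> tuple[str, ...]:
    return tuple(_BUILTINS)


def _network_from_mapping(doc: Mapping, name: str = "custom") -> SiteNetwork:
    try:
        sites = tuple(str(s) for s in doc["sites"])
        primary = {str(k): str(v) for k, v in dict(doc["primary_edges"]).items()}
    except KeyError as exc:
        raise NetworkSpecError(f"network document missing key {exc}") from exc
    secondary: dict[tuple[str, str], str] = {}
    for edge in doc.get("secondary_edges", []):
        key = (str(edge["from"]), str(edge["to"]))
        if key in secondary:
            raise NetworkSpecError(f"duplicate secondary edge {key[0]}->{key[1]}")
        secondary[key] = str(edge["symbol"])
    return SiteNetwork(sites, primary, secondary, name=name)


def load_network(spec: str | Mapping | io.IOBase) -> SiteNetwork:
    """Load a :class:`SiteNetwork` from a builtin name, YAML/JSON path, mapping or stream.

    A plain string is first looked up among the builtin fixtures
    (``tongue``, ``ovarian``) and otherwise treated as a file path.
    """
    if isinstance(spec, Mapping):
        return _network_from_mapping(spec)
    if isinstance(spec, str):
        if spec in _BUILTINS:
            return _network_from_mapping(_BUILTINS[spec], name=spec)
        with open(spec) as fh:
            doc = yaml.safe_load(fh)
        return _network_from_mapping(doc, name=spec)
    doc = yaml.safe_load(spec)
    return _network_from_mapping(doc)


def enumerate_reachable_states(net: SiteNetwork) -> StateSpace:
    """Enumerate every state reachable from the all-negative state.

    A negative site can activate when it has a primary edge or at least one
    positive in-network feeder.  States are ordered breadth-first by number
    of positive sites, lexicographically by status string within a level,
    so indices are deterministic for a given site order.
    """
    n = net.n_sites
    start = MetastaticState((0,) * n)
    seen = {start.status}
    queue = deque([start])
    while queue:
        state = queue.popleft()
        for v, site in enumerate(net.sites):
            if state.status[v] == 1:
                continue
            feeds = site in net.primary_edges or any(
                state.status[net.site_index(u)] for u in net.feeders_of(site)
            )
            if not feeds:
                continue
            nxt = state.activate(v)
            if nxt.status not in seen:
                seen.add(nxt.status)
                queue.append(nxt)
    ordered = sorted((MetastaticState(s) for s in seen), key=lambda st: (st.n_positive, str(st)))
    return StateSpace(tuple(ordered))


def state_is_attainable(net: SiteNetwork, state: MetastaticState) -> bool:
    """Reachability of a single state without enumerating the space.

    Grows the positive set from scratch: a positive site of ``state`` may
    be added once it has a primary edge or an already-added feeder.  The
    state is attainable iff all its positive sites get added.
    """
    target = {net.sites[v] for v, b in enumerate(state.status) if b}
    added: set[str] = set()
    progress = True
    while progress:
        progress = False
        for site in target - added:
            if site in net.primary_edges or any(u in added for u in net.feeders_of(site)):
                added.add(site)
                progress = True
    return added == target


def is_reachable(space: StateSpace, state: MetastaticState | str) -> bool:
    """True iff ``state`` belongs to the reachable state space."""
    if isinstance(state, str):
        state = MetastaticState.from_string(state)
    if state.n_sites != space.n_sites:
        raise ValueError(f"state has {state.n_sites} sites, space has {space.n_sites}")
    return state in space


def build_generator(net: SiteNetwork, space: StateSpace, theta: RateParameters) -> np.ndarray:
    """Assemble the CTMC generator Q over ``space``.

    Convention: ``Q[i, j]`` is the rate of moving from state ``j`` to state
    ``i`` (columns sum to zero), so the master equation reads dP/dt = Q P.
    A transition exists only between states differing by a single site
    flipping 0 -> 1, at the summed inflow rate of that site.
    """
    theta.validate_for(net)
    m = space.n_states
    q = np.zeros((m, m))
    for j, state in enumerate(space.states):
        for v, site in enumerate(net.sites):
            if state.status[v] == 1:
                continue
            rate = net.activation_rate(site, state.status, theta)
            if rate == 0.0:
                continue
            nxt = state.activate(v)
            if nxt in space:
                i = space.index(nxt)
                q[i, j] += rate
        q[j, j] = -q[:, j].sum()
    return q
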