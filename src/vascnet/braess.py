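"""Braess-paradox traffic analogy: affine-latency route networks and
Wardrop user equilibrium.

Remodeling vascular networks behave like drivers on a road network: the
worked example here is the classic four-node diamond.  Each of two routes
from start to end is one constant 45-minute road plus one congestible
road with latency rho/100 minutes (rho = vehicles on that road).  With
4000 vehicles the user equilibrium splits evenly, 2000 per route, and
every driver takes 45 + 20 = 65 min.  Adding a zero-latency bypass
between the interior nodes creates a third route using both congestible
roads; the first adopter enjoys 40 min, but once everyone follows, the
new equilibrium costs 80 min — worse for all.  Removing links (as
remodeling vessel networks do) avoids this adverse regime.

The solver enumerates route support sets; with affine latencies each
support's equal-time condition is a linear solve, so the returned
equilibrium is exact.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Link",
    "TrafficNetwork",
    "EquilibriumResult",
    "build_diamond_network",
    "route_travel_time",
    "wardrop_equilibrium",
    "braess_delta",
    "load_network_yaml",
]


@dataclasses.dataclass(frozen=True)
class Link:
    """Directed road with affine latency l(rho) = a + b·rho (minutes)."""

    src: str
    dst: str
    a: float  # free-flow minutes
    b: float  # minutes per vehicle

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("latency coefficients must be non-negative")

    def latency(self, rho: float) -> float:
        return self.a + self.b * rho


@dataclasses.dataclass
class TrafficNetwork:
    """Directed links plus an explicit list of start→end routes.

    Routes are stored as tuples of link indices; ``route_names`` gives a
    stable label per route.
    """

    nodes: Sequence[str]
    links: Sequence[Link]
    routes: Sequence[tuple[int, ...]]
    route_names: Sequence[str]
    start: str = "start"
    end: str = "end"

    def __post_init__(self):
        if not self.routes:
            raise ValueError("network must declare at least one route")
        for r in self.routes:
            node = self.start
            for li in r:
                link = self.links[li]
                if link.src != node:
                    raise ValueError(f"route {r} is not a connected path")
                node = link.dst
            if node != self.end:
                raise ValueError(f"route {r} does not end at {self.end!r}")

    @property
    def n_routes(self) -> int:
        return len(self.routes)

    def link_flows(self, route_flows: Sequence[float]) -> np.ndarray:
        rho = np.zeros(len(self.links))
        for f, r in zip(route_flows, self.routes):
            for li in r:
                rho[li] += f
        return rho

    def free_flow_times(self) -> np.ndarray:
        return np.array([sum(self.links[li].a for li in r) for r in self.routes])


@dataclasses.dataclass
class EquilibriumResult:
    """Route flows and travel times at Wardrop user equilibrium."""

    route_flows: np.ndarray
    route_times: np.ndarray
    equilibrium_time: float  # common time of used routes (minutes)
    total_demand: float
    route_names: tuple[str, ...]


def build_diamond_network(with_bypass: bool) -> TrafficNetwork:
    """The diamond example: start→γ and ε→end are congestible (rho/100
    min), start→ε and γ→end are constant 45 min; the optional bypass γ→ε
    costs (approximately) zero, giving the third route γ–ε (both
    congestible roads)."""
    links = [
        Link("start", "gamma", 0.0, 1.0 / 100.0),   # orange
        Link("gamma", "end", 45.0, 0.0),            # blue
        Link("start", "epsilon", 45.0, 0.0),        # blue
        Link("epsilon", "end", 0.0, 1.0 / 100.0),   # orange
    ]
    routes = [(0, 1), (2, 3)]
    names = ["upper", "lower"]
    nodes = ["start", "gamma", "epsilon", "end"]
    if with_bypass:
        links.append(Link("gamma", "epsilon", 0.0, 0.0))  # purple bypass
        routes.append((0, 4, 3))
        names.append("bypass")
    return TrafficNetwork(nodes=nodes, links=links,
                          routes=[tuple(r) for r in routes], route_names=names)


def route_travel_time(network: TrafficNetwork, link_flows, route_index: int) -> float:
    """Travel time of one route given per-link flows: sum of a + b·rho."""
    if not 0 <= route_index < network.n_routes:
        raise IndexError("route not in network")
    rho = np.asarray(link_flows, dtype=float)
    if (rho < 0).any():
        raise ValueError("link flows must be non-negative")
    return float(sum(network.links[li].latency(rho[li])
                     for li in network.routes[route_index]))


def _route_times(network: TrafficNetwork, route_flows) -> np.ndarray:
    rho = network.link_flows(route_flows)
    return np.array([route_travel_time(network, rho, i)
                     for i in range(network.n_routes)])


def wardrop_equilibrium(network: TrafficNetwork, total_demand: float,
                        tolerance: float = 1e-6) -> EquilibriumResult:
    """Solve the user equilibrium: all used routes share one travel time
    and no unused route is faster (within ``tolerance`` minutes).

    For each candidate support set of routes, the equal-time + demand
    conditions form a linear system in the route flows (latencies are
    affine); the support whose solution is non-negative and
    equilibrium-consistent is returned.  A user equilibrium always exists
    for non-negative affine latencies.
    """
    if total_demand < 0:
        raise ValueError("total_demand must be >= 0")
    nr = network.n_routes
    if total_demand == 0:
        times = network.free_flow_times()
        return EquilibriumResult(
            route_flows=np.zeros(nr), route_times=times,
            equilibrium_time=float(times.min()), total_demand=0.0,
            route_names=tuple(network.route_names))

    c = network.free_flow_times()
    # M[r, s] = sum of b over links shared by routes r and s
    M = np.zeros((nr, nr))
    for r in range(nr):
        for s in range(nr):
            shared = set(network.routes[r]) & set(network.routes[s])
            M[r, s] = sum(network.links[li].b for li in shared)

    for size in range(1, nr + 1):
        for support in itertools.combinations(range(nr), size):
            sup = list(support)
            # unknowns f_sup; equations: T_r = T_r0 for r in sup, sum f = D
            A = np.zeros((size, size))
            rhs = np.zeros(size)
            r0 = sup[0]
            for row, r in enumerate(sup[1:]):
                A[row, :] = M[r, sup] - M[r0, sup]
                rhs[row] = c[r0] - c[r]
            A[size - 1, :] = 1.0
            rhs[size - 1] = total_demand
            try:
                f_sup = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                # singular support (e.g. duplicate routes): least-squares
                f_sup, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if not np.allclose(A @ f_sup, rhs, atol=1e-6):
                continue
            if (f_sup < -1e-9).any():
                continue
            flows = np.zeros(nr)
            flows[sup] = np.clip(f_sup, 0.0, None)
            times = _route_times(network, flows)
            t_eq = float(times[sup].mean())
            if np.abs(times[sup] - t_eq).max() > max(tolerance, 1e-9):
                continue
            unused = [r for r in range(nr) if r not in support]
            if any(times[r] < t_eq - max(tolerance, 1e-9) for r in unused):
                continue
            return EquilibriumResult(
                route_flows=flows, route_times=times, equilibrium_time=t_eq,
                total_demand=float(total_demand),
                route_names=tuple(network.route_names))
    raise RuntimeError("no equilibrium support found (should not happen for "
                       "affine non-negative latencies)")


def braess_delta(network_without: TrafficNetwork, network_with: TrafficNetwork,
                 total_demand: float) -> float:
    """Change in equilibrium travel time caused by the bypass, in minutes;
    positive = paradox present (the new link hurts everyone)."""
    eq0 = wardrop_equilibrium(network_without, total_demand)
    eq1 = wardrop_equilibrium(network_with, total_demand)
    return eq1.equilibrium_time - eq0.equilibrium_time


def load_network_yaml(path) -> TrafficNetwork:
    """Load a TrafficNetwork from YAML: ``nodes``, ``links`` (src, dst, a,
    b), ``routes`` (node sequences), optional ``start``/``end``."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    links = [Link(l["src"], l["dst"], float(l["a"]), float(l["b"]))
             for l in data["links"]]
    index = {(l.src, l.dst): i for i, l in enumerate(links)}
    routes, names = [], []
    for i, seq in enumerate(data["routes"]):
        routes.append(tuple(index[(a, b)] for a, b in zip(seq, seq[1:])))
        names.append(data.get("route_names", [f"route{j}" for j in
                                              range(len(data["routes"]))])[i])
    return TrafficNetwork(nodes=data["nodes"], links=links, routes=routes,
                          route_names=names,
                          start=data.get("start", "start"),
                          end=data.get("end", "end"))
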