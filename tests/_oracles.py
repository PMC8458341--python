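"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library code paths they check: clustering by
exhaustive neighbour-pair counting, path length by a hand-rolled BFS, and
the traffic user equilibrium by integer enumeration of route splits
minimising the Beckmann potential.
"""

from collections import deque

import numpy as np


def brute_local_clustering(adj: dict, v) -> float:
    nbrs = list(adj[v])
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = 0
    for i in range(k):
        for j in range(i + 1, k):
            if nbrs[j] in adj[nbrs[i]]:
                links += 1
    return 2.0 * links / (k * (k - 1))


def brute_mean_clustering(adj: dict) -> float:
    if not adj:
        return float("nan")
    return sum(brute_local_clustering(adj, v) for v in adj) / len(adj)


def _bfs_dists(adj: dict, src) -> dict:
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def brute_char_path_length(adj: dict) -> float:
    """Mean hop distance over unordered pairs of the largest component."""
    if not adj:
        return float("nan")
    seen = set()
    components = []
    for v in adj:
        if v not in seen:
            comp = set(_bfs_dists(adj, v))
            seen |= comp
            components.append(comp)
    lcc = max(components, key=len)
    if len(lcc) < 2:
        return float("nan")
    total = 0
    npairs = 0
    for v in lcc:
        d = _bfs_dists(adj, v)
        for w in lcc:
            if w != v:
                total += d[w]
                npairs += 1
    return total / npairs


def graph_to_adj(g) -> dict:
    adj = {v: set() for v in g.nodes}
    for u, v in g.edges():
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def wardrop_oracle(network, demand: int):
    """Integer-split user equilibrium by Beckmann-potential minimisation.

    Enumerates every split of ``demand`` vehicles over the routes (step 1)
    and returns (flows, equilibrium_time) at the potential minimum, where
    the equilibrium time is the slowest used route.  Supports 2- or
    3-route networks.
    """
    nr = network.n_routes
    nl = len(network.links)
    a = np.array([l.a for l in network.links])
    b = np.array([l.b for l in network.links])
    R = np.zeros((nl, nr))
    for r, route in enumerate(network.routes):
        for li in route:
            R[li, r] += 1.0

    def used_time(flows):
        rho = R @ flows
        times = np.array([sum(a[li] + b[li] * rho[li] for li in route)
                          for route in network.routes])
        used = flows > 0
        if not used.any():
            return float(times.min())
        return float(times[used].max())

    if demand == 0:
        return np.zeros(nr), used_time(np.zeros(nr))

    if nr == 2:
        f1 = np.arange(demand + 1, dtype=float)
        f = np.stack([f1, demand - f1])       # (2, demand+1)
        rho = R @ f                            # (nl, demand+1)
        phi = (a[:, None] * rho + 0.5 * b[:, None] * rho ** 2).sum(axis=0)
        best = f[:, int(np.argmin(phi))]
        return best, used_time(best)

    if nr == 3:
        best_phi, best = np.inf, None
        for f3 in range(demand + 1):
            f1 = np.arange(demand - f3 + 1, dtype=float)
            f = np.stack([f1, demand - f3 - f1, np.full_like(f1, f3)])
            rho = R @ f
            phi = (a[:, None] * rho + 0.5 * b[:, None] * rho ** 2).sum(axis=0)
            i = int(np.argmin(phi))
            if phi[i] < best_phi:
                best_phi, best = phi[i], f[:, i]
        return best, used_time(best)

    raise NotImplementedError("oracle supports 2 or 3 routes")
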