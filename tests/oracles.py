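"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way (triple
enumeration, union-find, all-pairs sums, high-precision special functions)
and never shares code with the package.
"""

from __future__ import annotations

import numpy as np


def bessel_k(order: int, x: float) -> float:
    """High-precision modified Bessel function of the second kind (mpmath)."""
    import mpmath

    return float(mpmath.besselk(order, x))


def brute_adjacency(positions, threshold: float = 1.0):
    """Adjacency sets from an O(N^2) distance scan with inclusive threshold."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(pos[i] - pos[j])) <= threshold + 1e-9:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def brute_transitivity(adj) -> float:
    """3 * triangles / connected triples by full triple enumeration."""
    nodes = [i for i, s in adj.items() if s]
    triangles = 0
    triples = 0
    for i in nodes:
        for j in nodes:
            for k in nodes:
                if i < j < k:
                    links = (j in adj[i]) + (k in adj[i]) + (k in adj[j])
                    if links == 3:
                        triangles += 1
        ki = len(adj[i])
        triples += ki * (ki - 1) // 2
    return 0.0 if triples == 0 else 3.0 * triangles / triples


def brute_clustering(adj):
    """Per-node clustering by neighbor-pair enumeration; 0 for degree < 2."""
    out = {}
    for i, nbrs in adj.items():
        if not nbrs:
            continue
        k = len(nbrs)
        if k < 2:
            out[i] = 0.0
            continue
        nlist = sorted(nbrs)
        links = sum(
            1
            for a in range(len(nlist))
            for b in range(a + 1, len(nlist))
            if nlist[b] in adj[nlist[a]]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def brute_knn(adj) -> float:
    """Average nearest-neighbor degree over non-isolated nodes."""
    nodes = [i for i, s in adj.items() if s]
    total = 0.0
    for i in nodes:
        total += sum(len(adj[j]) for j in adj[i]) / len(adj[i])
    return total / len(nodes)


class UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def unionfind_components(adj):
    """Component partition of the non-isolated nodes via union-find."""
    nodes = [i for i, s in adj.items() if s]
    uf = UnionFind(nodes)
    for i in nodes:
        for j in adj[i]:
            uf.union(i, j)
    groups = {}
    for i in nodes:
        groups.setdefault(uf.find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: (-len(g), min(g)))


def separation_ode_solution(delta, sigma, r0, t_eval):
    """Separation of a noise-free attracting pair: dr/dt = -2 (delta/sigma) K1(r/sigma).

    Solved with a tight-tolerance adaptive Runge-Kutta integrator,
    independent of the package's Euler stepping.
    """
    from scipy.integrate import solve_ivp
    from scipy.special import k1

    def rhs(_, r):
        return [-2.0 * (delta / sigma) * k1(r[0] / sigma)]

    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), [r0], t_eval=t_eval,
                    rtol=1e-10, atol=1e-12, method="RK45")
    assert sol.success
    return sol.y[0]
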