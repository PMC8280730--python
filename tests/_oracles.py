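"""Independent reference implementations used as test oracles.

Everything here is deliberately primitive (exhaustive enumeration, numerical
rank analysis, plain steepest descent) and shares no code with the package's
production paths.
"""

from __future__ import annotations

import itertools

import numpy as np


# --------------------------------------------------------------------------
# brute-force term enumeration on a graph
# --------------------------------------------------------------------------


def brute_force_angles(edges):
    nodes = sorted({n for e in edges for n in e})
    es = {frozenset(e) for e in edges}
    out = set()
    for i, j, k in itertools.permutations(nodes, 3):
        if frozenset((i, j)) in es and frozenset((j, k)) in es and i < k:
            out.add((i, j, k))
    return out


def brute_force_dihedrals(edges):
    nodes = sorted({n for e in edges for n in e})
    es = {frozenset(e) for e in edges}
    out = set()
    for path in itertools.permutations(nodes, 4):
        i, j, k, l = path
        if (frozenset((i, j)) in es and frozenset((j, k)) in es
                and frozenset((k, l)) in es):
            out.add(min(path, path[::-1]))
    return out


# --------------------------------------------------------------------------
# numerical-rank dependence oracle for separability-breaking couplings
# --------------------------------------------------------------------------


def _coord_grad(x, atoms, kind):
    """Gradient (flattened) of one internal coordinate at configuration x."""
    h = 1e-6

    def value(xf):
        p = [xf[a] for a in atoms]
        if kind == "bond":
            return np.linalg.norm(p[0] - p[1])
        if kind == "angle":
            a = p[0] - p[1]
            b = p[2] - p[1]
            c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            return np.arccos(np.clip(c, -1, 1))
        # dihedral
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        return np.arctan2(np.dot(m1, n2), np.dot(n1, n2))

    n = len(x)
    ids = list(x)
    g = np.zeros(3 * n)
    for ai, a in enumerate(ids):
        for d in range(3):
            xp = {k: v.copy() for k, v in x.items()}
            xm = {k: v.copy() for k, v in x.items()}
            xp[a][d] += h
            xm[a][d] -= h
            g[3 * ai + d] = (value(xp) - value(xm)) / (2 * h)
    return g


def mixed_dependence(topology, dummy_set, seed=0) -> bool:
    """True iff the retained dummy-containing term coordinates are
    algebraically entangled with physical internal coordinates.

    Coordinates considered: every retained term that involves a dummy atom
    (set S), plus the complete geometric internal-coordinate set of the
    physical subgraph (set P: all bonds, angles and 4-paths among physical
    atoms).  A coupling exists iff the Jacobians satisfy
    rank(J_S) + rank(J_P) > rank(J_[S,P]), i.e. some dependence mixes the
    two blocks.  Evaluated at two random generic configurations.
    """
    import networkx as nx

    g = topology.graph()
    phys = [a for a in topology.atoms if a not in dummy_set]
    sub = g.subgraph(phys)

    s_coords = []
    for t in topology.bond_terms + topology.urey_bradley_terms:
        if any(a in dummy_set for a in t.atoms):
            s_coords.append(("bond", t.atoms))
    for t in topology.angle_terms:
        if any(a in dummy_set for a in t.atoms):
            s_coords.append(("angle", t.atoms))
    for t in topology.dihedral_terms:
        if any(a in dummy_set for a in t.atoms):
            s_coords.append(("dihedral", t.atoms))

    p_coords = [("bond", tuple(sorted(e))) for e in sub.edges]
    for c in sub.nodes:
        for a, b in itertools.combinations(sorted(sub.neighbors(c)), 2):
            p_coords.append(("angle", (a, c, b)))
    seen = set()
    for j, k in sub.edges:
        for i in sub.neighbors(j):
            for l in sub.neighbors(k):
                if len({i, j, k, l}) == 4:
                    t = (i, j, k, l)
                    key = min(t, t[::-1])
                    if key not in seen:
                        seen.add(key)
                        p_coords.append(("dihedral", key))

    rng = np.random.default_rng(seed)
    verdicts = []
    for _ in range(2):
        base = topology.coords_array()
        x = {a: base[i] + 0.15 * rng.standard_normal(3)
             for i, a in enumerate(topology.atoms)}
        js = np.array([_coord_grad(x, atoms, kind) for kind, atoms in s_coords]) \
            if s_coords else np.zeros((0, 3 * len(x)))
        jp = np.array([_coord_grad(x, atoms, kind) for kind, atoms in p_coords]) \
            if p_coords else np.zeros((0, 3 * len(x)))
        tol = 1e-7

        def rank(m):
            if not len(m):
                return 0
            sv = np.linalg.svd(m, compute_uv=False)
            return int(np.sum(sv > tol * sv[0])) if sv[0] > 0 else 0

        jall = np.vstack([js, jp])
        verdicts.append(rank(js) + rank(jp) > rank(jall))
    return all(verdicts)


# --------------------------------------------------------------------------
# independent steepest-descent minimizer
# --------------------------------------------------------------------------


def steepest_descent(energy_grad_fn, x0, step=1e-3, max_iter=200000, gtol=1e-6):
    """Plain gradient descent with backtracking; slow but dependency-free."""
    x = np.array(x0, float)
    e, g = energy_grad_fn(x)
    s = step
    for _ in range(max_iter):
        if np.abs(g).max() <= gtol:
            return x, e, True
        xn = x - s * g
        en, gn = energy_grad_fn(xn)
        if en < e:
            x, e, g = xn, en, gn
            s = min(s * 1.2, 1.0)
        else:
            s *= 0.5
            if s < 1e-12:
                return x, e, False
    return x, e, False
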