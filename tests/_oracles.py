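"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit path enumeration,
numerical quadrature, definitional sums of squares — and shares no code
with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

from osteophylo.trees import Phylogeny, RegimeMap


# ------------------------------------------------------ tree path plumbing

def ancestors(tree: Phylogeny, node: int) -> list[int]:
    out = []
    while node != -1:
        out.append(node)
        node = int(tree.parent[node])
    return out


def mrca(tree: Phylogeny, i: int, j: int) -> int:
    ai = ancestors(tree, i)
    aj = set(ancestors(tree, j))
    for a in ai:
        if a in aj:
            return a
    raise RuntimeError("disconnected tree")


def vcv_by_paths(tree: Phylogeny) -> np.ndarray:
    """C by explicit root-to-MRCA path enumeration per tip pair."""
    n = tree.n_tips
    C = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            m = mrca(tree, int(tree.tip_indices[a]), int(tree.tip_indices[b]))
            total = 0.0
            node = m
            while node != 0:
                total += float(tree.blen[node])
                node = int(tree.parent[node])
            C[a, b] = total
    return C


def segments_to_node(tree: Phylogeny, rm: RegimeMap, node: int):
    """(t_start, t_end, state) segments from the root down to ``node``."""
    path = [n for n in reversed(ancestors(tree, node)) if n != 0]
    t = 0.0
    segs = []
    for n in path:
        for s, d in rm.segments[n]:
            segs.append((t, t + d, s))
            t += d
    return segs


# ----------------------------------------------------- BM / EB / OU oracles

def bm_cov_brute(tree: Phylogeny, rm: RegimeMap, sigma2) -> np.ndarray:
    """Multi-rate BM covariance by per-segment accumulation on MRCA paths."""
    n = tree.n_tips
    V = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            m = mrca(tree, int(tree.tip_indices[a]), int(tree.tip_indices[b]))
            for t0, t1, s in segments_to_node(tree, rm, m):
                rate = sigma2[s] if isinstance(sigma2, dict) else sigma2
                V[a, b] += rate * (t1 - t0)
    return V


def bm_loglik_brute(tree, rm, x, sigma2, z0) -> float:
    V = bm_cov_brute(tree, rm, sigma2)
    return float(stats.multivariate_normal(np.full(tree.n_tips, z0), V,
                                           allow_singular=False).logpdf(x))


def eb_loglik_brute(tree, x, sigma2, z0, r) -> float:
    """EB as BM on a quadrature-transformed tree (sigma^2 = 1)."""
    blen = np.zeros(tree.n_nodes)
    for i in range(1, tree.n_nodes):
        t1 = float(tree.depths[tree.parent[i]])
        t2 = float(tree.depths[i])
        val, _ = integrate.quad(lambda t: np.exp(r * t), t1, t2)
        blen[i] = sigma2 * val
    warped = Phylogeny(tree.parent, blen, tree.labels)
    from osteophylo.trees import uniform_regime_map
    rm = uniform_regime_map(warped, "all")
    return bm_loglik_brute(warped, rm, x, 1.0, z0)


def ou_loglik_brute(tree, rm, x, alpha, sigma2, theta) -> float:
    """OU mean and covariance by numerical integration along tip paths."""
    n = tree.n_tips
    T = tree.depths[tree.tip_indices]
    th = (lambda s: theta[s]) if isinstance(theta, dict) else (lambda s: theta)
    z0 = th(rm.root_state)
    mean = np.zeros(n)
    for a in range(n):
        tip = int(tree.tip_indices[a])
        segs = segments_to_node(tree, rm, tip)
        total = z0 * np.exp(-alpha * T[a])
        for t0, t1, s in segs:
            val, _ = integrate.quad(
                lambda t: alpha * th(s) * np.exp(-alpha * (T[a] - t)), t0, t1)
            total += val
        mean[a] = total
    V = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            m = mrca(tree, int(tree.tip_indices[a]), int(tree.tip_indices[b]))
            s_ab = float(tree.depths[m])
            val, _ = integrate.quad(
                lambda t: sigma2 * np.exp(-alpha * (T[a] - t))
                * np.exp(-alpha * (T[b] - t)), 0.0, s_ab)
            V[a, b] = V[b, a] = val
    return float(stats.multivariate_normal(mean, V).logpdf(x))


# ------------------------------------------------------------ random trees

def random_tree(rng: np.random.Generator, n_tips: int,
                ultrametric: bool = False) -> Phylogeny:
    """Random topology by sequential tip attachment, exp branch lengths."""
    from osteophylo.synth import simulate_tree

    tree = simulate_tree(n_tips, seed=int(rng.integers(2**31)),
                         unit_height=ultrametric)
    if ultrametric:
        return tree
    blen = tree.blen.copy()
    blen[1:] = rng.exponential(0.5, size=len(blen) - 1) + 0.05
    return Phylogeny(tree.parent, blen, tree.labels)


def random_regime_map(rng: np.random.Generator, tree: Phylogeny,
                      states: tuple[str, ...]) -> RegimeMap:
    """Random painting: each branch split into 1-3 random-state segments."""
    segs: list[list[tuple[str, float]]] = [[]]
    for i in range(1, tree.n_nodes):
        L = float(tree.blen[i])
        k = int(rng.integers(1, 4))
        cuts = np.sort(rng.random(k - 1)) * L
        bounds = np.concatenate([[0.0], cuts, [L]])
        segs.append([(states[rng.integers(len(states))],
                      float(bounds[j + 1] - bounds[j])) for j in range(k)])
    return RegimeMap(tree, segs, states[rng.integers(len(states))])


# ------------------------------------------------------------------ ANOVA

def anova_f_brute(values, groups):
    """F and p from the definitional sums of squares."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    grand = values.mean()
    ssb = sum(np.sum(groups == g) * (values[groups == g].mean() - grand) ** 2
              for g in levels)
    ssw = sum(np.sum((values[groups == g] - values[groups == g].mean()) ** 2)
              for g in levels)
    df1 = len(levels) - 1
    df2 = len(values) - len(levels)
    F = (ssb / df1) / (ssw / df2)
    return F, float(stats.f.sf(F, df1, df2))


# --------------------------------------------------------------- Mk oracle

def mk2_pair_lik_brute(q: float, t: float, same: bool) -> float:
    """Two-tip, 2-state likelihood from the closed-form P(t), uniform root."""
    p_same = 0.5 * (1 + np.exp(-2 * q * t))
    p_diff = 0.5 * (1 - np.exp(-2 * q * t))
    total = 0.0
    for root in range(2):
        a, b = (0, 0) if same else (0, 1)
        pra = p_same if root == a else p_diff
        prb = p_same if root == b else p_diff
        total += 0.5 * pra * prb
    return total
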