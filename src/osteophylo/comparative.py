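"""Increment-wise group comparisons: ANOVA, Bonferroni gate, RRPP, PLS.

Two complementary views of trait-habit association are provided.  The
ahistorical view treats species as independent: a one-way ANOVA of each
dimensionless trait on locomotor habit at every 5% increment, with
Tukey-Kramer pairwise comparisons, and a Bonferroni family gate across the
19 interior increments (threshold 0.05/19 ~ 0.0026) so pairwise differences
are only reported where the omnibus test survives the correction.

The historical view accounts for shared ancestry.  The phylogenetic ANOVA
whitens data and design by C^{-1/2} (the Brownian-motion covariance from
the tree) and assesses the GLS F statistic by residual randomization in a
permutation procedure (RRPP): residuals of the reduced (intercept-only)
model are permuted, added back to its fitted values, and F recomputed.
A two-block partial least squares statistic measures how strongly habit
clusters on the phylogeny: block A holds tip scores from the
eigendecomposition of the centered C matrix, block B the centered habit
indicators; r_PLS is the correlation of the first pair of singular-vector
scores, with a permutation p-value over tip-to-habit assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .trees import Phylogeny

__all__ = [
    "ANOVAResult",
    "PhyloANOVAResult",
    "PLSResult",
    "anova_tukey",
    "bonferroni_gate",
    "rrpp_phylo_anova",
    "pls_phylo_habit",
]


@dataclass
class ANOVAResult:
    """One-way ANOVA with Tukey-Kramer pairwise comparisons."""

    F: float
    df_between: int
    df_within: int
    p_omnibus: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj
    increment: int | None = None
    trait: str | None = None
    gate_passed: bool | None = None


def anova_tukey(values, groups, increment: int | None = None,
                trait: str | None = None) -> ANOVAResult:
    """Classical one-way F test plus Tukey HSD (Tukey-Kramer for unequal n).

    Degenerate data with zero variance within and between groups returns
    F = 0 and p = 1 throughout rather than NaN.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    by = {g: values[groups == g] for g in levels}
    for g, v in by.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    n = len(values)
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    df_b = len(levels) - 1
    df_w = n - len(levels)
    pairs = list(combinations(levels, 2))
    if ss_within <= 1e-30 * max(ss_between, 1.0) and ss_between <= 1e-30:
        tukey = pd.DataFrame(
            [{"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0}
             for a, b in pairs])
        return ANOVAResult(0.0, df_b, df_w, 1.0, tukey, increment, trait)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hsd = pairwise_tukeyhsd(values, groups, alpha=0.05)
    tukey = pd.DataFrame({
        "group1": [p1 for p1, _ in pairs],
        "group2": [p2 for _, p2 in pairs],
        "meandiff": hsd.meandiffs,
        "p_adj": hsd.pvalues,
    })
    return ANOVAResult(float(F), df_b, df_w, p, tukey, increment, trait)


def bonferroni_gate(results: list[ANOVAResult],
                    family_alpha: float = 0.05) -> list[ANOVAResult]:
    """Gate pairwise reporting on the Bonferroni-corrected omnibus p.

    The threshold is family_alpha divided by the number of increments in
    the family (0.05/19 ~ 0.0026 for the standard 19 interior increments);
    an increment whose omnibus p exceeds it reports no pairwise
    differences, whatever the raw Tukey p-values say.
    """
    m = len(results)
    if m == 0:
        raise ValueError("no ANOVA results to gate")
    if m != 19:
        warnings.warn(f"Bonferroni family has {m} increments, not 19; "
                      f"threshold is {family_alpha}/{m}", stacklevel=2)
    threshold = family_alpha / m
    gated = []
    for r in results:
        passed = r.p_omnibus <= threshold
        tukey = r.tukey if passed else r.tukey.iloc[0:0]
        gated.append(ANOVAResult(r.F, r.df_between, r.df_within, r.p_omnibus,
                                 tukey, r.increment, r.trait, gate_passed=passed))
    return gated


# ------------------------------------------------------------------- RRPP

@dataclass
class PhyloANOVAResult:
    F_gls: float
    p_perm: float
    n_permutations: int
    seed: int
    increment: int | None = None
    trait: str | None = None


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    vals, vecs = linalg.eigh(C)
    if vals.min() <= 1e-10 * vals.max():
        raise linalg.LinAlgError(
            "singular phylogenetic covariance (zero branch lengths "
            "collapsing tips?)")
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def _design(groups: np.ndarray) -> np.ndarray:
    levels = sorted(pd.unique(groups).tolist())
    X = np.ones((len(groups), len(levels)))
    for j, g in enumerate(levels[1:], start=1):
        X[:, j] = (groups == g).astype(float)
    return X


def rrpp_phylo_anova(tree: Phylogeny, values, groups, n_perm: int = 999,
                     seed: int = 0, increment: int | None = None,
                     trait: str | None = None) -> PhyloANOVAResult:
    """Phylogenetic ANOVA by residual randomization (RRPP).

    ``values`` and ``groups`` may be label-indexed Series aligned to the
    tree's tips.  The GLS F compares the habit model to the intercept-only
    model after whitening by C^{-1/2}; significance comes from permuting
    reduced-model residuals, with p = (#{F* >= F} + 1) / (n_perm + 1).
    """
    if isinstance(values, pd.Series):
        values = values.reindex(tree.tip_labels).to_numpy(dtype=float)
    if isinstance(groups, pd.Series):
        groups = groups.reindex(tree.tip_labels).to_numpy()
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = tree.n_tips
    if len(values) != n or len(groups) != n:
        raise ValueError("values/groups do not match the tree's tips")
    C, _ = tree.vcv()
    P = _inv_sqrt(C)
    y = P @ values
    Xf = P @ _design(groups)
    Xr = P @ np.ones((n, 1))
    Hf = Xf @ np.linalg.pinv(Xf)
    Hr = Xr @ np.linalg.pinv(Xr)
    df1 = np.linalg.matrix_rank(Xf) - np.linalg.matrix_rank(Xr)
    df2 = n - np.linalg.matrix_rank(Xf)

    def f_stat(Y):
        rss_f = np.sum((Y - Hf @ Y) ** 2, axis=0)
        rss_r = np.sum((Y - Hr @ Y) ** 2, axis=0)
        return ((rss_r - rss_f) / df1) / (rss_f / df2)

    F_obs = float(f_stat(y[:, None])[0])
    fitted_r = Hr @ y
    resid_r = y - fitted_r
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)]).T  # n x n_perm
    Y_perm = fitted_r[:, None] + resid_r[perms]
    F_perm = f_stat(Y_perm)
    p = (np.sum(F_perm >= F_obs) + 1) / (n_perm + 1)
    return PhyloANOVAResult(F_obs, float(p), n_perm, seed, increment, trait)


# -------------------------------------------------------------------- PLS

@dataclass
class PLSResult:
    r_pls: float
    p_perm: float
    n_permutations: int
    seed: int


def _phylo_scores(tree: Phylogeny) -> np.ndarray:
    """Tip scores from the eigendecomposition of the centered C matrix."""
    C, _ = tree.vcv()
    n = C.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Cc = J @ C @ J
    vals, vecs = linalg.eigh(Cc)
    keep = vals > 1e-10 * max(vals.max(), 1.0)
    return vecs[:, keep] * np.sqrt(vals[keep])


def _r_pls(A: np.ndarray, B: np.ndarray) -> float:
    n = A.shape[0]
    S = (A - A.mean(0)).T @ (B - B.mean(0)) / (n - 1)
    U, _, Vt = np.linalg.svd(S, full_matrices=False)
    u = A @ U[:, 0]
    v = B @ Vt[0]
    if u.std() == 0 or v.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(u, v)[0, 1]))


def pls_phylo_habit(tree: Phylogeny, groups, n_perm: int = 999,
                    seed: int = 0) -> PLSResult:
    """Two-block PLS correlation between phylogeny and habit membership.

    Block A: phylogenetic tip scores; block B: centered habit indicator
    matrix.  r_PLS is the correlation of the first singular-vector score
    pair of the cross-block covariance; the null permutes which tip carries
    which habit.
    """
    if isinstance(groups, pd.Series):
        groups = groups.reindex(tree.tip_labels).to_numpy()
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least two habit levels")
    n = tree.n_tips
    if len(groups) != n:
        raise ValueError("groups do not match the tree's tips")
    A = _phylo_scores(tree)
    B = np.column_stack([(groups == g).astype(float) for g in levels])
    B = B - B.mean(0)
    r_obs = _r_pls(A, B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Bp = B[rng.permutation(n)]
        if _r_pls(A, Bp) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PLSResult(r_obs, float(p), n_perm, seed)
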