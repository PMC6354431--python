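"""Mk fitting, stochastic character mapping, and model fitting across maps.

Locomotor habits are observed only at the tips; the regime histories the
multi-rate and multi-optimum trait models need are latent.  Following the
stochastic-mapping approach, an equal-rates continuous-time Markov (Mk)
model is fitted to the tip states by Felsenstein pruning, many complete
branch histories consistent with the tips are sampled from its conditional
distribution, trait models are fitted on every sampled history, and AICc
values and parameters are averaged across the sample (500 maps in the
reference design; configurable).

Branch paths conditioned on endpoint states are drawn by rejection sampling
of forward Mk realizations, with a uniformization sampler as a guaranteed-
termination fallback for improbable endpoint combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .evomodels import (MODEL_NAMES, ModelFitResult, akaike_weights,
                        alpha_significance, fit_model)
from .trees import Phylogeny, RegimeMap

__all__ = [
    "MkFit",
    "MapEnsemble",
    "ModelComparison",
    "fit_mk_er",
    "sample_histories",
    "fit_across_maps",
    "THREE_REGIME_MAPPING",
]

# the three-regime scheme keeps the two specialised swimming/climbing
# habits distinct and pools the remaining lineages
THREE_REGIME_MAPPING = {"fossorial": "other", "generalist": "other"}


def _er_pmat(q: float, t: float, k: int) -> np.ndarray:
    """Equal-rates Mk transition matrix exp(Qt) in closed form."""
    e = np.exp(-k * q * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, (1.0 + (k - 1) * e) / k)
    return P


def _pruning(tree: Phylogeny, tip_state_idx: np.ndarray, q: float, k: int):
    """Downpass conditional likelihoods; returns (L, log-scale, lnL)."""
    L = np.zeros((tree.n_nodes, k))
    logscale = 0.0
    pmats = [None] * tree.n_nodes
    for i in range(1, tree.n_nodes):
        pmats[i] = _er_pmat(q, float(tree.blen[i]), k)
    tip_pos = {int(n): p for p, n in enumerate(tree.tip_indices)}
    for i in tree.postorder():
        if not tree.children[i]:
            L[i, tip_state_idx[tip_pos[i]]] = 1.0
        else:
            v = np.ones(k)
            for c in tree.children[i]:
                v = v * (pmats[c] @ L[c])
            m = v.max()
            if m <= 0:
                return L, -np.inf, -np.inf
            L[i] = v / m
            logscale += np.log(m)
    lnL = float(np.log(L[0].mean()) + logscale)  # uniform root prior
    return L, pmats, lnL


@dataclass
class MkFit:
    """Fitted equal-rates Mk model for the habit character."""

    q: float
    lnL: float
    k_states: int
    states: tuple[str, ...]
    at_bound: bool = False
    converged: bool = True


def fit_mk_er(tree: Phylogeny, tip_states: dict[str, str],
              states: tuple[str, ...] | None = None) -> MkFit:
    """ML estimate of the single transition rate of the equal-rates Mk model.

    The likelihood is computed by Felsenstein pruning with a uniform root
    prior; ``q`` is the rate of each specific i->j transition.  A character
    with a single observed state drives q to its lower bound, which is
    returned flagged rather than hidden.
    """
    if states is None:
        states = tuple(sorted(set(tip_states.values())))
    k = len(states)
    idx = {s: j for j, s in enumerate(states)}
    obs = np.array([idx[tip_states[lab]] for lab in tree.tip_labels])
    h = tree.height
    lo, hi = 1e-8 / h, 500.0 / h
    if len(set(obs.tolist())) < 2:
        _, _, lnL = _pruning(tree, obs, lo, k)
        return MkFit(lo, lnL, k, states, at_bound=True, converged=False)

    def neg(logq):
        return -_pruning(tree, obs, float(np.exp(logq)), k)[2]

    grid = np.log(np.geomspace(lo, hi, 30))
    vals = [neg(g) for g in grid]
    j = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        neg, bounds=(grid[max(0, j - 1)], grid[min(len(grid) - 1, j + 1)]),
        method="bounded", options={"xatol": 1e-10},
    )
    q = float(np.exp(res.x))
    lnL = -float(res.fun)
    return MkFit(q, lnL, k, states, at_bound=q <= lo * 3 or q >= hi / 1.5)


# ------------------------------------------------------------ path sampling

def _sample_path_rejection(rng, a: int, b: int, t: float, q: float, k: int,
                           max_tries: int = 10_000):
    """Forward-simulate Mk from state a, accept paths ending in b."""
    leave = (k - 1) * q
    for _ in range(max_tries):
        s = a
        times, states = [], []
        u = 0.0
        while True:
            w = rng.exponential(1.0 / leave)
            if u + w >= t:
                break
            u += w
            s = (s + 1 + rng.integers(k - 1)) % k
            times.append(u)
            states.append(s)
        if s == b:
            return times, states
    return None


def _er_rn(n: int, k: int) -> float:
    """Closed-form entries of R^n for the uniformized ER jump chain.

    R has zero diagonal and 1/(k-1) off-diagonal; R^n = (1/k) J +
    (I - J/k) (-1/(k-1))^n, returned as (diag entry, off entry).
    """
    lam = (-1.0 / (k - 1)) ** n
    return 1.0 / k + (1 - 1.0 / k) * lam, (1.0 - lam) / k


def _sample_path_uniformized(rng, a: int, b: int, t: float, q: float, k: int):
    """Exact endpoint-conditioned path via uniformization (rate (k-1)q)."""
    mu = (k - 1) * q
    e = np.exp(-k * q * t)
    p_ab = (1.0 + (k - 1) * e) / k if a == b else (1.0 - e) / k
    # sample the jump count N | endpoints
    u = rng.random() * p_ab
    log_pois = -mu * t
    cum = 0.0
    n = 0
    pois = np.exp(log_pois)
    while True:
        dn, on = _er_rn(n, k)
        rn_ab = dn if a == b else on
        cum += pois * rn_ab
        if cum >= u or n > 10_000:
            break
        n += 1
        pois *= mu * t / n
    # jump times: order statistics of n uniforms on (0, t)
    jump_times = np.sort(rng.random(n) * t)
    # sequential intermediate states
    states = []
    s = a
    for m in range(1, n + 1):
        rem = n - m
        dn, on = _er_rn(rem, k)
        probs = np.empty(k)
        for c in range(k):
            r_sc = 0.0 if c == s else 1.0 / (k - 1)
            rn_cb = dn if c == b else on
            probs[c] = r_sc * rn_cb
        tot = probs.sum()
        if tot <= 0:  # numerically stranded; restart from rejection cap
            raise RuntimeError("uniformization dead end")
        s = int(rng.choice(k, p=probs / tot))
        states.append(s)
    if n > 0 and states[-1] != b:
        raise RuntimeError("uniformization endpoint mismatch")
    if n == 0 and a != b:
        raise RuntimeError("uniformization sampled zero jumps for a != b")
    return list(jump_times), states


@dataclass
class MapEnsemble:
    """A sample of regime histories conditioned on the observed tips."""

    maps: list[RegimeMap]
    mk: MkFit
    seed: int

    def __len__(self):
        return len(self.maps)

    def write(self, directory) -> None:
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = []
        for i, m in enumerate(self.maps):
            name = f"map_{i:04d}.tsv"
            (directory / name).write_text(m.to_text())
            index.append({"map": i, "file": name, "n_changes": m.n_changes()})
        pd.DataFrame(index).to_csv(directory / "index.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory, tree: Phylogeny, mk: MkFit, seed: int = 0) -> "MapEnsemble":
        from pathlib import Path
        directory = Path(directory)
        index = pd.read_csv(directory / "index.tsv", sep="\t")
        maps = [RegimeMap.from_text(tree, (directory / f).read_text())
                for f in index["file"]]
        return cls(maps, mk, seed)


def sample_histories(tree: Phylogeny, tip_states: dict[str, str], mk: MkFit,
                     n_maps: int = 500, seed: int = 0,
                     max_tries: int = 10_000) -> MapEnsemble:
    """Sample complete regime histories consistent with the tip habits.

    Per map: node states are drawn root-down from the pruning conditionals
    (uniform root prior), then each branch's path is drawn conditional on
    its endpoint states — by rejection up to ``max_tries`` forward
    simulations, falling back to exact uniformization sampling.
    """
    k = mk.k_states
    states = mk.states
    idx = {s: j for j, s in enumerate(states)}
    obs = np.array([idx[tip_states[lab]] for lab in tree.tip_labels])
    L, pmats, lnL = _pruning(tree, obs, mk.q, k)
    if not np.isfinite(lnL):
        raise ValueError("tip states have zero likelihood under the Mk fit")
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=int)
        pr = L[0] / L[0].sum()
        node_state[0] = rng.choice(k, p=pr)
        segments: list[list[tuple[str, float]]] = [[] for _ in range(tree.n_nodes)]
        for i in range(1, tree.n_nodes):
            sp = node_state[tree.parent[i]]
            w = pmats[i][sp] * L[i]
            node_state[i] = rng.choice(k, p=w / w.sum())
            a, b, t = int(sp), int(node_state[i]), float(tree.blen[i])
            if t == 0:
                if a != b:
                    raise RuntimeError(f"state change on zero-length branch {i}")
                segments[i] = [(states[a], 0.0)]
                continue
            path = _sample_path_rejection(rng, a, b, t, mk.q, k, max_tries)
            if path is None:
                try:
                    path = _sample_path_uniformized(rng, a, b, t, mk.q, k)
                except RuntimeError as exc:
                    raise RuntimeError(
                        f"path sampling failed on branch to node {i} "
                        f"({states[a]}->{states[b]}, length {t}): {exc}"
                    ) from exc
            times, path_states = path
            segs = []
            prev_t, prev_s = 0.0, a
            for u, s in zip(times, path_states):
                segs.append((states[prev_s], u - prev_t))
                prev_t, prev_s = u, s
            segs.append((states[prev_s], t - prev_t))
            segments[i] = segs
        maps.append(RegimeMap(tree, segments, states[node_state[0]]))
    return MapEnsemble(maps, mk, seed)


# ------------------------------------------------------- fits across maps

@dataclass
class ModelComparison:
    """Per-model mean AICc, weights and diagnostics for one trait."""

    table: pd.DataFrame          # index: model; mean_aicc, weight, k, n_ok, ...
    mean_params: dict[str, dict]
    best_model: str
    alpha_flags: dict[str, bool]
    unreliable: list[str] = field(default_factory=list)


def _mean_params(fits: list[ModelFitResult]) -> dict:
    out: dict = {}
    keys = fits[0].params.keys()
    for key in keys:
        vals = [f.params[key] for f in fits]
        if isinstance(vals[0], dict):
            out[key] = {s: float(np.mean([v[s] for v in vals])) for s in vals[0]}
        else:
            out[key] = float(np.mean(vals))
    return out


def fit_across_maps(tree: Phylogeny, ensemble: MapEnsemble, x,
                    models: tuple[str, ...] = MODEL_NAMES, seed: int = 0,
                    three_regime_mapping: dict[str, str] | None = None,
                    ) -> ModelComparison:
    """Fit every model on every sampled history; compare by mean AICc.

    Regime-free models (BM1, OU1, EB) are fitted once.  Three-regime models
    collapse the sampled four-state histories via ``three_regime_mapping``
    (default: pool fossorial + generalist).  Per model, AICc and parameters
    are arithmetic means over maps; Akaike weights come from the mean AICc;
    the best model has the lowest mean AICc with exact ties broken toward
    fewer parameters.  Unconverged fits are dropped from the average; a
    model losing more than half its fits is marked unreliable.
    """
    if not len(ensemble):
        raise ValueError("empty map ensemble")
    if three_regime_mapping is None:
        three_regime_mapping = THREE_REGIME_MAPPING
    height = tree.height
    rows = []
    mean_params: dict[str, dict] = {}
    alpha_flags: dict[str, bool] = {}
    unreliable: list[str] = []
    dropped: dict[str, int] = {}
    for model in models:
        needs_map = model in ("BM3", "BM4", "OU3", "OU4")
        if not needs_map:
            fits = [fit_model(tree, x, model, seed=seed)]
        else:
            fits = []
            n_drop = 0
            for j, rm in enumerate(ensemble.maps):
                if model in ("BM3", "OU3"):
                    rm = rm.relabel(three_regime_mapping)
                try:
                    f = fit_model(tree, x, model, regime_map=rm, seed=seed + j)
                except ValueError:
                    # a map may not realise every regime (e.g. a habit never
                    # visits the tree interior); such maps cannot inform a
                    # model that requires that regime
                    n_drop += 1
                    continue
                if f.converged:
                    fits.append(f)
                else:
                    n_drop += 1
            dropped[model] = n_drop
            if not fits or n_drop > len(ensemble) / 2:
                unreliable.append(model)
            if not fits:
                rows.append({"model": model, "mean_aicc": np.inf, "k": np.nan,
                             "mean_lnL": np.nan, "n_ok": 0})
                continue
        mean_aicc = float(np.mean([f.aicc for f in fits]))
        mean_params[model] = _mean_params(fits)
        rows.append({"model": model, "mean_aicc": mean_aicc, "k": fits[0].k,
                     "mean_lnL": float(np.mean([f.lnL for f in fits])),
                     "n_ok": len(fits)})
        if model.startswith("OU"):
            flags = []
            for f in fits:
                if f.alpha_se is not None or f.alpha_at_bound:
                    flags.append(alpha_significance(f, tree_height=height).significant)
            alpha_flags[model] = bool(flags) and (np.mean(flags) > 0.5)
    table = pd.DataFrame(rows).set_index("model")
    finite = table["mean_aicc"].replace(np.inf, np.nan).dropna()
    w = akaike_weights(finite) if len(finite) >= 2 else pd.Series(1.0, index=finite.index)
    table["weight"] = w.reindex(table.index).fillna(0.0)
    # best: lowest mean AICc, exact ties -> fewer parameters
    cand = table.loc[finite.index]
    best_aicc = cand["mean_aicc"].min()
    ties = cand[cand["mean_aicc"] == best_aicc]
    best = ties.sort_values("k").index[0]
    return ModelComparison(table=table, mean_params=mean_params,
                           best_model=str(best), alpha_flags=alpha_flags,
                           unreliable=unreliable)
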