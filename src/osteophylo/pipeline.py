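"""End-to-end orchestration: geometry -> statistics -> model selection.

A run is described by a :class:`RunConfig` (plain-text YAML, ~20 knobs) and
produces TSV tables: the per-specimen trait table, the gated ANOVA/Tukey
significance matrix, phylogenetic ANOVA and PLS results, the per-increment
model-comparison table, a best-model summary, and a JSON manifest recording
the configuration and seeds so a run can be reproduced byte-for-byte.

Stochastic stages draw their seeds from the master seed through a stable
string hash of the task identity, so results do not depend on execution
order.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative import anova_tukey, bonferroni_gate, pls_phylo_habit, rrpp_phylo_anova
from .evomodels import MODEL_NAMES
from .geometry import extract_profile, read_stack
from .simmap import fit_across_maps, fit_mk_er, sample_histories
from .trees import Phylogeny

__all__ = ["RunConfig", "run_pipeline", "summarize_best_models", "derive_seed"]

DIMENSIONLESS_TRAITS = ("csa_d", "sma_ml_d", "sma_cc_d", "mod_ml_d",
                        "mod_cc_d", "r_ml", "r_cc")
INTERIOR_INCREMENTS = tuple(range(5, 100, 5))


def derive_seed(master: int, *parts) -> int:
    """Stable per-task seed: CRC32 of the task identity mixed with master."""
    tag = zlib.crc32("|".join(str(p) for p in parts).encode())
    return int(np.random.SeedSequence([int(master), tag]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All knobs of one pipeline run (YAML-serializable)."""

    tree: str = ""
    habits: str = ""
    trait_table: str = ""              # precomputed long-format trait TSV
    stacks: list[str] = field(default_factory=list)  # or slice directories
    output_dir: str = "osteophylo_out"
    traits: list[str] = field(default_factory=lambda: list(DIMENSIONLESS_TRAITS))
    increments: list[int] = field(default_factory=lambda: list(INTERIOR_INCREMENTS))
    models: list[str] = field(default_factory=lambda: list(MODEL_NAMES))
    n_maps: int = 500
    n_perm: int = 999
    family_alpha: float = 0.05
    seed: int = 0
    rotate: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def validate(self) -> None:
        if not self.trait_table and not self.stacks:
            raise ValueError("config needs either trait_table or stacks")
        for p in [self.tree, self.habits, self.trait_table, *self.stacks]:
            if p and not Path(p).exists():
                raise FileNotFoundError(p)


def load_trait_table(config: RunConfig) -> pd.DataFrame:
    if config.trait_table:
        df = pd.read_csv(config.trait_table, sep="\t")
    else:
        frames = []
        for d in config.stacks:
            stack = read_stack(d, rotate=config.rotate)
            frames.append(extract_profile(stack).to_frame())
        df = pd.concat(frames, ignore_index=True)
    if "species" not in df.columns:
        df["species"] = df["specimen_id"]
    if "bone" not in df.columns:
        df["bone"] = "humerus"
    return df


def species_means(df: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Average multiple specimens to one value per species/bone/increment."""
    cols = [t for t in traits if t in df.columns]
    return (df.groupby(["species", "bone", "increment_pct"], as_index=False)[cols]
            .mean())


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the output bundle.

    Stages: trait extraction (or table load), species averaging, per-trait
    per-increment ANOVA + Tukey with the Bonferroni gate, phylogenetic
    ANOVA + PLS, stochastic mapping + model comparison, best-model summary,
    and a reproducibility manifest.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    df = load_trait_table(config)
    traits = [t for t in config.traits if t in df.columns]
    if not traits:
        raise ValueError("none of the configured traits appear in the table")
    written["traits"] = out / "traits.tsv"
    df.to_csv(written["traits"], sep="\t", index=False)

    means = species_means(df, traits)
    habits = pd.read_csv(config.habits, sep="\t").set_index("species")["habit"]
    tree = Phylogeny.read(config.tree)
    missing = set(tree.tip_labels) - set(means["species"])
    if missing:
        raise ValueError(f"trait table lacks tree tips: {sorted(missing)}")

    # ---------------------------------------------- ahistorical ANOVA
    anova_rows, tukey_rows = [], []
    for bone in sorted(means["bone"].unique()):
        sub = means[means["bone"] == bone]
        for trait in traits:
            results = []
            for inc in config.increments:
                at = sub[sub["increment_pct"] == inc]
                res = anova_tukey(at[trait].to_numpy(),
                                  habits.reindex(at["species"]).to_numpy(),
                                  increment=inc, trait=trait)
                results.append(res)
            for res in bonferroni_gate(results, config.family_alpha):
                anova_rows.append({
                    "bone": bone, "trait": trait, "increment_pct": res.increment,
                    "F": res.F, "df_between": res.df_between,
                    "df_within": res.df_within, "p_omnibus": res.p_omnibus,
                    "gate_passed": res.gate_passed,
                })
                for _, row in res.tukey.iterrows():
                    tukey_rows.append({
                        "bone": bone, "trait": trait,
                        "increment_pct": res.increment,
                        "group1": row["group1"], "group2": row["group2"],
                        "meandiff": row["meandiff"], "p_adj": row["p_adj"],
                        "significant": row["p_adj"] <= 0.05,
                    })
    written["anova"] = out / "anova.tsv"
    pd.DataFrame(anova_rows).to_csv(written["anova"], sep="\t", index=False)
    written["tukey"] = out / "tukey_gated.tsv"
    pd.DataFrame(tukey_rows).to_csv(written["tukey"], sep="\t", index=False)

    # ------------------------------------------- phylogenetic ANOVA + PLS
    phylo_rows = []
    for bone in sorted(means["bone"].unique()):
        sub = means[means["bone"] == bone]
        for trait in traits:
            for inc in config.increments:
                at = sub[sub["increment_pct"] == inc].set_index("species")
                res = rrpp_phylo_anova(
                    tree, at[trait], habits, n_perm=config.n_perm,
                    seed=derive_seed(config.seed, "rrpp", bone, trait, inc),
                    increment=inc, trait=trait)
                phylo_rows.append({
                    "bone": bone, "trait": trait, "increment_pct": inc,
                    "F_gls": res.F_gls, "p_perm": res.p_perm,
                    "n_permutations": res.n_permutations, "seed": res.seed,
                })
    written["phylo_anova"] = out / "phylo_anova.tsv"
    pd.DataFrame(phylo_rows).to_csv(written["phylo_anova"], sep="\t", index=False)

    pls = pls_phylo_habit(tree, habits, n_perm=config.n_perm,
                          seed=derive_seed(config.seed, "pls"))
    written["pls"] = out / "pls.tsv"
    pd.DataFrame([{"r_pls": pls.r_pls, "p_perm": pls.p_perm,
                   "n_permutations": pls.n_permutations,
                   "seed": pls.seed}]).to_csv(written["pls"], sep="\t", index=False)

    # -------------------------------------- stochastic maps + model fits
    tip_states = {s: habits[s] for s in tree.tip_labels}
    mk = fit_mk_er(tree, tip_states)
    ensemble = sample_histories(tree, tip_states, mk, n_maps=config.n_maps,
                                seed=derive_seed(config.seed, "simmap"))
    comp_rows = []
    for bone in sorted(means["bone"].unique()):
        sub = means[means["bone"] == bone]
        for trait in traits:
            for inc in config.increments:
                at = sub[sub["increment_pct"] == inc].set_index("species")
                comp = fit_across_maps(
                    tree, ensemble, at[trait], models=tuple(config.models),
                    seed=derive_seed(config.seed, "fit", bone, trait, inc))
                for model, row in comp.table.iterrows():
                    comp_rows.append({
                        "bone": bone, "trait": trait, "increment_pct": inc,
                        "model": model, "mean_aicc": row["mean_aicc"],
                        "mean_lnL": row["mean_lnL"], "k": row["k"],
                        "n_ok": row["n_ok"], "weight": row["weight"],
                        "best": model == comp.best_model,
                        "alpha_significant": comp.alpha_flags.get(model, False),
                        "unreliable": model in comp.unreliable,
                    })
    comp_df = pd.DataFrame(comp_rows)
    written["model_comparison"] = out / "model_comparison.tsv"
    comp_df.to_csv(written["model_comparison"], sep="\t", index=False)

    summary = summarize_best_models(comp_df)
    written["best_models"] = out / "best_model_summary.tsv"
    summary.to_csv(written["best_models"], sep="\t", index=False)

    manifest = {
        "package": "osteophylo",
        "version": __version__,
        "config": asdict(config),
        "mk_rate": mk.q,
        "mk_lnL": mk.lnL,
        "n_maps": len(ensemble),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    written["manifest"] = out / "manifest.json"
    written["manifest"].write_text(json.dumps(manifest, indent=2))
    return written


def summarize_best_models(comparison: pd.DataFrame) -> pd.DataFrame:
    """Best-model counts per model, with significant-alpha sub-counts.

    One row per (bone, trait, model): the number of increments where the
    model had the lowest mean AICc, and — for OU models — how many of those
    wins also showed an attraction strength significantly above zero.
    """
    rows = []
    for (bone, trait), grp in comparison.groupby(["bone", "trait"]):
        for model in grp["model"].unique():
            sub = grp[(grp["model"] == model) & grp["best"]]
            n_best = int(len(sub))
            n_sig = int(sub["alpha_significant"].sum()) if model.startswith("OU") else 0
            rows.append({"bone": bone, "trait": trait, "model": model,
                         "n_best_increments": n_best,
                         "n_alpha_significant": n_sig})
    return pd.DataFrame(rows)
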