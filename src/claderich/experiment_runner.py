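"""Replicated clade-sampling experiments and summary tables.

The main entry point, :func:`run_replicates`, repeats the full analysis
chain — sample clades, resolve nesting, measure ages and richness,
estimate diversification rates, apply exclusion filters, build the reduced
one-tip-per-clade tree, and fit four regressions — over ``n_replicates``
independent clade sets, then averages r^2 and p across replicates and
reports the percentage of significant replicates per relationship, in the
layout of a published summary table (rows: richness~age, richness~rate,
rate~age, richness~age+rate).

Also provided: the incomplete-sampling experiment (re-run on a randomly
thinned tree), substitution of described species richness for in-tree tip
counts with rank escalation, a paired t-test comparing r^2 sets between
approaches, and a scenario-contrast driver over synthetic forests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import clade_sampling, phylo_regression, rate_estimators, tree_io
from .clade_sampling import CladeRecord
from .synthetic_data import ScenarioConfig, simulate_clade_forest
from .tree_io import TimeTree, clade_tips, drop_tips, reduced_tree

logger = logging.getLogger("claderich")

RELATIONSHIPS = (
    "richness~age",
    "richness~rate",
    "rate~age",
    "richness~age+rate",
)


@dataclass
class RunConfig:
    """Design of a replicated clade-sampling analysis.

    Defaults follow the replicated random-sampling design: 50 clades per
    replicate, 10 replicates, crown ages, the crown method-of-moments
    estimator with epsilon = 0.5, PGLS, and exclusion of clades with rates
    above 1 species/Myr, clades in polytomies, and zero crown ages.
    """

    m_clades: int = 50
    n_replicates: int = 10
    epsilon: float = 0.5
    epsilon_list: tuple[float, ...] = (0.0, 0.5, 0.9)
    age_basis: str = "crown"
    engine: str = "pgls"
    max_rate: float = 1.0
    exclude_polytomy: bool = True
    exclude_zero_crown: bool = True
    polytomy_scope: str = "subtree"
    strata: dict[int, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.age_basis not in ("crown", "stem"):
            raise ValueError("age_basis must be 'crown' or 'stem'")
        if self.engine not in ("pgls", "ols"):
            raise ValueError("engine must be 'pgls' or 'ols'")
        if self.m_clades < 4 or self.n_replicates < 1:
            raise ValueError("need m_clades >= 4 and n_replicates >= 1")
        if not (0 <= self.epsilon < 1):
            raise ValueError("epsilon must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epsilon_list"] = list(self.epsilon_list)
        return d


@dataclass
class ReplicateSummary:
    """Across-replicate averages for one relationship."""

    relationship: str
    mean_r2: float
    mean_p: float
    pct_significant: float
    n_clades_total: int
    n_replicates: int
    mean_lambda: float | None = None


def _replicate_seed(seed: int, replicate: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(salt, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def _fit_models(
    records: list[CladeRecord],
    rtree: TimeTree | None,
    reps: list[str] | None,
    config: RunConfig,
) -> dict[str, phylo_regression.RegressionResult]:
    age = np.array(
        [r.crown_age if config.age_basis == "crown" else r.stem_age for r in records]
    )
    rate = np.array([r.rate for r in records], dtype=float)
    log_rich = np.log10([r.richness for r in records])

    def fit(x, y):
        if config.engine == "pgls":
            return phylo_regression.pgls_fit(x, y, reduced_tree=rtree, tip_order=reps)
        return phylo_regression.ols_fit(x, y)

    return {
        "richness~age": fit(age, log_rich),
        "richness~rate": fit(rate, log_rich),
        "rate~age": fit(age, rate),
        "richness~age+rate": fit(np.column_stack([age, rate]), log_rich),
    }


def run_single_replicate(
    tree: TimeTree,
    config: RunConfig,
    replicate: int = 0,
    candidates: list[int] | None = None,
):
    """One replicate: sample, resolve, measure, estimate, filter, regress.

    Returns (per-model results dict, retained records, exclusion log) or
    None when fewer than 4 clades survive filtering (PGLS needs degrees of
    freedom); the caller logs and skips such replicates.
    """
    seed = _replicate_seed(config.seed, replicate)
    if candidates is None:
        sampled = clade_sampling.sample_clades(
            tree, config.m_clades, seed=seed, strata=config.strata
        )
    else:
        rng = np.random.default_rng(seed)
        if config.m_clades > len(candidates):
            raise ValueError("m_clades exceeds the supplied candidate list")
        idx = rng.choice(len(candidates), size=config.m_clades, replace=False)
        sampled = [candidates[i] for i in sorted(idx)]

    retained_ids, nested_ids = clade_sampling.resolve_nesting(tree, sampled)
    records = clade_sampling.build_records(
        tree, retained_ids, polytomy_scope=config.polytomy_scope
    )
    nested_records = clade_sampling.build_records(
        tree, nested_ids, polytomy_scope=config.polytomy_scope
    )
    for rec in nested_records:
        rec.nested = True
    rate_estimators.fill_rates(
        records, age_basis=config.age_basis, epsilon=config.epsilon
    )
    retained, exclusion_log = clade_sampling.apply_filters(
        records,
        max_rate=config.max_rate,
        exclude_polytomy=config.exclude_polytomy,
        exclude_zero_crown=config.exclude_zero_crown,
    )
    exclusion_log = [(rec, "nested") for rec in nested_records] + exclusion_log
    if len(retained) < 4:
        return None
    if config.engine == "pgls":
        rtree, reps = reduced_tree(tree, [r.node_id for r in retained])
    else:
        rtree, reps = None, None
    results = _fit_models(retained, rtree, reps, config)
    return results, retained, exclusion_log


def run_replicates(
    tree: TimeTree,
    config: RunConfig,
    candidates: list[int] | None = None,
) -> tuple[pd.DataFrame, list[ReplicateSummary]]:
    """Replicated analysis; returns per-replicate table and summaries.

    The per-replicate frame has one row per (replicate, relationship) with
    r^2 (adjusted for the multiple regression), p (slope p for simple
    models, model-F p for the multiple model), Pagel's lambda and the
    retained clade count.  Summaries average over completed replicates.
    """
    config.validate()
    rows = []
    for k in range(config.n_replicates):
        out = run_single_replicate(tree, config, replicate=k, candidates=candidates)
        if out is None:
            logger.warning("replicate %d skipped: <4 clades after filtering", k)
            continue
        results, retained, _ = out
        for rel in RELATIONSHIPS:
            res = results[rel]
            multiple = "+" in rel
            rows.append(
                dict(
                    replicate=k,
                    relationship=rel,
                    r2=res.adjusted_r_squared if multiple else res.r_squared,
                    p=res.model_p_value if multiple else float(res.slope_p_values[0]),
                    lambda_pagel=res.lambda_pagel,
                    n_clades=len(retained),
                )
            )
        logger.info("replicate %d: %d clades retained", k, len(retained))
    per_rep = pd.DataFrame(rows)
    summaries = []
    for rel in RELATIONSHIPS:
        sub = per_rep[per_rep.relationship == rel] if len(per_rep) else per_rep
        if len(sub) == 0:
            raise RuntimeError("no replicate completed; tree too small for config")
        lam = sub.lambda_pagel.dropna()
        summaries.append(
            ReplicateSummary(
                relationship=rel,
                mean_r2=float(sub.r2.mean()),
                mean_p=float(sub.p.mean()),
                pct_significant=float((sub.p < 0.05).mean() * 100.0),
                n_clades_total=int(
                    sub.drop_duplicates("replicate").n_clades.sum()
                ),
                n_replicates=int(len(sub)),
                mean_lambda=float(lam.mean()) if len(lam) else None,
            )
        )
    return per_rep, summaries


def summary_frame(summaries: list[ReplicateSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def subsampling_experiment(
    tree: TimeTree,
    config: RunConfig,
    keep_fraction: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Re-run the replicated analysis on a randomly thinned tree.

    Tests robustness to incomplete taxon sampling: the full tree and a tree
    with ``keep_fraction`` of tips retained are analysed with the same
    machinery and independent seeds; returns the paired per-replicate
    frames and summaries.
    """
    config.validate()
    sub_seed = _replicate_seed(config.seed, 0, salt=7)
    reduced = drop_tips(tree, keep_fraction, seed=sub_seed)
    n_cand = len(clade_sampling.list_candidate_clades(reduced))
    if n_cand < config.m_clades:
        raise ValueError(
            f"reduced tree has only {n_cand} candidate clades; "
            f"lower m_clades (={config.m_clades})"
        )
    full_rep, full_sum = run_replicates(tree, config)
    red_config = RunConfig(**{**config.to_dict(), "seed": config.seed + 1,
                              "strata": config.strata,
                              "epsilon_list": config.epsilon_list})
    red_rep, red_sum = run_replicates(reduced, red_config)
    return {
        "full_replicates": full_rep,
        "full_summary": summary_frame(full_sum),
        "reduced_replicates": red_rep,
        "reduced_summary": summary_frame(red_sum),
    }


def described_richness_merge(
    tree: TimeTree,
    records: list[CladeRecord],
    richness_table: dict[str, float],
    taxonomy: pd.DataFrame,
    rank_columns: list[str] | None = None,
    epsilon: float = 0.5,
) -> list[CladeRecord]:
    """Replace in-tree tip counts with described species richness.

    ``taxonomy`` maps each tip label (column ``tip``) to its taxon path in
    ascending rank order (e.g. genus, family, order).  For a clade spanning
    two or more taxa at some rank, richness becomes the sum of described
    counts (``richness_table``) of the sampled taxa at the highest such
    rank; a clade confined to a single genus keeps its sampled tip count.
    Rates are recomputed from the adjusted richness.
    """
    if rank_columns is None:
        rank_columns = [c for c in taxonomy.columns if c != "tip"]
    tip_to_path = taxonomy.set_index("tip")[rank_columns]
    for rec in records:
        tips = clade_tips(tree, rec.node_id)
        missing = sorted(t for t in tips if t not in tip_to_path.index)
        if missing:
            raise KeyError(f"tips missing from taxonomy table: {missing}")
        paths = tip_to_path.loc[sorted(tips)]
        # highest rank at which the clade spans >= 2 sampled taxa
        chosen_rank = None
        for rank in reversed(rank_columns):
            if paths[rank].nunique() >= 2:
                chosen_rank = rank
                break
        if chosen_rank is None:  # single genus: keep sampled count
            continue
        taxa = sorted(paths[chosen_rank].unique())
        absent = [t for t in taxa if t not in richness_table]
        if absent:
            raise KeyError(
                f"taxa missing from described-richness table: {absent}"
            )
        rec.richness = int(sum(richness_table[t] for t in taxa))
    rate_estimators.fill_rates(records, age_basis="crown", epsilon=epsilon)
    return records


@dataclass
class PairedComparison:
    statistic: float
    df: int
    p_value: float
    mean_difference: float
    degenerate: bool = False


def compare_r2_sets(
    set_a: list[float], set_b: list[float], paired: bool = True
) -> PairedComparison:
    """Two-sided t-test on two sets of r^2 values.

    Paired by default (same replicates analysed two ways).  If the paired
    differences have zero variance the t statistic is undefined; p = 1 is
    returned with the ``degenerate`` flag set.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal-length sets")
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 values per set")
    if paired:
        d = a - b
        # sd of differences at rounding-noise level: t is undefined
        if float(np.std(d, ddof=1)) <= 1e-9 * max(1.0, float(np.abs(d).max())):
            return PairedComparison(
                statistic=math.nan, df=len(d) - 1, p_value=1.0,
                mean_difference=float(d.mean()), degenerate=True,
            )
        t, p = stats.ttest_rel(a, b)
        return PairedComparison(
            statistic=float(t), df=len(d) - 1, p_value=float(p),
            mean_difference=float(d.mean()),
        )
    t, p = stats.ttest_ind(a, b)
    return PairedComparison(
        statistic=float(t), df=len(a) + len(b) - 2, p_value=float(p),
        mean_difference=float(a.mean() - b.mean()),
    )


def scenario_contrast(
    preset: str,
    n_sets: int = 10,
    seed: int = 0,
    n_clades: int = 50,
    engine: str = "pgls",
) -> pd.DataFrame:
    """Fit the four models on the marked clades of ``n_sets`` fresh forests.

    Each set simulates an independent forest from the named preset and
    regresses over its marked clades (the truth-table entries), yielding
    one row per set with r^2 for richness~age and richness~rate.  Under
    ``age_driven`` the age model should win in most sets; under
    ``rate_driven`` the rate model should.
    """
    rows = []
    for k in range(n_sets):
        forest_seed = _replicate_seed(seed, k, salt=3)
        cfg = ScenarioConfig.from_preset(preset, seed=forest_seed, n_clades=n_clades)
        tree, truth = simulate_clade_forest(cfg)
        clade_ids = truth.node_id.tolist()
        records = clade_sampling.build_records(tree, clade_ids)
        rate_estimators.fill_rates(records, age_basis="crown", epsilon=0.5)
        run_cfg = RunConfig(engine=engine)
        if engine == "pgls":
            rtree, reps = reduced_tree(tree, clade_ids)
        else:
            rtree, reps = None, None
        results = _fit_models(records, rtree, reps, run_cfg)
        rows.append(
            dict(
                set=k,
                preset=preset,
                r2_richness_age=results["richness~age"].r_squared,
                r2_richness_rate=results["richness~rate"].r_squared,
                age_wins=results["richness~age"].r_squared
                > results["richness~rate"].r_squared,
            )
        )
    return pd.DataFrame(rows)


def rate_recovery_experiment(
    n_clades: int = 200,
    lambda_median: float = 0.2,
    lambda_sdlog: float = 0.0,
    age_range: tuple[float, float] = (5.0, 50.0),
    epsilon_true: float = 0.0,
    epsilon_assumed: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """True vs estimated net diversification on simulated birth-death clades.

    Simulates ``n_clades`` independent clades with speciation rates drawn
    from a lognormal (``lambda_sdlog = 0`` fixes the rate at the median)
    and crown ages uniform over ``age_range``, then estimates each clade's
    rate with the crown method-of-moments estimator.  Returns a frame with
    true_r, est_r, crown_age and n_tips per clade — the substrate for
    median-relative-error and true-vs-estimated-correlation checks.
    """
    from .synthetic_data import simulate_bd_tip_count

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xEC0,)))
    rows = []
    for i in range(n_clades):
        lam = lambda_median * float(np.exp(lambda_sdlog * rng.standard_normal()))
        mu = epsilon_true * lam
        age = float(rng.uniform(*age_range))
        n = simulate_bd_tip_count(lam, mu, age, seed=int(rng.integers(2**31)))
        rows.append(
            dict(
                true_r=lam - mu,
                est_r=rate_estimators.ms_crown_rate(n, age, epsilon_assumed),
                crown_age=age,
                n_tips=n,
            )
        )
    return pd.DataFrame(rows)


def records_frame(records: list[CladeRecord]) -> pd.DataFrame:
    """Clade records as a table (one row per clade, rate columns per epsilon)."""
    rows = []
    for r in records:
        row = dict(
            node_id=r.node_id,
            richness=r.richness,
            crown_age=r.crown_age,
            stem_age=r.stem_age,
            rate=r.rate,
            nested=r.nested,
            in_polytomy=r.in_polytomy,
            zero_crown=r.zero_crown,
            rate_excluded=r.rate_excluded,
        )
        for (basis, eps), val in r.rates.items():
            row[f"rate_{basis}_eps{eps:g}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
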