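"""Synthetic ultrametric clade forests with known diversification structure.

The generator builds a single rooted ultrametric tree carrying ``n_clades``
monophyletic birth-death clades hanging from a deep ladder backbone, each
with its own true speciation rate drawn from a lognormal distribution, plus
a per-clade truth table.  Two presets set up the contrast at the heart of
the clade-age vs diversification-rate debate:

* ``age_driven`` — near-identical rates across clades but widely varying
  stem ages, so richness differences are driven by time.
* ``rate_driven`` — narrow range of stem ages but strongly dispersed rates,
  so richness differences are driven by diversification rate.

Structural artifacts found in real supertrees (polytomies, zero-length
terminal branches, incomplete random taxon sampling) can be injected on
top, with total tree depth conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .tree_io import TimeTree, parse_newick, drop_tips

_MAX_REJECTIONS = 100_000


def _fmt(x) -> str:
    return repr(float(x))

PRESETS = {
    # shared rates, wide ages: richness tracks time
    "age_driven": dict(
        stem_age_range=(5.0, 100.0), lambda_median=0.05, lambda_sdlog=0.05
    ),
    # narrow ages, dispersed rates: richness tracks rate
    "rate_driven": dict(
        stem_age_range=(20.0, 30.0), lambda_median=0.06, lambda_sdlog=0.5
    ),
}


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic clade-forest generator.

    Rates are in species/Myr, ages in Myr.  ``lambda_median``/``lambda_sdlog``
    parameterize the lognormal from which clade speciation rates are drawn;
    ``epsilon_true`` is the generating relative extinction mu/lambda shared
    by all clades.  Crown ages are a uniform fraction of each clade's stem
    age (``crown_fraction_range``).
    """

    n_clades: int = 50
    stem_age_range: tuple[float, float] = (5.0, 100.0)
    lambda_median: float = 0.05
    lambda_sdlog: float = 0.05
    epsilon_true: float = 0.0
    scenario_preset: str | None = None
    polytomy_fraction: float = 0.0
    zero_branch_fraction: float = 0.0
    sampling_fraction: float = 1.0
    seed: int = 0
    crown_fraction_range: tuple[float, float] = (0.6, 0.95)
    backbone_interval: float = 10.0

    @classmethod
    def from_preset(cls, name: str, seed: int = 0, **overrides) -> "ScenarioConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        kwargs = dict(PRESETS[name])
        kwargs.update(overrides)
        return cls(scenario_preset=name, seed=seed, **kwargs)

    def validate(self) -> None:
        lo, hi = self.stem_age_range
        if not (0 < lo <= hi):
            raise ValueError("stem_age_range must be positive and ordered")
        if self.n_clades < 2:
            raise ValueError("n_clades must be >= 2")
        if not (0 <= self.epsilon_true < 1):
            raise ValueError("epsilon_true must be in [0, 1)")
        for name in ("polytomy_fraction", "zero_branch_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.lambda_median <= 0 or self.lambda_sdlog < 0:
            raise ValueError("lambda_median > 0 and lambda_sdlog >= 0 required")
        flo, fhi = self.crown_fraction_range
        if not (0 < flo <= fhi < 1):
            raise ValueError("crown_fraction_range must lie inside (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _grow_lineage(lam, mu, t0, horizon, rng, labeler):
    """Simulate one lineage forward from time t0 to the horizon.

    Returns (newick_core, node_time) for the pruned surviving subtree,
    with extinct lineages removed and unifurcations suppressed, or None
    if the lineage leaves no extant descendant.  ``node_time`` is the time
    of the returned node (horizon for tips, split time for internals).
    """
    total = lam + mu
    t1 = t0 + rng.exponential(1.0 / total) if total > 0 else math.inf
    if t1 >= horizon:
        return labeler(), horizon
    if rng.random() >= lam / total:  # extinction
        return None
    left = _grow_lineage(lam, mu, t1, horizon, rng, labeler)
    right = _grow_lineage(lam, mu, t1, horizon, rng, labeler)
    if left is None and right is None:
        return None
    if left is None or right is None:
        return left if right is None else right
    (lc, lt), (rc, rt) = left, right
    return f"({lc}:{_fmt(lt - t1)},{rc}:{_fmt(rt - t1)})", t1


def _bd_crown_newick(lam, mu, crown_age, rng, label_prefix="t"):
    """Newick core (no trailing ';') of a birth-death clade of depth
    ``crown_age``, conditioned on both crown lineages surviving."""
    if lam <= mu or mu < 0:
        raise ValueError("require speciation_rate > extinction_rate >= 0")
    if crown_age <= 0:
        raise ValueError("crown_age must be positive")
    for _ in range(_MAX_REJECTIONS):
        counter = [0]

        def labeler():
            counter[0] += 1
            return f"{label_prefix}{counter[0]}"

        a = _grow_lineage(lam, mu, 0.0, crown_age, rng, labeler)
        b = _grow_lineage(lam, mu, 0.0, crown_age, rng, labeler)
        if a is not None and b is not None:
            (ac, at), (bc, bt) = a, b
            return f"({ac}:{_fmt(at)},{bc}:{_fmt(bt)})"
    raise RuntimeError(
        f"birth-death simulation rejected {_MAX_REJECTIONS} times "
        f"(lambda={lam}, mu={mu}, t={crown_age}); these parameters make "
        "clade survival nearly impossible"
    )


def simulate_bd_clade(
    speciation_rate: float,
    extinction_rate: float,
    crown_age: float,
    seed: int,
) -> TimeTree:
    """Constant-rate birth-death clade started from two lineages at the crown.

    Forward-time simulation over ``crown_age`` Myr, conditioned (by
    rejection) on both crown lineages leaving extant descendants, so the
    returned tree is exactly ultrametric with depth ``crown_age``.
    """
    rng = np.random.default_rng(seed)
    core = _bd_crown_newick(speciation_rate, extinction_rate, crown_age, rng)
    return parse_newick(core + ";")


def simulate_bd_tip_count(
    speciation_rate: float,
    extinction_rate: float,
    crown_age: float,
    seed: int,
) -> int:
    """Extant tip count of a simulated birth-death clade.

    Same process and conditioning as :func:`simulate_bd_clade` (two crown
    lineages, both must survive) but tracks only lineage counts, so very
    large clades cost one Gillespie event per birth/death rather than a
    tree — used by parameter-recovery experiments where only richness
    matters.
    """
    lam, mu = speciation_rate, extinction_rate
    if lam <= mu or mu < 0:
        raise ValueError("require speciation_rate > extinction_rate >= 0")
    if crown_age <= 0:
        raise ValueError("crown_age must be positive")
    rng = np.random.default_rng(seed)
    p_birth = lam / (lam + mu)
    for _ in range(_MAX_REJECTIONS):
        counts = []
        for _side in range(2):
            k, t = 1, 0.0
            while k > 0:
                t += rng.exponential(1.0 / ((lam + mu) * k))
                if t >= crown_age:
                    break
                k += 1 if rng.random() < p_birth else -1
            if k == 0:
                break
            counts.append(k)
        if len(counts) == 2:
            return counts[0] + counts[1]
    raise RuntimeError(
        f"birth-death simulation rejected {_MAX_REJECTIONS} times "
        f"(lambda={lam}, mu={mu}, t={crown_age})"
    )


def _clade_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based seed split: clade simulations are order-independent
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_clade_forest(config: ScenarioConfig) -> tuple[TimeTree, pd.DataFrame]:
    """A single ultrametric tree of ``n_clades`` marked birth-death clades.

    Clades hang, each with a pendant sister tip realizing its stem age, from
    a ladder backbone whose joins sit at fixed intervals above the deepest
    stem age.  Returns the tree and a truth table with one row per clade:
    clade_id, node_id (crown node in the returned tree), true_lambda,
    true_mu, true_r, stem_age, crown_age, n_tips.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0xD1CE,)))
    n = config.n_clades
    lo, hi = config.stem_age_range
    stem_ages = rng.uniform(lo, hi, size=n)
    flo, fhi = config.crown_fraction_range
    crown_ages = stem_ages * rng.uniform(flo, fhi, size=n)
    lambdas = config.lambda_median * np.exp(
        config.lambda_sdlog * rng.standard_normal(n)
    )
    mus = config.epsilon_true * lambdas

    units: list[tuple[str, float]] = []  # (newick core, stem age)
    tip_sets: list[list[str]] = []
    for i in range(n):
        crng = _clade_rng(config.seed, i)
        core = _bd_crown_newick(
            lambdas[i], mus[i], crown_ages[i], crng, label_prefix=f"c{i}_s"
        )
        n_tips_i = core.count(f"c{i}_s")
        tip_sets.append([f"c{i}_s{j}" for j in range(1, n_tips_i + 1)])
        stem, crown = stem_ages[i], crown_ages[i]
        unit = f"({core}:{_fmt(stem - crown)},out{i}:{_fmt(stem)})"
        units.append((unit, stem))

    max_stem = float(stem_ages.max())
    dt = config.backbone_interval
    cur_core, cur_depth = units[0]
    for k in range(1, n):
        join_depth = max_stem + k * dt
        uk_core, uk_depth = units[k]
        if uk_depth >= join_depth:
            raise ValueError("stem age exceeds backbone join depth")
        cur_core = (
            f"({cur_core}:{_fmt(join_depth - cur_depth)},"
            f"{uk_core}:{_fmt(join_depth - uk_depth)})"
        )
        cur_depth = join_depth

    tree = parse_newick(cur_core + ";")
    rows = []
    for i in range(n):
        node_id = tree.mrca_id(tip_sets[i])
        rows.append(
            dict(
                clade_id=i,
                node_id=node_id,
                true_lambda=lambdas[i],
                true_mu=mus[i],
                true_r=lambdas[i] - mus[i],
                stem_age=stem_ages[i],
                crown_age=crown_ages[i],
                n_tips=len(tip_sets[i]),
            )
        )
    return tree, pd.DataFrame(rows)


def inject_artifacts(
    tree: TimeTree, config: ScenarioConfig
) -> tuple[TimeTree, dict]:
    """Inject polytomies, zero-length cherry branches and incomplete sampling.

    * ``polytomy_fraction`` of collapsible internal nodes (non-root,
      internal parent edge) are merged into their parent, child edges
      extended so node depths are conserved.
    * ``zero_branch_fraction`` of cherries have their pendant tip edges set
      to 0, the removed length donated to the cherry's stem edge, so total
      depth is conserved and the cherry's crown age becomes 0.
    * ``sampling_fraction`` < 1 prunes tips uniformly at random.

    Returns the modified tree and a log: ``polytomy_tip_sets`` /
    ``zero_cherry_tip_sets`` list the tip-label sets below each altered
    node (node ids are reassigned in the new tree).
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xA27,))
    )
    dtree = tree._dtree.clone(depth=1)
    log: dict = {"polytomy_tip_sets": [], "zero_cherry_tip_sets": []}

    if config.polytomy_fraction > 0:
        eligible = [
            nd
            for nd in dtree.postorder_node_iter()
            if not nd.is_leaf()
            and nd.parent_node is not None
        ]
        k = int(round(config.polytomy_fraction * len(eligible)))
        if k > 0:
            idx = sorted(rng.choice(len(eligible), size=k, replace=False))
            for i in idx:
                nd = eligible[i]
                log["polytomy_tip_sets"].append(
                    frozenset(lf.taxon.label for lf in nd.leaf_iter())
                )
            # collapse children-first so nested selections behave
            for i in idx:
                nd = eligible[i]
                parent = nd.parent_node
                elen = nd.edge.length or 0.0
                for ch in list(nd.child_nodes()):
                    ch.edge.length = (ch.edge.length or 0.0) + elen
                    parent.add_child(ch)
                parent.remove_child(nd)

    if config.zero_branch_fraction > 0:
        cherries = [
            nd
            for nd in dtree.postorder_node_iter()
            if not nd.is_leaf()
            and nd.parent_node is not None
            and all(ch.is_leaf() for ch in nd.child_nodes())
        ]
        k = int(round(config.zero_branch_fraction * len(cherries)))
        if k > 0:
            idx = sorted(rng.choice(len(cherries), size=k, replace=False))
            for i in idx:
                nd = cherries[i]
                donate = max((ch.edge.length or 0.0) for ch in nd.child_nodes())
                for ch in nd.child_nodes():
                    ch.edge.length = 0.0
                if nd.edge is not None and nd.parent_node is not None:
                    nd.edge.length = (nd.edge.length or 0.0) + donate
                log["zero_cherry_tip_sets"].append(
                    frozenset(ch.taxon.label for ch in nd.child_nodes())
                )

    out = TimeTree(dtree)
    if config.sampling_fraction < 1:
        sub_seed = int(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(0x5A3,))
            .generate_state(1)[0] % (2**31)
        )
        out = drop_tips(out, config.sampling_fraction, seed=sub_seed)
    return out, log
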