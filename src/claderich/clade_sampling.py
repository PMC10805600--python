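"""Random clade sampling, nesting resolution and exclusion filters.

A candidate clade is any internal node with at least two descendant tips,
excluding the root (sampling the whole tree is degenerate, and a
single-species clade has no crown age).  Sampling is uniform without
replacement, optionally stratified by subtree so that, e.g., every
across-life replicate contains a fixed number of clades from each domain.
When one sampled clade is nested inside another, the younger one is
excluded, transitively, until no nesting remains — nested clades would
trivially favour the clade-age hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree_io import TimeTree, clade_tips, detect_artifacts, node_ages


@dataclass
class CladeRecord:
    """One sampled clade's measurements and exclusion flags."""

    node_id: int
    crown_age: float
    stem_age: float
    richness: int
    rate: float | None = None
    rates: dict = field(default_factory=dict)
    nested: bool = False
    in_polytomy: bool = False
    zero_crown: bool = False
    rate_excluded: bool = False


def list_candidate_clades(tree: TimeTree) -> list[int]:
    """All internal, non-root nodes with >= 2 descendant tips, in
    deterministic (node-id) order."""
    root = tree.root_id
    counts: dict[int, int] = {}
    out = []
    for nd in tree._dtree.postorder_node_iter():
        if nd.is_leaf():
            counts[nd.cr_id] = 1
        else:
            counts[nd.cr_id] = sum(counts[ch.cr_id] for ch in nd.child_nodes())
            if nd.cr_id != root and counts[nd.cr_id] >= 2:
                out.append(nd.cr_id)
    return sorted(out)


def sample_clades(
    tree: TimeTree,
    m: int,
    seed: int,
    strata: dict[int, int] | None = None,
) -> list[int]:
    """Sample ``m`` candidate clades uniformly without replacement.

    ``strata`` maps a subtree root node id to the number of clades to draw
    from inside that subtree; counts must sum to ``m``.  With no strata the
    whole tree is a single stratum.
    """
    rng = np.random.default_rng(seed)
    candidates = list_candidate_clades(tree)
    if strata is None:
        if m > len(candidates):
            raise ValueError(
                f"requested {m} clades but only {len(candidates)} candidates"
            )
        idx = rng.choice(len(candidates), size=m, replace=False)
        return [candidates[i] for i in sorted(idx)]
    if sum(strata.values()) != m:
        raise ValueError("strata counts must sum to m")
    chosen: list[int] = []
    for stratum_root, count in strata.items():
        tree.node(stratum_root)  # existence check
        pool = [
            nid for nid in candidates
            if nid == stratum_root or tree.is_ancestor(stratum_root, nid)
        ]
        pool = [nid for nid in pool if nid != tree.root_id]
        if count > len(pool):
            raise ValueError(
                f"stratum {stratum_root} has {len(pool)} candidates, "
                f"cannot draw {count}"
            )
        idx = rng.choice(len(pool), size=count, replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return chosen


def resolve_nesting(
    tree: TimeTree, clade_ids: list[int]
) -> tuple[list[int], list[int]]:
    """Exclude the younger clade of every nested pair, transitively.

    Returns (retained ids, excluded ids).  Age = crown age; ties are broken
    by excluding the larger node id, for determinism.
    """
    depths = tree.node_depths()
    retained = list(dict.fromkeys(clade_ids))
    excluded: list[int] = []
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                if tree.is_ancestor(a, b) or tree.is_ancestor(b, a):
                    ca, cb = depths[a], depths[b]
                    if ca < cb:
                        drop = a
                    elif cb < ca:
                        drop = b
                    else:
                        drop = max(a, b)
                    retained.remove(drop)
                    excluded.append(drop)
                    changed = True
                    break
            if changed:
                break
    return retained, excluded


def build_records(
    tree: TimeTree,
    clade_ids: list[int],
    polytomy_scope: str = "subtree",
) -> list[CladeRecord]:
    """Measure age, richness and artifact flags for each clade."""
    ages = node_ages(tree)
    flags = detect_artifacts(tree, polytomy_scope=polytomy_scope)
    records = []
    for nid in clade_ids:
        crown = ages.crown_age(nid)
        stem = ages.stem_age(nid)
        rec = CladeRecord(
            node_id=nid,
            crown_age=crown,
            stem_age=stem,
            richness=len(clade_tips(tree, nid)),
            in_polytomy=flags[nid].in_polytomy,
            zero_crown=crown <= 0.0,
        )
        records.append(rec)
    return records


def apply_filters(
    records: list[CladeRecord],
    max_rate: float = 1.0,
    exclude_polytomy: bool = True,
    exclude_zero_crown: bool = True,
) -> tuple[list[CladeRecord], list[tuple[CladeRecord, str]]]:
    """Exclusion filters applied after rate estimation.

    Retained records have rate <= ``max_rate`` (species/Myr), are not in
    polytomies, and have positive crown age.  The exclusion log records one
    reason per dropped clade, first matching in the order
    zero_crown -> polytomy -> rate.  Excluded clades are not replaced, so
    replicate sizes vary.
    """
    retained: list[CladeRecord] = []
    log: list[tuple[CladeRecord, str]] = []
    for rec in records:
        if exclude_zero_crown and (rec.zero_crown or rec.rate is None):
            log.append((rec, "zero_crown"))
            continue
        if exclude_polytomy and rec.in_polytomy:
            log.append((rec, "polytomy"))
            continue
        if rec.rate is not None and rec.rate > max_rate:
            rec.rate_excluded = True
            log.append((rec, "rate"))
            continue
        retained.append(rec)
    return retained, log
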