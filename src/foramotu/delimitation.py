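"""Distance-based and tree-based MOTU delimitation.

The two automated delimitation routes used for the genotype/lineage
levels of the molecular nomenclature:

* a barcode-gap method in the spirit of Automated Barcode Gap Discovery
  (ABGD): scan a ladder of prior intraspecific divergences, locate a
  significant discontinuity in the ranked pairwise K80 distances, link
  pairs below the gap into groups, and re-apply recursively within
  groups — giving a coarsest (initial) and a finest (recursive)
  partition at the lowest prior that exhibits a gap;
* a simplified Poisson Tree Process (PTP): branch lengths of a rooted
  tree are modelled as two exponential classes (speciation vs
  within-species) and species subtree roots are sought greedily under
  AIC.  The greedy heuristic is a reimplementation; an import path for
  external PTP output preserves fidelity to the published tool.

Level-1 (lineage) is the coarsest validated partition, level-2
(genotype) the finest, level-3 the basegroups from curation; a partition
is discarded when it splits a basegroup (oversplit) or merges different
morphospecies (lumping).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "AbgdConfig",
    "PtpConfig",
    "Partition",
    "MOTUHierarchy",
    "k80_distance",
    "abgd_partition",
    "ptp_partition",
    "ptp_exhaustive",
    "import_partition",
    "build_hierarchy",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # K80 distances, substitutions/site; +inf when saturated
    P: np.ndarray  # transition proportions
    Q: np.ndarray  # transversion proportions
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)


@dataclass(frozen=True)
class AbgdConfig:
    Pmin: float = 0.001
    Pmax: float = 0.1
    n_steps: int = 10
    X: float = 1.5  # relative gap width
    min_group_size: int = 3  # smallest group re-examined recursively

    def validate(self) -> None:
        if not 0.0 < self.Pmin < self.Pmax < 1.0:
            raise ValueError("require 0 < Pmin < Pmax < 1")
        if self.X <= 0:
            raise ValueError("X must be > 0")


@dataclass(frozen=True)
class PtpConfig:
    criterion: str = "aic"  # {aic, loglik_gain}
    loglik_gain_threshold: float = 2.0


@dataclass
class Partition:
    method: str  # {abgd_initial, abgd_recursive, ptp, imported}
    parameters: dict
    groups: dict[str, str]  # basetype_id -> group label

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))


@dataclass
class MOTUHierarchy:
    """Per-basetype lineage (lvl-1), genotype (lvl-2) and basegroup
    (lvl-3) labels plus the partition-validation report."""

    assignments: pd.DataFrame  # index basetype_id; columns lvl1 lvl2 lvl3
    validation: dict


# ---------------------------------------------------------------------------
# K80 distances


def k80_pair(a: str, b: str) -> tuple[float, float, float]:
    """K80 distance for one aligned pair with complete deletion of
    columns holding gaps or ambiguity codes.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q); saturated pairs (either
    log argument <= 0) get d = +inf.
    """
    if len(a) != len(b):
        raise ValueError("aligned motifs have unequal length")
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable columns after complete deletion")
    P, Q = ts / n, tv / n
    a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        return math.inf, P, Q
    return -0.5 * math.log(a1) - 0.25 * math.log(a2), P, Q


def k80_distance(alignment: dict[str, str]) -> DistanceMatrix:
    """Pairwise K80 distance matrix over aligned basetype motifs."""
    taxa = sorted(alignment)
    n = len(taxa)
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            dij, pij, qij = k80_pair(alignment[taxa[i]], alignment[taxa[j]])
            d[i, j] = d[j, i] = dij
            P[i, j] = P[j, i] = pij
            Q[i, j] = Q[j, i] = qij
            if math.isinf(dij):
                saturated.append((taxa[i], taxa[j]))
                logger.warning("k80: saturated pair %s-%s", taxa[i], taxa[j])
    return DistanceMatrix(taxa=taxa, d=d, P=P, Q=Q, saturated=saturated)


# ---------------------------------------------------------------------------
# barcode-gap partitioning


def _significant_gaps(dist_values: np.ndarray, prior: float,
                      X: float) -> list[tuple[float, float]]:
    """Significant discontinuities in the ranked distances above a prior.

    Returns (threshold, width) per significant gap.  A gap between
    consecutive sorted distances d_i < d_{i+1} counts as a barcode gap
    when its width exceeds X times the local distance scale
    max(d_i, prior): the discontinuity must dominate both the cluster it
    rises from and the assumed intraspecific divergence.  Gaps entirely
    below the prior are never candidates.
    """
    ds = np.sort(dist_values[np.isfinite(dist_values)])
    if ds.size < 2:
        return []
    gaps = np.diff(ds)
    out = []
    for i, g in enumerate(gaps):
        if g <= 0 or ds[i + 1] <= prior:
            continue
        if g > X * max(ds[i], prior):
            out.append((float(ds[i]), float(g)))
    return out


def _link_below(dm: DistanceMatrix, subset: list[str],
                threshold: float) -> list[list[str]]:
    """Single-linkage components joining pairs with d <= threshold."""
    idx = {t: i for i, t in enumerate(dm.taxa)}
    parent = {t: t for t in subset}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(subset):
        for b in subset[i + 1:]:
            if dm.d[idx[a], idx[b]] <= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    comps: dict[str, list[str]] = {}
    for t in subset:
        comps.setdefault(find(t), []).append(t)
    return sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])


def _pair_values(dm: DistanceMatrix, subset: list[str]) -> np.ndarray:
    idx = [dm.taxa.index(t) for t in subset]
    sub = dm.d[np.ix_(idx, idx)]
    return sub[np.triu_indices(len(idx), k=1)]


def _widest_gap(dm, subset, prior, cfg) -> float | None:
    gaps = _significant_gaps(_pair_values(dm, subset), prior, cfg.X)
    if not gaps:
        return None
    # dominant barcode gap: maximal width; ties resolved toward the
    # higher threshold (fewer groups)
    return max(gaps, key=lambda tw: (tw[1], tw[0]))[0]


def _recursive_split(dm, subset, prior, cfg) -> list[list[str]]:
    if len(subset) < cfg.min_group_size:
        return [sorted(subset)]
    thr = _widest_gap(dm, subset, prior, cfg)
    if thr is None:
        return [sorted(subset)]
    groups = _link_below(dm, subset, thr)
    if len(groups) == 1:
        return groups
    out = []
    for g in groups:
        out.extend(_recursive_split(dm, g, prior, cfg))
    return out


def _as_partition(method, parameters, groups) -> Partition:
    mapping = {}
    for gi, g in enumerate(groups):
        for t in g:
            mapping[t] = f"{method}_{gi + 1:02d}"
    return Partition(method=method, parameters=parameters, groups=mapping)


def abgd_partition(dm: DistanceMatrix, config: AbgdConfig | None = None):
    """Barcode-gap partitions across a ladder of priors.

    Returns ``(all_partitions, initial, recursive)``: per prior an
    (initial, recursive) pair, plus the retained pair at the lowest
    prior exhibiting a significant gap.  When no prior yields a gap the
    single-group partition is returned with a warning.
    """
    config = config or AbgdConfig()
    config.validate()
    if len(dm.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    priors = np.logspace(
        math.log10(config.Pmin), math.log10(config.Pmax), config.n_steps
    )
    ladder = []
    retained = None
    for prior in priors:
        thr = _widest_gap(dm, dm.taxa, float(prior), config)
        if thr is None:
            initial_groups = [sorted(dm.taxa)]
            recursive_groups = [sorted(dm.taxa)]
        else:
            initial_groups = _link_below(dm, dm.taxa, thr)
            recursive_groups = []
            for g in initial_groups:
                recursive_groups.extend(
                    _recursive_split(dm, g, float(prior), config)
                )
        pi = _as_partition("abgd_initial", {"prior": float(prior)},
                           initial_groups)
        pr = _as_partition("abgd_recursive", {"prior": float(prior)},
                           recursive_groups)
        ladder.append((float(prior), pi, pr))
        if retained is None and thr is not None:
            retained = (pi, pr)
    if retained is None:
        logger.warning("abgd: no barcode gap at any prior; single group")
        retained = (ladder[0][1], ladder[0][2])
    return ladder, retained[0], retained[1]


# ---------------------------------------------------------------------------
# simplified Poisson Tree Process


def _edges_below(node) -> list[float]:
    out = []
    for nd in node.preorder_iter():
        if nd is node:
            continue
        if nd.edge.length and nd.edge.length > 0:
            out.append(nd.edge.length)
    return out


def _delimitation_score(tree, roots, config: PtpConfig) -> float:
    """AIC of the two-class exponential branch-length model for the
    delimitation whose species subtrees are rooted at ``roots``."""
    within = []
    for r in roots:
        within.extend(_edges_below(r))
    all_edges = _edges_below(tree.seed_node)
    total, n_tot = sum(all_edges), len(all_edges)
    w, n_w = sum(within), len(within)
    s, n_s = total - w, n_tot - n_w

    def class_ll(n, tot):
        if n == 0:
            return 0.0
        if tot <= 0:
            return -math.inf  # zero-length class cannot carry a rate
        lam = n / tot
        return n * math.log(lam) - n
    ll = class_ll(n_w, w) + class_ll(n_s, s)
    k = 2 if (n_w and n_s) else 1
    return 2 * k - 2 * ll


def _species_partition(tree, roots) -> list[list[str]]:
    return sorted(
        (sorted(lf.taxon.label for lf in r.leaf_iter()) for r in roots),
        key=lambda g: g[0],
    )


def _hill_climb(tree, roots, config, order):
    """Best-improvement split/merge hill climb from a starting
    delimitation; deterministic through preorder tie-breaking."""
    roots = set(roots)
    score = _delimitation_score(tree, roots, config)
    improved = True
    while improved:
        improved = False
        best = None
        for r in sorted(roots, key=order.get):
            kids = r.child_nodes()
            if kids:  # split move
                cand = (roots - {r}) | set(kids)
                s = _delimitation_score(tree, cand, config)
                if best is None or s < best[0] - 1e-12:
                    best = (s, cand)
        # merge moves: a node all of whose children are current roots
        parents = {r.parent_node for r in roots if r.parent_node}
        for p in sorted(parents, key=order.get):
            kids = set(p.child_nodes())
            if kids <= roots:
                cand = (roots - kids) | {p}
                s = _delimitation_score(tree, cand, config)
                if best is None or s < best[0] - 1e-12:
                    best = (s, cand)
        if best is not None and best[0] < score - 1e-9:
            score, roots = best[0], best[1]
            improved = True
    return score, roots


def _threshold_roots(tree, threshold):
    """Maximal subtrees whose internal edges are all <= threshold; their
    roots delimit species under a rate cut at ``threshold``."""
    coherent = {}
    for nd in tree.postorder_node_iter():
        kids = nd.child_nodes()
        coherent[nd] = all(
            coherent[k] and (k.edge.length or 0.0) <= threshold
            for k in kids
        )
    roots = []
    for nd in tree.preorder_node_iter():
        par = nd.parent_node
        if coherent[nd] and (par is None or not coherent[par]):
            roots.append(nd)
    return set(roots)


def ptp_partition(tree: dendropy.Tree,
                  config: PtpConfig | None = None) -> Partition:
    """Greedy simplified-PTP delimitation on a rooted tree.

    Hill-climbs with split moves (replace a species root by its
    children) and merge moves (replace a sibling set of species roots by
    their parent) under AIC, from several deterministic starting points:
    the single-species delimitation, the all-singletons delimitation and
    every branch-length-threshold delimitation.  The best local optimum
    is returned; ties break toward fewer species and preorder order.
    """
    config = config or PtpConfig()
    edges = _edges_below(tree.seed_node)
    if not edges:
        groups = [sorted(lf.taxon.label for lf in tree.leaf_node_iter())]
        return _as_partition("ptp", {"note": "zero-length tree"}, groups)

    order = {nd: i for i, nd in enumerate(tree.preorder_node_iter())}
    starts = [
        {tree.seed_node},
        set(tree.leaf_node_iter()),
    ]
    for thr in sorted(set(edges)):
        starts.append(_threshold_roots(tree, thr))
    best = None
    for start in starts:
        score, roots = _hill_climb(tree, start, config, order)
        key = (score, len(roots), tuple(sorted(order[r] for r in roots)))
        if best is None or key < best[0]:
            best = (key, roots)
    score = best[0][0]
    groups = _species_partition(tree, best[1])
    return _as_partition("ptp", {"aic": score}, groups)


def _antichain_covers(node):
    """All species-root sets covering the subtree of ``node``."""
    own = [[node]]
    kids = node.child_nodes()
    if not kids:
        return own
    per_child = [_antichain_covers(c) for c in kids]
    combos = [[]]
    for options in per_child:
        combos = [acc + opt for acc in combos for opt in options]
    return own + combos


def ptp_exhaustive(tree: dendropy.Tree,
                   config: PtpConfig | None = None) -> Partition:
    """Exact optimum over every possible delimitation (small trees).

    Enumerates all antichain covers of the tree; intended as the oracle
    for the greedy search on trees with few tips.
    """
    config = config or PtpConfig()
    edges = _edges_below(tree.seed_node)
    if not edges:
        groups = [sorted(lf.taxon.label for lf in tree.leaf_node_iter())]
        return _as_partition("ptp", {"note": "zero-length tree"}, groups)
    best = None
    for roots in _antichain_covers(tree.seed_node):
        s = _delimitation_score(tree, set(roots), config)
        key = (s, len(roots))
        if best is None or key < best[0]:
            best = (key, set(roots))
    return _as_partition(
        "ptp", {"aic": best[0][0]}, _species_partition(tree, best[1])
    )


def import_partition(frame: pd.DataFrame, method: str = "imported") -> Partition:
    """Pass an externally computed partition through unchanged.

    Expects columns ``basetype_id`` and ``group``.
    """
    groups = dict(zip(frame["basetype_id"].astype(str),
                      frame["group"].astype(str)))
    return Partition(method=method, parameters={}, groups=groups)


# ---------------------------------------------------------------------------
# hierarchy assembly and validation


def _roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, sym in vals:
        while n >= v:
            out.append(sym)
            n -= v
    return "".join(out)


def _letters(n: int) -> str:
    out = ""
    while n > 0:
        n, r = divmod(n - 1, 26)
        out = chr(ord("a") + r) + out
    return out


def _validate_partition(partition: Partition, basegroup_of: dict[str, str],
                        morpho_of: dict[str, str]) -> list[dict]:
    violations = []
    by_bg: dict[str, set[str]] = {}
    for bt, grp in partition.groups.items():
        by_bg.setdefault(basegroup_of[bt], set()).add(grp)
    for bg, grps in sorted(by_bg.items()):
        if len(grps) > 1:
            violations.append(
                {"type": "oversplit", "basegroup": bg,
                 "partitions": sorted(grps)}
            )
    by_grp: dict[str, set[str]] = {}
    for bt, grp in partition.groups.items():
        by_grp.setdefault(grp, set()).add(morpho_of[bt])
    for grp, morphos in sorted(by_grp.items()):
        if len(morphos) > 1:
            violations.append(
                {"type": "lumping", "partition": grp,
                 "morphospecies": sorted(morphos)}
            )
    return violations


def _nests_within(fine: dict[str, str], coarse: dict[str, str]) -> bool:
    parent: dict[str, str] = {}
    for bt, g in fine.items():
        if g in parent and parent[g] != coarse[bt]:
            return False
        parent[g] = coarse[bt]
    return True


def build_hierarchy(
    partitions: list[Partition],
    basegroups,
    morphospecies: dict[str, str],
    tree_order: list[str] | None = None,
) -> MOTUHierarchy:
    """Assemble the validated three-tier MOTU hierarchy.

    ``partitions`` are candidate delimitations over the basetypes;
    partitions that split a basegroup (oversplit) or merge different
    morphospecies (lumping) are discarded.  Among the valid ones the
    coarsest becomes level-1 (lineages, roman numerals) and the finest
    level-2 (genotypes, letters); level-3 are the basegroups (digits).
    Labels are assigned in ``tree_order`` of the first member basetype
    (lexicographic when no order is given).
    """
    basegroup_of = {}
    for bg in basegroups:
        for bt in bg.basetypes:
            basegroup_of[bt] = bg.basegroup_id
    taxa = sorted(basegroup_of)
    report = {"discarded": [], "retained": []}
    valid = []
    for p in partitions:
        if set(p.groups) != set(taxa):
            raise ValueError(
                f"partition {p.method} does not cover all basetypes"
            )
        violations = _validate_partition(p, basegroup_of, morphospecies)
        if violations:
            report["discarded"].append(
                {"method": p.method, "parameters": p.parameters,
                 "violations": violations}
            )
        else:
            valid.append(p)
            report["retained"].append(
                {"method": p.method, "parameters": p.parameters,
                 "n_groups": p.n_groups}
            )
    if not valid:
        raise ValueError(
            f"all candidate partitions invalid: {report['discarded']}"
        )
    coarse = min(valid, key=lambda p: (p.n_groups, p.method))
    fine = max(valid, key=lambda p: (p.n_groups, p.method))
    if not _nests_within(fine.groups, coarse.groups):
        raise ValueError(
            "finest valid partition does not nest within the coarsest"
        )
    if not _nests_within({bt: basegroup_of[bt] for bt in taxa}, fine.groups):
        raise ValueError("basegroups do not nest within the finest partition")

    pos = {bt: (tree_order.index(bt) if tree_order else i)
           for i, bt in enumerate(taxa)}

    def ordered_groups(mapping):
        groups: dict[str, list[str]] = {}
        for bt in taxa:
            groups.setdefault(mapping[bt], []).append(bt)
        return sorted(groups.values(), key=lambda g: min(pos[bt] for bt in g))

    lvl1_label, lvl2_label, lvl3_label = {}, {}, {}
    for i, lineage in enumerate(ordered_groups(coarse.groups)):
        l1 = _roman(i + 1)
        for bt in lineage:
            lvl1_label[bt] = l1
        genotypes = [g for g in ordered_groups(fine.groups)
                     if g[0] in lineage]
        for j, genotype in enumerate(genotypes):
            l2 = f"{l1}{_letters(j + 1)}"
            for bt in genotype:
                lvl2_label[bt] = l2
            bgs = sorted(
                {basegroup_of[bt] for bt in genotype},
                key=lambda b: min(pos[bt] for bt in taxa
                                  if basegroup_of[bt] == b),
            )
            for k, bg in enumerate(bgs):
                l3 = f"{l2}{k + 1}"
                for bt in genotype:
                    if basegroup_of[bt] == bg:
                        lvl3_label[bt] = l3
    frame = pd.DataFrame(
        {
            "basetype_id": taxa,
            "lvl1": [lvl1_label[t] for t in taxa],
            "lvl2": [lvl2_label[t] for t in taxa],
            "lvl3": [lvl3_label[t] for t in taxa],
            "basegroup_id": [basegroup_of[t] for t in taxa],
            "morphospecies": [morphospecies[t] for t in taxa],
        }
    ).set_index("basetype_id")
    return MOTUHierarchy(assignments=frame, validation=report)
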