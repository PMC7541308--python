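"""Average-linkage clustering and the dynamic hybrid tree cut.

The hybrid cut walks the dendrogram bottom-up, maintaining branches as the
merges accumulate.  When two branches meet, each is tested against three
criteria — minimum size, core scatter (how tight the branch's early-joining
core is) and gap (how far below the joining height the branch's core closed)
— and branches passing all three are frozen as clusters.  ``deep_split``
(0-4) tunes the scatter/gap thresholds from conservative to aggressive
splitting via the published constant mapping.  Objects left over after the
walk are optionally assigned to the nearest cluster in a PAM-like stage,
provided their average dissimilarity to the cluster is within the cluster's
own assignment radius.  Label 0 means unassigned.

Numerical note: with a high soft-threshold power the 1 - TOM dissimilarities
compress against 1 and merge heights become nearly indistinguishable on the
raw scale.  The cut criteria are therefore evaluated on the monotone
transform ``-log(1 - h)``, which decompresses the near-1 region without
changing the tree; when heights exceed 1 (a generic dissimilarity), the raw
scale is used as-is.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger("protnet")

# deep_split -> maximum normalized core scatter; min gap = 0.75 * (1 - scatter)
_MAX_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}

# membership floor, as a fraction of the weakest core member's within-cluster
# connectivity, used both when trimming finalized branches and when the PAM
# stage decides whether an unassigned object may join a cluster
_CONNECTIVITY_FLOOR = 1.0 / 3.0


def cluster_tree(dissimilarity: np.ndarray) -> np.ndarray:
    """Average-linkage dendrogram (scipy linkage matrix) from a square dissimilarity.

    scipy's nearest-neighbor chain agglomeration is deterministic; equal
    heights are merged lowest-index-first, so runs are reproducible.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if np.isnan(D).any():
        raise ValueError("dissimilarity contains NaN")
    if D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    condensed = squareform(D, checks=False)
    return linkage(condensed, method="average")


class _Branch:
    """Mutable node state during the bottom-up walk.

    ``members``/``attach`` describe the node's *live* branch — the part still
    accreting objects.  ``frozen`` holds clusters already finalized inside
    the subtree; once a branch is frozen its members are settled and later
    merges cannot rearrange them.
    """

    __slots__ = ("members", "attach", "frozen")

    def __init__(self, members, attach):
        self.members: list[int] = members          # live leaf indices
        self.attach: list[float] = attach          # (transformed) joining heights
        self.frozen: list[list[int]] = []          # finalized clusters in subtree


def _core_stats(members: list[int], attach: list[float], core_size: int) -> tuple[float, float]:
    """(mean, max) joining height of the branch core (earliest joiners)."""
    heights = np.sort(np.asarray(attach))
    core = heights[: max(2, min(core_size, heights.size))]
    return float(core.mean()), float(core.max())


def _qualifies(branch: _Branch, merge_height: float, min_size: int,
               max_scatter: float, min_gap: float) -> bool:
    if len(branch.members) < min_size:
        return False
    scatter, core_top = _core_stats(branch.members, branch.attach, min_size)
    if scatter > max_scatter:
        return False
    return (merge_height - core_top) >= min_gap


def dynamic_hybrid_cut(
    Z: np.ndarray,
    dissimilarity: np.ndarray,
    deep_split: int = 4,
    min_module_size: int = 25,
    pam_stage: bool = True,
    cut_height: float | None = None,
) -> np.ndarray:
    """Adaptive dendrogram cut; returns integer labels with 0 = unassigned.

    ``cut_height`` (on the raw dissimilarity scale) defaults to 99% of the
    dendrogram height range; merges above it never fuse clusters.  Cluster
    ids are ordered by decreasing size (1 = largest).
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if min_module_size > n:
        warnings.warn("min_module_size exceeds the number of objects; all unassigned")
        return np.zeros(n, dtype=int)
    heights = Z[:, 2]
    h_max = float(heights.max())

    if h_max <= 1.0 + 1e-9:
        def g(h):
            return -np.log1p(-np.minimum(h, 1.0 - 1e-12))
    else:
        def g(h):
            return np.asarray(h, dtype=float)

    gh = g(heights)
    if cut_height is None:
        cut_g = float(gh.min() + 0.99 * (gh.max() - gh.min()))
    else:
        cut_g = float(g(cut_height))
    # Scatter/gap thresholds are normalized between the lowest merges (5th
    # percentile) and a ceiling taken as the larger of the median merge
    # height and the 99%-range cut on the raw dissimilarity scale.  When the
    # tree is mostly noise merges (which concentrate in its upper half) the
    # median keeps credible cores well below them; when genuine clusters
    # dominate the tree the raw-scale cut keeps the ceiling above their
    # internal structure.
    h_min = float(heights.min())
    raw_cut = h_min + 0.99 * (h_max - h_min)
    lo = float(np.quantile(gh, 0.05))
    hi = max(float(np.quantile(gh, 0.50)), float(g(raw_cut)))
    span = max(hi - lo, np.finfo(float).tiny)
    mcs = _MAX_CORE_SCATTER[int(deep_split)]
    max_abs_scatter = lo + mcs * span
    min_abs_gap = 0.75 * (1.0 - mcs) * span

    S = 1.0 - D if h_max <= 1.0 + 1e-9 else np.exp(-D)
    np.fill_diagonal(S, 0.0)
    proto_min = max(3, min_module_size // 2)

    def is_proto(branch: _Branch) -> bool:
        """A tight-core sibling that deserves to keep growing on its own."""
        if len(branch.members) < proto_min:
            return False
        scatter, _ = _core_stats(branch.members, branch.attach, min_module_size)
        return scatter <= max_abs_scatter

    def trim(branch: _Branch) -> list[int]:
        """Drop weakly connected late joiners when a branch is finalized.

        The branch core (its earliest joiners) sets a connectivity floor:
        a member whose mean similarity to the core falls below
        ``_CONNECTIVITY_FLOOR`` times the weakest core member's internal
        connectivity is released to the unassigned pool (and may return in
        the PAM stage).
        """
        members = np.asarray(branch.members)
        if members.size <= min_module_size:
            return list(branch.members)
        order = np.argsort(np.asarray(branch.attach), kind="stable")
        core = members[order[:min_module_size]]
        within = S[np.ix_(core, core)]
        floor = _CONNECTIVITY_FLOOR * (within.sum(axis=1) / (core.size - 1)).min()
        keep = set(core.tolist())
        for p in members[order[min_module_size:]]:
            if S[p, core].mean() >= floor:
                keep.add(int(p))
        return [p for p in branch.members if p in keep]

    base = float(min(0.0, gh.min()))
    branches: dict[int, _Branch] = {i: _Branch([i], [base]) for i in range(n)}
    clusters: list[list[int]] = []

    for step, (ia, ib, h, _) in enumerate(Z):
        node_id = n + step
        hg = float(g(h))
        a, b = branches.pop(int(ia)), branches.pop(int(ib))
        merged = _Branch(members=[], attach=[])
        merged.frozen = a.frozen + b.frozen
        qa = _qualifies(a, hg, min_module_size, max_abs_scatter, min_abs_gap)
        qb = _qualifies(b, hg, min_module_size, max_abs_scatter, min_abs_gap)
        if hg > cut_g:
            # above the cut nothing may fuse: freeze qualifying live branches,
            # everything else stays unassigned
            for child, q in ((a, qa), (b, qb)):
                if q:
                    merged.frozen.append(trim(child))
        elif qa and qb:
            # genuine junction of two clusters
            merged.frozen += [trim(a), trim(b)]
        elif qa or qb:
            done, other = (a, b) if qa else (b, a)
            if is_proto(other) or len(other.members) > len(done.members):
                # junction with a growing proto-cluster or with a larger
                # unassigned pool: close the finished cluster, the sibling
                # keeps accreting
                merged.frozen.append(trim(done))
                merged.members = other.members
                merged.attach = other.attach
            else:
                # small scattered sibling: absorb it and keep growing
                merged.members = done.members + other.members
                merged.attach = done.attach + [hg] * len(other.members)
        else:
            # plain accretion; branch continuity follows the larger live
            # child (ties: first-listed)
            big, small = (a, b) if len(a.members) >= len(b.members) else (b, a)
            merged.members = big.members + small.members
            merged.attach = big.attach + [hg] * len(small.members)
        branches[node_id] = merged

    for branch in branches.values():
        clusters.extend(branch.frozen)
        if len(branch.members) >= min_module_size:
            scatter, _ = _core_stats(branch.members, branch.attach, min_module_size)
            if scatter <= max_abs_scatter:
                clusters.append(trim(branch))

    # dissolve undersized clusters (trimming may shrink below the minimum)
    clusters = [c for c in clusters if len(c) >= min_module_size]

    labels = np.zeros(n, dtype=int)
    # order by decreasing size; ties by smallest member index for determinism
    clusters.sort(key=lambda c: (-len(c), min(c)))
    for cid, members in enumerate(clusters, start=1):
        labels[members] = cid

    if pam_stage and clusters:
        labels = _pam_assign(labels, D, len(clusters))
    if not clusters:
        logger.warning("dynamic hybrid cut found no clusters")
    return labels


def _pam_assign(labels: np.ndarray, D: np.ndarray, k: int) -> np.ndarray:
    """Assign leftover objects to the nearest cluster within its radius.

    Nearness is mean similarity (1 - dissimilarity) to the cluster; the
    assignment radius is ``_CONNECTIVITY_FLOOR`` times the weakest member's
    average within-cluster connectivity, so an object clearly less connected
    than the cluster's own periphery stays unassigned.
    """
    labels = labels.copy()
    unassigned = np.flatnonzero(labels == 0)
    if unassigned.size == 0:
        return labels
    S = 1.0 - D if D.max() <= 1.0 + 1e-9 else np.exp(-D)
    np.fill_diagonal(S, 0.0)
    radii = np.empty(k)
    mean_s = np.empty((len(labels), k))
    for cid in range(1, k + 1):
        members = np.flatnonzero(labels == cid)
        m = members.size
        within = S[np.ix_(members, members)]
        radii[cid - 1] = _CONNECTIVITY_FLOOR * (within.sum(axis=1) / max(m - 1, 1)).min()
        mean_s[:, cid - 1] = S[:, members].mean(axis=1)
    best = np.argmax(mean_s[unassigned], axis=1)
    sim = mean_s[unassigned, best]
    accept = sim >= radii[best]
    labels[unassigned[accept]] = best[accept] + 1
    return labels
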