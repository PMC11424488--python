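"""Copy-number event phylogenies and phylogenetic signal of tumor sidedness.

The distance between two total-copy-number profiles is the minimum number of
events — each adding or subtracting 1 on a contiguous run of bins — that
transform one into the other. Copy number is floored at zero and a bin that
reaches zero is absorbed: it can never regain copies, and events spanning it
leave it unchanged. Trees are built by neighbor joining over pairwise
distances including an artificial diploid root taxon, rooted at that taxon,
with branch event counts taken as rounded branch lengths.

The sidedness analysis estimates Pagel's lambda for a left/right trait on the
tree leaves: lambda scales the shared (off-diagonal) covariance of a Brownian
motion model, so lambda near 1 means the trait tracks the phylogeny (left and
right samples form clades) and lambda near 0 means it is independent of it.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .copy_number import SampleCN

__all__ = [
    "MEDInfeasibleError",
    "med_distance",
    "med_distance_genome",
    "EventTree",
    "build_event_tree",
    "count_events",
    "SidednessTrait",
    "sidedness_signal",
    "trait_from_location",
    "pagel_lambda",
]

DIPLOID_TAXON = "diploid"
MIN_PGA = 0.01


class MEDInfeasibleError(ValueError):
    """Target profile unreachable (nonzero copy number where the source is zero)."""


def _min_plus_1d(f: np.ndarray, axis: int) -> np.ndarray:
    """min over k of f[k] + max(0, i - k), along one axis.

    Decomposes into a prefix-min of (f[k] - k) + i for k <= i and a
    suffix-min of f[k] for k >= i.
    """
    f = np.moveaxis(f, axis, 0)
    idx = np.arange(f.shape[0]).reshape((-1,) + (1,) * (f.ndim - 1))
    g = np.minimum.accumulate(f - idx, axis=0) + idx
    h = np.minimum.accumulate(f[::-1], axis=0)[::-1]
    return np.moveaxis(np.minimum(g, h), 0, axis)


def med_distance(p: Sequence[int], q: Sequence[int]) -> int:
    """Minimum number of contiguous +/-1 events transforming ``p`` into ``q``.

    Computed by a dynamic program over deletion/amplification coverage
    profiles: in an optimal solution all deletions can be placed before all
    amplifications, so the state at each position is the number of deletion
    events ``u`` and amplification events ``v`` covering it, and the event
    count is the total positive increment of ``u`` and ``v`` along the
    genome. Positions at zero in ``p`` (or driven to zero because ``q`` is
    zero) are transparent: events may span them without effect, so their
    coverage is unconstrained.

    The distance is directional (``p`` to ``q``); zero-absorption makes it
    asymmetric. Raises :class:`MEDInfeasibleError` when ``q`` is nonzero at a
    position where ``p`` is zero.
    """
    p = np.asarray(p, dtype=int)
    q = np.asarray(q, dtype=int)
    if p.shape != q.shape:
        raise ValueError("profiles must have equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("copy numbers must be nonnegative")
    if np.any((p == 0) & (q > 0)):
        raise MEDInfeasibleError("nonzero target at an absorbed (zero) source position")
    if p.size == 0 or np.array_equal(p, q):
        return 0

    # collapse adjacent positions with identical (p, q): events merge across them
    keep = np.ones(p.size, dtype=bool)
    keep[1:] = (p[1:] != p[:-1]) | (q[1:] != q[:-1])
    p, q = p[keep], q[keep]

    U = int(p.max())
    V = int(q.max()) + U
    INF = np.inf

    def allowed_mask(pi: int, qi: int) -> np.ndarray:
        m = np.full((U + 1, V + 1), INF)
        if pi == 0:
            m[:, :] = 0.0
        elif qi == 0:
            m[pi:, :] = 0.0
        else:
            lo, hi = max(0, pi - qi), pi - 1
            us = np.arange(lo, hi + 1)
            m[us, us + qi - pi] = 0.0
        return m

    # boundary: u_0 = v_0 = 0 before the first position
    uu = np.arange(U + 1)[:, None]
    vv = np.arange(V + 1)[None, :]
    cost = (uu + vv).astype(float) + allowed_mask(int(p[0]), int(q[0]))
    for pi, qi in zip(p[1:], q[1:]):
        cost = _min_plus_1d(cost, axis=0)
        cost = _min_plus_1d(cost, axis=1)
        cost = cost + allowed_mask(int(pi), int(qi))
    return int(cost.min())


def med_distance_genome(
    p: np.ndarray, q: np.ndarray, chrom: Optional[np.ndarray] = None
) -> int:
    """MED summed per chromosome (events never span chromosome boundaries)."""
    if chrom is None:
        return med_distance(p, q)
    total = 0
    for c in pd.unique(np.asarray(chrom, dtype=object)):
        m = np.asarray(chrom) == c
        total += med_distance(np.asarray(p)[m], np.asarray(q)[m])
    return total


def _symmetrized(p, q, chrom) -> float:
    """Mean of both MED directions; the finite one if the other is infeasible."""
    d_pq = d_qp = None
    try:
        d_pq = med_distance_genome(p, q, chrom)
    except MEDInfeasibleError:
        pass
    try:
        d_qp = med_distance_genome(q, p, chrom)
    except MEDInfeasibleError:
        pass
    if d_pq is None and d_qp is None:
        raise MEDInfeasibleError("profiles mutually unreachable")
    if d_pq is None:
        return float(d_qp)
    if d_qp is None:
        return float(d_pq)
    return (d_pq + d_qp) / 2.0


@dataclass
class EventTree:
    """Rooted copy-number event tree for one participant.

    Leaves are the participant's qualifying samples plus an artificial
    diploid taxon at the root. Each edge carries an integer event count
    (rounded neighbor-joining branch length, floored at zero).
    """

    tree: dendropy.Tree
    sample_ids: list[str]
    root_taxon: str = DIPLOID_TAXON
    distance_matrix: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self._round_edges()

    def _round_edges(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None:
                # half-up rounding: a 0.5-length NJ branch carries one event
                edge.events = int(max(0, np.floor(edge.length + 0.5)))
            else:
                edge.events = 0

    @classmethod
    def from_newick(cls, newick: str, root_taxon: str = DIPLOID_TAXON) -> "EventTree":
        """Build from a newick string whose branch lengths are event counts.

        The tree must contain a leaf named ``root_taxon``; the tree is
        (re)rooted on the edge leading to it.
        """
        tree = dendropy.Tree.get(data=newick, schema="newick")
        node = _find_leaf(tree, root_taxon)
        _root_at_taxon_edge(tree, node)
        samples = [
            t.label for t in tree.taxon_namespace if t.label != root_taxon
        ]
        return cls(tree=tree, sample_ids=samples, root_taxon=root_taxon)

    @property
    def mrca(self) -> dendropy.Node:
        """Most recent common ancestor of the tumor leaves."""
        return self.tree.mrca(taxon_labels=self.sample_ids)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def _root_at_taxon_edge(tree: dendropy.Tree, leaf: dendropy.Node) -> None:
    """Place the root on the leaf's pendant edge, flush against the leaf.

    The leaf keeps a zero-length edge to the root and the full pendant
    length moves to the other side, so no branch length (event count) is
    lost in rooting.
    """
    length = leaf.edge.length or 0.0
    if leaf.parent_node is None:  # already the root
        return
    tree.reroot_at_edge(leaf.edge, length1=length, length2=0.0,
                        update_bipartitions=False)


def _find_leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == label:
            return leaf
    raise ValueError(f"taxon {label!r} not found in tree")


def build_event_tree(
    samples: Sequence[SampleCN], min_pga: float = MIN_PGA
) -> Optional[EventTree]:
    """Neighbor-joining event tree over a participant's samples.

    Bins are collapsed to maximal runs with constant copy number across all
    samples; the pairwise matrix of minimum-event distances (including the
    diploid root: CN 2 on autosomes, 1 on sex chromosomes) is fed to neighbor
    joining and the tree is rooted at the diploid taxon. Samples with PGA
    below ``min_pga`` are excluded; fewer than two qualifying samples yield
    no tree.
    """
    qual = [s for s in samples if s.pga >= min_pga]
    if len(qual) < 2:
        warnings.warn("fewer than 2 samples with PGA >= %g; no tree built" % min_pga)
        return None

    prof = qual[0].segments.profile
    chrom = prof.chrom
    root = np.where(prof.is_sex, 1, 2).astype(int)
    mat = np.stack([root] + [s.bin_cn for s in qual])  # taxa x bins

    # run-length collapse: keep bins where any sample's CN or the chromosome changes
    keep = np.ones(mat.shape[1], dtype=bool)
    keep[1:] = np.any(mat[:, 1:] != mat[:, :-1], axis=0) | (chrom[1:] != chrom[:-1])
    mat = mat[:, keep]
    chrom_r = chrom[keep]

    labels = [DIPLOID_TAXON] + [s.sample_id for s in qual]
    k = len(labels)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = _symmetrized(mat[i], mat[j], chrom_r)
    dm_frame = pd.DataFrame(D, index=labels, columns=labels)

    csv = io.StringIO()
    dm_frame.to_csv(csv)
    csv.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=csv, delimiter=",")
    tree = pdm.nj_tree()
    node = _find_leaf(tree, DIPLOID_TAXON)
    _root_at_taxon_edge(tree, node)
    return EventTree(tree=tree, sample_ids=[s.sample_id for s in qual],
                     distance_matrix=dm_frame)


def count_events(etree: EventTree) -> tuple[int, int, Optional[float]]:
    """(total, subclonal, subclonality) event counts of an event tree.

    Total sums every branch's events; subclonal sums branches strictly below
    the most recent common ancestor of the tumor leaves (clonal events lie on
    the diploid-root side of that node). Subclonality is the subclonal
    fraction, undefined (None) for an event-free tree.
    """
    mrca = etree.mrca
    total = 0
    subclonal = 0
    below = set()
    for node in mrca.preorder_iter():
        if node is not mrca:
            below.add(node)
    for edge in etree.tree.preorder_edge_iter():
        if edge.head_node is etree.tree.seed_node:
            continue
        total += edge.events
        if edge.head_node in below:
            subclonal += edge.events
    subclonality = None if total == 0 else subclonal / total
    return total, subclonal, subclonality


# ---------------------------------------------------------------------------
# phylogenetic signal (Pagel's lambda)


@dataclass
class SidednessTrait:
    """Sidedness trait values and Pagel's lambda estimate for one tree."""

    traits: dict
    lambda_: float = np.nan
    p_value: float = np.nan
    log_lik: float = np.nan
    status: str = "ok"  # ok | failed
    classification: str = field(default="")

    def __post_init__(self) -> None:
        if self.status == "ok" and not self.classification:
            if self.lambda_ > 0.8:
                self.classification = "strong"
            elif self.lambda_ < 0.2:
                self.classification = "mixed"
            else:
                self.classification = "intermediate"


def trait_from_location(label: str) -> float:
    """Side trait coding: right -> 1, left -> 0, anything else -> 0.5."""
    lab = str(label).lower()
    if lab.startswith("right"):
        return 1.0
    if lab.startswith("left"):
        return 0.0
    return 0.5


def _vcv_from_tree(etree: EventTree, jitter: float = 1e-6) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance (shared root-to-tip path length) among tumor leaves.

    The diploid root leaf is dropped before computing depths; the reference
    root for path lengths is the tumor MRCA's parent-side root so shared
    truncal branches contribute to every covariance. Zero-length branches are
    regularized by a small jitter on the diagonal.
    """
    tree = etree.tree.clone(depth=1)
    tree.prune_taxa_with_labels([etree.root_taxon])
    # node depths from the (post-prune) root using event counts as lengths
    root = tree.seed_node
    depth = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        length = node.edge.length if node.edge.length is not None else 0.0
        depth[node] = depth[node.parent_node] + max(0.0, float(length))
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                C[i, i] = depth[leaves[i]]
            else:
                mrca = tree.mrca(taxa=[leaves[i].taxon, leaves[j].taxon])
                C[i, j] = C[j, i] = depth[mrca]
    C = C + jitter * np.eye(n)
    return C, labels


def pagel_lambda(C: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs lambda=0.

    ``C`` is the Brownian covariance; lambda scales its off-diagonal
    entries. The mean and rate are profiled out analytically. Returns
    (lambda_hat, max log-likelihood, LRT p-value against lambda = 0).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)

    def negll(lam: float) -> float:
        V = lam * C + (1 - lam) * np.diag(np.diag(C))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        one = np.ones(n)
        Vi_y = np.linalg.solve(V, y)
        Vi_1 = np.linalg.solve(V, one)
        mu = (one @ Vi_y) / (one @ Vi_1)
        resid = y - mu
        sigma2 = (resid @ np.linalg.solve(V, resid)) / n
        if sigma2 <= 0:
            return np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        return 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

    res = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    # guard against local optima at the boundary
    cand = [(negll(l), l) for l in (0.0, 1.0, float(res.x))]
    nll_hat, lam_hat = min(cand)
    ll_hat = -nll_hat
    ll0 = -negll(0.0)
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    return float(lam_hat), float(ll_hat), p


def sidedness_signal(etree: EventTree, locations: dict) -> SidednessTrait:
    """Pagel's lambda for prostate sidedness of a participant's samples.

    ``locations`` maps sample id to a side label (right/left/middle/apex...).
    Requires at least 3 tumor leaves. A constant trait carries no signal and
    the estimation is reported as failed (no test is produced).
    """
    if len(etree.sample_ids) < 3:
        raise ValueError("sidedness signal requires >= 3 tumor leaves")
    traits = {s: trait_from_location(locations[s]) for s in etree.sample_ids}
    C, labels = _vcv_from_tree(etree)
    y = np.array([traits[lab] for lab in labels])
    if np.allclose(y, y[0]):
        return SidednessTrait(traits=traits, status="failed", classification="undefined")
    lam, ll, p = pagel_lambda(C, y)
    return SidednessTrait(traits=traits, lambda_=lam, p_value=p, log_lik=ll)
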