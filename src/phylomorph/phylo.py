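"""Phylogenetic comparative analyses of shape.

A time-calibrated phylogeny relates species mean shapes under a Brownian
motion (BM) null: trait covariance among species is proportional to shared
branch length (the matrix C).  This module provides the multivariate
phylogenetic-signal statistic K (ratio of observed to BM-expected trait
variance, 1 under BM), phylogenetic ANOVA by generalized least squares with
residual randomization, maximum-likelihood ancestral shape states,
phylomorphospace projection, UPGMA phenograms from phenotypic distances,
and a tanglegram-style screen for phenotype/phylogeny discordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .stats import AnovaResult, design_matrices, linear_model_anova

__all__ = [
    "Phylogeny",
    "SignalResult",
    "AncestralStates",
    "normalize_label",
    "species_means",
    "phylo_covariance",
    "kmult",
    "pgls_anova",
    "ancestral_states",
    "phylomorphospace",
    "upgma",
    "discordant_pairs",
]


def normalize_label(label: str) -> str:
    """Canonical tip/species label: stripped, internal spaces to underscores."""
    return "_".join(str(label).strip().split())


class TreeError(ValueError):
    pass


class ReconciliationError(ValueError):
    """Tips and data rows do not match; lists the offenders."""

    def __init__(self, missing_data: list[str], missing_tips: list[str]):
        self.missing_data = missing_data
        self.missing_tips = missing_tips
        super().__init__(
            f"tree/data mismatch: tips without data {missing_data}; "
            f"data without tips {missing_tips}"
        )


class Phylogeny:
    """Rooted tree with positive branch lengths, wrapping a dendropy tree.

    Tip labels are normalized (spaces to underscores) and must be unique.
    Node ``index`` attributes are assigned in preorder; index 0 is the root.
    """

    def __init__(self, tree: dendropy.Tree, normalize: bool = True):
        self.tree = tree
        root = tree.seed_node
        if len(root.child_nodes()) < 2:
            raise TreeError("tree must be rooted with >= 2 root children")
        self.nodes = list(tree.preorder_node_iter())
        labels = []
        for i, node in enumerate(self.nodes):
            node.index = i
            if node.is_leaf():
                if node.taxon is None:
                    raise TreeError("leaf without a taxon label")
                lab = normalize_label(node.taxon.label) if normalize else node.taxon.label
                node.taxon.label = lab
                labels.append(lab)
            if node is not root:
                if node.edge.length is None or node.edge.length <= 0:
                    raise TreeError(
                        f"non-positive or missing branch length above node {i}"
                    )
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        self._tip_labels = labels
        self._tip_index = {lab: n.index for lab, n in zip(labels, self.leaves())}
        self._depths = self._compute_depths()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, **kw) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree, **kw)

    @classmethod
    def from_file(cls, path, schema: str | None = None, **kw) -> "Phylogeny":
        path = str(path)
        if schema is None:
            with open(path) as fh:
                head = fh.read(64)
            schema = "nexus" if head.lstrip().lower().startswith("#nexus") else "newick"
        tree = dendropy.Tree.get(path=path, schema=schema)
        return cls(tree, **kw)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- basic structure --------------------------------------------------
    def leaves(self):
        return self.tree.leaf_node_iter()

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def _compute_depths(self) -> np.ndarray:
        depths = np.zeros(len(self.nodes))
        for node in self.nodes:
            if node.parent_node is not None:
                depths[node.index] = depths[node.parent_node.index] + node.edge.length
        return depths

    @property
    def depths(self) -> np.ndarray:
        """Root-to-node path lengths, indexed by node index."""
        return self._depths

    def edges(self) -> list[tuple[int, int, float]]:
        """(parent_index, child_index, length) for every non-root edge."""
        return [
            (n.parent_node.index, n.index, float(n.edge.length))
            for n in self.nodes
            if n.parent_node is not None
        ]

    def node_for_tip(self, label: str):
        idx = self._tip_index.get(normalize_label(label))
        if idx is None:
            raise KeyError(f"tip {label!r} not in tree")
        return self.nodes[idx]

    def mrca(self, a: str, b: str):
        na, nb = self.node_for_tip(a), self.node_for_tip(b)
        anc_a = set()
        node = na
        while node is not None:
            anc_a.add(node.index)
            node = node.parent_node
        node = nb
        while node.index not in anc_a:
            node = node.parent_node
        return node

    def path_to_ancestor(self, tip: str, ancestor) -> list[int]:
        """Node indices from ``ancestor`` down to ``tip`` (both included)."""
        path = []
        node = self.node_for_tip(tip)
        while node is not ancestor:
            path.append(node.index)
            node = node.parent_node
            if node is None:
                raise TreeError(f"{ancestor} is not an ancestor of {tip!r}")
        path.append(ancestor.index)
        return path[::-1]

    def clade_edges(self, ancestor) -> list[tuple[int, int, float]]:
        """All edges descended from ``ancestor``."""
        out = []
        stack = list(ancestor.child_nodes())
        while stack:
            node = stack.pop()
            out.append((node.parent_node.index, node.index, float(node.edge.length)))
            stack.extend(node.child_nodes())
        return out

    # -- distances and covariance -----------------------------------------
    def covariance(self, tip_order: list[str] | None = None) -> np.ndarray:
        """BM covariance C: C_ij = depth of MRCA(i, j), diagonal = tip depths."""
        order = self._resolve_order(tip_order)
        pos = {lab: i for i, lab in enumerate(order)}
        n = len(order)
        c = np.zeros((n, n))
        # postorder: collect descendant tip positions per node; tips that first
        # meet at a node share that node's depth
        tipsets: dict[int, list[int]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                if lab in pos:
                    tipsets[node.index] = [pos[lab]]
                    c[pos[lab], pos[lab]] = self._depths[node.index]
                else:
                    tipsets[node.index] = []
                continue
            child_sets = [tipsets.pop(ch.index) for ch in node.child_nodes()]
            d = self._depths[node.index]
            for i in range(len(child_sets)):
                for j in range(i + 1, len(child_sets)):
                    for a in child_sets[i]:
                        for b in child_sets[j]:
                            c[a, b] = c[b, a] = d
            tipsets[node.index] = [t for s in child_sets for t in s]
        return c

    def path_distance_matrix(self, tip_order: list[str] | None = None) -> np.ndarray:
        """Patristic (sum of branch lengths) distances between tips."""
        order = self._resolve_order(tip_order)
        c = self.covariance(order)
        depths = np.diag(c)
        return depths[:, None] + depths[None, :] - 2 * c

    def _resolve_order(self, tip_order) -> list[str]:
        if tip_order is None:
            return self.tip_labels
        order = [normalize_label(t) for t in tip_order]
        missing = [t for t in order if t not in self._tip_index]
        extra = [t for t in self._tip_index if t not in set(order)]
        if missing or extra:
            raise ReconciliationError(missing_tips=missing, missing_data=extra)
        return order


@dataclass
class SignalResult:
    k_statistic: float
    p_value: float
    perm_distribution: np.ndarray
    n_perm: int


@dataclass
class AncestralStates:
    """Per-node trait vectors: tips carry the data, internal nodes the
    branch-length-weighted ML (BM) estimates."""

    states: np.ndarray  # (n_nodes, p) indexed by Phylogeny node index
    tree: Phylogeny

    @property
    def root(self) -> np.ndarray:
        return self.states[0]

    def internal(self) -> dict[int, np.ndarray]:
        return {
            n.index: self.states[n.index] for n in self.tree.nodes if not n.is_leaf()
        }

    def objective(self) -> float:
        """Sum over edges of squared change divided by branch length."""
        tot = 0.0
        for p, ch, ln in self.tree.edges():
            tot += float(((self.states[p] - self.states[ch]) ** 2).sum()) / ln
        return tot


def species_means(aligned, species: np.ndarray, tree: Phylogeny | None = None) -> pd.DataFrame:
    """Per-species mean flattened shapes, optionally reconciled to tree tips.

    Returns a DataFrame indexed by normalized species label with one column
    per flattened coordinate, rows ordered to match the tree's tips when a
    tree is given.
    """
    from .stats import _flat

    x = _flat(aligned)
    species = np.asarray([normalize_label(s) for s in species])
    if species.shape[0] != x.shape[0]:
        raise ValueError("one species label per specimen required")
    means = pd.DataFrame(x).groupby(species).mean()
    means.index.name = "species"
    if tree is not None:
        have = set(means.index)
        tips = set(tree.tip_labels)
        if have != tips:
            raise ReconciliationError(
                missing_data=sorted(tips - have), missing_tips=sorted(have - tips)
            )
        means = means.loc[tree.tip_labels]
    return means


def phylo_covariance(tree: Phylogeny, tip_order: list[str] | None = None) -> np.ndarray:
    """Among-species BM covariance matrix C (shared root-to-MRCA path lengths)."""
    return tree.covariance(tip_order)


def _spd_inverse(c: np.ndarray, floor: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Inverse and inverse square root of a symmetric PD matrix.

    Eigenvalues at or below ``floor`` (relative to the largest) indicate a
    pathological tree and raise rather than being pseudo-inverted.
    """
    w, v = np.linalg.eigh((c + c.T) / 2)
    if w.min() <= floor * max(w.max(), 1.0):
        raise TreeError(
            f"phylogenetic covariance numerically singular (min eigenvalue {w.min():.3e})"
        )
    inv = (v / w) @ v.T
    inv_sqrt = (v / np.sqrt(w)) @ v.T
    return inv, inv_sqrt


def _align_table(y, tree: Phylogeny) -> np.ndarray:
    """Values of a species x trait table in the tree's tip order."""
    if isinstance(y, pd.DataFrame):
        idx = [normalize_label(i) for i in y.index]
        y = y.set_axis(idx, axis=0)
        have, tips = set(idx), set(tree.tip_labels)
        if have != tips:
            raise ReconciliationError(
                missing_data=sorted(tips - have), missing_tips=sorted(have - tips)
            )
        return y.loc[tree.tip_labels].to_numpy(dtype=float)
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != tree.n_tips:
        raise ValueError("rows must equal number of tips (or pass a labeled DataFrame)")
    return arr


def _k_statistic(y: np.ndarray, c_inv: np.ndarray, trc: float, one_cinv: np.ndarray,
                 sum_cinv: float) -> float:
    n = y.shape[0]
    a = (one_cinv @ y) / sum_cinv  # phylogenetically weighted mean, (p,)
    r = y - a
    num = float((r * r).sum())
    den = float((r * (c_inv @ r)).sum())
    if den <= 0 or num <= 0:
        raise ValueError("zero trait variance: K undefined")
    expected = (trc - n / sum_cinv) / (n - 1)
    return (num / den) / expected


def kmult(
    y,
    tree: Phylogeny,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> SignalResult:
    """Multivariate phylogenetic signal K.

    K is the ratio of observed to BM-expected trait variance: with
    phylogenetically weighted mean a, K = [r'r / r'C^{-1}r] / [(tr C -
    n/(1'C^{-1}1)) / (n-1)] where r = Y - 1a.  K = 1 under BM; K < 1 means
    less resemblance among relatives than BM predicts.  Significance is by
    permuting the tip-to-row assignment.
    """
    yv = _align_table(y, tree)
    n = yv.shape[0]
    if n < 3:
        raise ValueError("K needs >= 3 species")
    c = tree.covariance(list(y.index) if isinstance(y, pd.DataFrame) else None)
    c_inv, _ = _spd_inverse(c)
    ones = np.ones(n)
    one_cinv = ones @ c_inv
    sum_cinv = float(one_cinv @ ones)
    trc = float(np.trace(c))
    k_obs = _k_statistic(yv, c_inv, trc, one_cinv, sum_cinv)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = np.empty(n_perm + 1)
    dist[0] = k_obs
    for j in range(n_perm):
        dist[j + 1] = _k_statistic(
            yv[rng.permutation(n)], c_inv, trc, one_cinv, sum_cinv
        )
    p = float((dist >= k_obs - 1e-14).sum() / (n_perm + 1))
    return SignalResult(k_statistic=float(k_obs), p_value=p, perm_distribution=dist,
                        n_perm=n_perm)


def pgls_anova(
    y,
    tree: Phylogeny,
    factors: dict[str, np.ndarray],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    effect_size_on_log: bool = True,
) -> AnovaResult:
    """Phylogenetic ANOVA: GLS transform then the RRPP linear-model machinery.

    Data and design (including the intercept) are premultiplied by
    T = C^{-1/2}; the sequential-SS / RRPP engine of
    :func:`phylomorph.stats.linear_model_anova` then runs on the transformed
    model.  With C equal to the identity the result is identical to the
    non-phylogenetic Procrustes ANOVA under the same seed.
    """
    yv = _align_table(y, tree)
    n = yv.shape[0]
    c = tree.covariance(list(y.index) if isinstance(y, pd.DataFrame) else None)
    _, t = _spd_inverse(c)
    blocks = design_matrices(factors, n)
    blocks_t = [(name, t @ cols) for name, cols in blocks]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return linear_model_anova(
        t @ yv,
        blocks_t,
        n_perm=n_perm,
        rng=rng,
        effect_size_on_log=effect_size_on_log,
        intercept=t @ np.ones((n, 1)),
    )


def ancestral_states(y, tree: Phylogeny) -> AncestralStates:
    """Maximum-likelihood (BM) ancestral trait vectors.

    The ML states minimize the branch-length-weighted sum of squared changes
    sum_edges ||x_parent - x_child||^2 / length, a quadratic problem solved
    as a linear system on the tree's weighted graph Laplacian.
    """
    yv = _align_table(y, tree)
    solver = ancestral_operator(tree)
    return AncestralStates(states=solver(yv), tree=tree)


def ancestral_operator(tree: Phylogeny):
    """Precompute the linear map tip data -> all node states (tips passed through).

    Returns a callable taking (n_tips, p) tip values in tree tip order and
    returning (n_nodes, p) states indexed by node index.  The map is linear,
    so one factorization serves any number of datasets.
    """
    n_nodes = len(tree.nodes)
    lap = np.zeros((n_nodes, n_nodes))
    for p_idx, c_idx, ln in tree.edges():
        w = 1.0 / ln
        lap[p_idx, p_idx] += w
        lap[c_idx, c_idx] += w
        lap[p_idx, c_idx] -= w
        lap[c_idx, p_idx] -= w
    tip_idx = np.array([tree.node_for_tip(lab).index for lab in tree.tip_labels])
    internal_idx = np.array(
        [n.index for n in tree.nodes if not n.is_leaf()], dtype=int
    )
    l_ii = lap[np.ix_(internal_idx, internal_idx)]
    l_it = lap[np.ix_(internal_idx, tip_idx)]
    solve_mat = np.linalg.solve(l_ii, -l_it)  # (n_internal, n_tips)

    def apply(tip_values: np.ndarray) -> np.ndarray:
        tip_values = np.atleast_2d(np.asarray(tip_values, dtype=float))
        states = np.zeros((n_nodes, tip_values.shape[1]))
        states[tip_idx] = tip_values
        states[internal_idx] = solve_mat @ tip_values
        return states

    return apply


def phylomorphospace(
    pca, anc: AncestralStates, tree: Phylogeny
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project the tree into PC1-PC2 of the species-mean morphospace.

    Tips keep their PCA scores exactly; internal nodes are the ancestral
    flattened shapes projected with the tip-derived eigenvectors.  Returns
    (nodes, edges) tables ready for plotting: nodes with node index, label,
    tip flag and all PC scores; edges as parent/child node indices.
    """
    scores_all = pca.project(anc.states)  # includes tips; identical to pca.scores rows
    rows = []
    for node in tree.nodes:
        lab = node.taxon.label if node.is_leaf() else ""
        rows.append(
            {"node": node.index, "label": lab, "is_tip": node.is_leaf()}
            | {f"PC{k + 1}": scores_all[node.index, k] for k in range(scores_all.shape[1])}
        )
    nodes = pd.DataFrame(rows).set_index("node")
    edges = pd.DataFrame(
        [(p, c) for p, c, _ in tree.edges()], columns=["parent", "child"]
    )
    return nodes, edges


def upgma(dist, labels: list[str] | None = None) -> Phylogeny:
    """Average-linkage (UPGMA) phenogram from a symmetric distance matrix.

    Clusters merge at height d/2 where d is the average between-cluster
    distance; ties are broken by the lowest-index pair (indices in input
    order, then cluster creation order).  An already-ultrametric input is
    reproduced exactly (its cophenetic matrix equals the input).
    """
    if isinstance(dist, pd.DataFrame):
        labels = [normalize_label(i) for i in dist.index]
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"t{i + 1}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.abs(np.diag(d)).max() > 0:
        raise ValueError("distance matrix must be square symmetric with zero diagonal")
    if d.min() < 0:
        raise ValueError("negative distances")

    d = d.copy().astype(float)
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    dmat = {(min(i, j), max(i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                dij = dmat[(min(i, j), max(i, j))]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, i, j)
        dij, i, j = best
        h = dij / 2.0
        bi, bj = h - heights[i], h - heights[j]
        newick[next_id] = f"({newick[i]}:{float(bi):.17g},{newick[j]}:{float(bj):.17g})"
        heights[next_id] = h
        sizes[next_id] = sizes[i] + sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dmat[(min(i, k), max(i, k))]
            djk = dmat[(min(j, k), max(j, k))]
            dmat[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return Phylogeny.from_newick(newick[active[0]] + ";")


def discordant_pairs(
    tree: Phylogeny, phenogram: Phylogeny, quantile: float = 0.5
) -> pd.DataFrame:
    """Screen for phenotype/phylogeny discordance (tanglegram crossings).

    Returns tip pairs that are sisters in the phenogram (share a parent with
    exactly two leaf children) but whose patristic distance on the phylogeny
    exceeds the given quantile of all pairwise tip distances, ranked by
    descending phylogenetic distance.  This is a screening aid; the choice
    of focal pairs for convergence testing remains with the analyst.
    """
    if set(tree.tip_labels) != set(phenogram.tip_labels):
        raise ReconciliationError(
            missing_data=sorted(set(phenogram.tip_labels) - set(tree.tip_labels)),
            missing_tips=sorted(set(tree.tip_labels) - set(phenogram.tip_labels)),
        )
    order = tree.tip_labels
    pos = {lab: i for i, lab in enumerate(order)}
    pdm = tree.path_distance_matrix(order)
    cut = float(np.quantile(pdm[np.triu_indices_from(pdm, k=1)], quantile))
    rows = []
    for node in phenogram.nodes:
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            a, b = kids[0].taxon.label, kids[1].taxon.label
            dphy = float(pdm[pos[a], pos[b]])
            if dphy > cut:
                rows.append({"tip_a": a, "tip_b": b, "phylo_distance": dphy})
    out = pd.DataFrame(rows, columns=["tip_a", "tip_b", "phylo_distance"])
    return out.sort_values("phylo_distance", ascending=False).reset_index(drop=True)
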