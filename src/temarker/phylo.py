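"""Distance trees with bootstrap support, and GTR+Gamma likelihood.

Tree building is neighbor joining on a model-corrected distance matrix;
support values come from column-bootstrap replicates. Likelihoods are
evaluated with Felsenstein pruning under the general time-reversible
model with a discrete-Gamma mixture of site rates on a *fixed* topology
(optionally with coordinate-wise branch-length optimisation); no heuristic
topology search is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as _gamma_dist

from .evodist import pairwise_distance_matrix
from .io import SequenceSet

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _check_distance_frame(D: pd.DataFrame) -> None:
    if D.shape[0] != D.shape[1] or list(D.index) != list(D.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(D.values, D.values.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D.values), 0):
        raise ValueError("distance matrix must have a zero diagonal")


def neighbor_joining(D: pd.DataFrame,
                     taxon_namespace: dendropy.TaxonNamespace | None = None,
                     collapse_zero: bool = True) -> dendropy.Tree:
    """Saitou–Nei neighbor joining, deterministic for a given input.

    Ties in the Q-criterion are broken by the first (row-major) minimal
    pair, so reruns are byte-identical. Negative branch lengths are clamped
    to zero with the deficit moved to the sister branch (path lengths
    through the parent are preserved); zero-length internal edges are then
    collapsed into polytomies, so a matrix with no signal degenerates to a
    star.
    """
    _check_distance_frame(D)
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = list(D.index)
    ns = taxon_namespace or dendropy.TaxonNamespace(labels)
    taxa = {t.label: t for t in ns}
    for lab in labels:
        if lab not in taxa:
            taxa[lab] = ns.new_taxon(lab)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa[lab])
        nodes.append(node)
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.iloc[i, j])

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d(i, j) / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        if li < 0:
            li, lj = 0.0, d(i, j)
        if lj < 0:
            li, lj = d(i, j), 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes.append(parent)
        u = next_id
        next_id += 1
        for k in active:
            if k not in (i, j):
                dist[(min(u, k), max(u, k))] = max(
                    0.0, (d(i, k) + d(j, k) - d(i, j)) / 2
                )
        active = [k for k in active if k not in (i, j)] + [u]
    # final three nodes join at an unrooted central node
    i, j, k = active
    root = dendropy.Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        root.add_child(nodes[a])
        nodes[a].edge.length = max(0.0, (d(a, b) + d(a, c) - d(b, c)) / 2)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    if collapse_zero:
        for node in list(tree.preorder_internal_node_iter()):
            if node.parent_node is not None and node.edge.length is not None \
                    and node.edge.length <= 0:
                node.edge.collapse()
    return tree


def tree_from_msa(msa: SequenceSet, model: str = "tn93",
                  taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Convenience builder: model distance matrix -> NJ tree."""
    return neighbor_joining(pairwise_distance_matrix(msa, model=model),
                            taxon_namespace=taxon_namespace)


def _internal_bipartitions(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    masks = set()
    n_leaves = len(tree.taxon_namespace)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is None or edge.head_node.is_leaf():
            continue
        b = edge.bipartition
        if b.is_trivial():
            continue
        masks.add(b.split_bitmask)
    return masks


def bootstrap_support(msa: SequenceSet, n_reps: int = 1000, seed: int = 0,
                      builder=None, model: str = "tn93") -> dendropy.Tree:
    """Column-bootstrap support for the full-data tree.

    Alignment columns are resampled with replacement ``n_reps`` times, a
    tree is rebuilt per replicate, and each internal bipartition of the
    full-data tree is labeled with the percentage of replicates containing
    it. Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ns = dendropy.TaxonNamespace([sid for sid, _ in msa.entries])
    if builder is None:
        def builder(m: SequenceSet, _ns=ns) -> dendropy.Tree:
            return tree_from_msa(m, model=model, taxon_namespace=_ns)
    full_tree = builder(msa)
    targets = _internal_bipartitions(full_tree)
    counts = {m: 0 for m in targets}
    rng = np.random.default_rng(seed)
    rows = [list(seq) for _, seq in msa.entries]
    arr = np.array(rows)  # (n_taxa, n_cols)
    ncols = arr.shape[1]
    for _ in range(n_reps):
        idx = rng.integers(0, ncols, size=ncols)
        rep = SequenceSet(
            entries=[(sid, "".join(arr[i, idx])) for i, (sid, _) in enumerate(msa.entries)],
            aligned=True,
        )
        try:
            rep_tree = builder(rep)
        except ValueError:   # e.g. a saturated replicate: counts nothing
            continue
        rep_masks = _internal_bipartitions(rep_tree)
        for m in targets & rep_masks:
            counts[m] += 1
    full_tree.encode_bipartitions()
    for edge in full_tree.preorder_edge_iter():
        node = edge.head_node
        if node.parent_node is None or node.is_leaf():
            continue
        b = edge.bipartition
        if b.is_trivial():
            continue
        support = 100.0 * counts[b.split_bitmask] / n_reps
        node.label = f"{support:.0f}"
        node.support = support
    return full_tree


# -- GTR + discrete Gamma likelihood --------------------------------------

@dataclass(frozen=True)
class GTRGammaModel:
    """General time-reversible model with discrete-Gamma rate mixture.

    ``exchangeabilities`` are the six symmetric rates in the order
    AC, AG, AT, CG, CT, GT; ``base_freqs`` are stationary frequencies in
    ACGT order. Category rates use mean-one median discretisation.
    """

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 3.4437
    n_categories: int = 5

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or any(r <= 0 for r in self.exchangeabilities):
            raise ValueError("need 6 positive exchangeabilities")
        if len(self.base_freqs) != 4 or any(f < 0 for f in self.base_freqs):
            raise ValueError("need 4 non-negative base frequencies")
        if abs(sum(self.base_freqs) - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1 within 1e-12")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Q normalised to one expected substitution per unit branch length."""
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        R = np.array([
            [0, ac, ag, at],
            [ac, 0, cg, ct],
            [ag, cg, 0, gt],
            [at, ct, gt, 0],
        ], dtype=float)
        pi = np.asarray(self.base_freqs)
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        return Q / mu

    def category_rates(self) -> np.ndarray:
        """Median-discretised Gamma rates, normalised to mean one."""
        k = self.n_categories
        if k == 1:
            return np.ones(1)
        quantiles = (2 * np.arange(k) + 1) / (2 * k)
        r = _gamma_dist.ppf(quantiles, a=self.gamma_shape, scale=1.0 / self.gamma_shape)
        return r / r.mean()


def _transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    # reversible Q is similar to a symmetric matrix; exponentiate by eigen
    sq = np.sqrt(pi)
    S = (Q * sq[:, None]) / sq[None, :]
    lam, U = np.linalg.eigh((S + S.T) / 2)
    E = (U * np.exp(lam * t)) @ U.T
    return (E * sq[None, :]) / sq[:, None]


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=int)


def gtr_gamma_loglik(msa: SequenceSet, tree: dendropy.Tree,
                     model: GTRGammaModel = GTRGammaModel()) -> float:
    """Log-likelihood of an alignment on a fixed tree, Felsenstein pruning.

    Branch lengths are in expected substitutions per site. Columns with a
    gap or N in a row are treated as missing data for that row
    (marginalised). The likelihood is invariant to the placement of the
    root for this reversible model.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if leaf_labels != set(msa.ids):
        raise ValueError("tree leaves and alignment rows do not match")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("tree has unset branch lengths")
    pi = np.asarray(model.base_freqs)
    Q = model.rate_matrix()
    rates = model.category_rates()

    codes = {sid: _encode(seq) for sid, seq in msa.entries}
    # compress identical site patterns
    mat = np.stack([codes[sid] for sid in msa.ids])
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    n_pat = patterns.shape[1]
    row_of = {sid: i for i, sid in enumerate(msa.ids)}

    leaf_partial: dict[str, np.ndarray] = {}
    for sid in msa.ids:
        part = np.zeros((n_pat, 4))
        col = patterns[row_of[sid]]
        missing = col < 0
        part[np.arange(n_pat)[~missing], col[~missing]] = 1.0
        part[missing] = 1.0
        leaf_partial[sid] = part

    site_like = np.zeros(n_pat)
    for rate in rates:
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                partials[id(node)] = leaf_partial[node.taxon.label]
                continue
            part = np.ones((n_pat, 4))
            for child in node.child_nodes():
                P = _transition_matrix(Q, pi, rate * child.edge.length)
                part *= partials.pop(id(child)) @ P.T
            partials[id(node)] = part
        root = tree.seed_node
        site_like += (partials[id(root)] @ pi) / len(rates)
    if np.any(site_like <= 0):
        raise ValueError("zero site likelihood; check the model and tree")
    return float(np.dot(counts, np.log(site_like)))


def optimize_branch_lengths(msa: SequenceSet, tree: dendropy.Tree,
                            model: GTRGammaModel = GTRGammaModel(),
                            tol: float = 1e-6, max_sweeps: int = 5) -> float:
    """Coordinate-wise Brent optimisation of branch lengths in place.

    Returns the final log-likelihood. The topology is never changed.
    """
    edges = [n.edge for n in tree.preorder_node_iter() if n.parent_node is not None]
    prev = gtr_gamma_loglik(msa, tree, model)
    for _ in range(max_sweeps):
        for edge in edges:
            def neg(x: float, _edge=edge) -> float:
                _edge.length = x
                return -gtr_gamma_loglik(msa, tree, model)
            res = minimize_scalar(neg, bounds=(1e-9, 10.0), method="bounded",
                                  options={"xatol": tol})
            edge.length = float(res.x)
        cur = gtr_gamma_loglik(msa, tree, model)
        if cur - prev < tol:
            break
        prev = cur
    return gtr_gamma_loglik(msa, tree, model)
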