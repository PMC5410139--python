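"""Maximum-likelihood machinery under TN93 (+G, +I).

The substitution model is the Tamura–Nei (1993) parameterization: distinct
purine (A<->G) and pyrimidine (C<->T) transition rates, one transversion
rate, arbitrary base frequencies.  Rate heterogeneity uses the discrete
gamma approximation with equal-probability categories and category-mean
rates, optionally mixed with a proportion of invariant sites: a site has
rate 0 with probability ``p_inv`` and otherwise one of the gamma rates,
rescaled so the mean total rate is 1 (branch lengths stay in expected
substitutions per site).

Log-likelihoods are computed by Felsenstein's pruning algorithm with
per-node rescaling, so valid inputs never underflow to -inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

import dendropy

from .alignment import Alignment, BASES
from .errors import ConfigError, TreeError
from .trees import read_newick, write_newick

_BASE_TO_INDEX = {b: i for i, b in enumerate(BASES)}
#: Compatible state sets for alignment characters (missing = all states).
_CHAR_STATES = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,),
    "-": (0, 1, 2, 3), "N": (0, 1, 2, 3), "?": (0, 1, 2, 3),
}


@dataclass
class SubstitutionModel:
    """TN93(+G+I) model specification.

    ``kappa1``/``kappa2`` are the purine/pyrimidine transition rates relative
    to the transversion rate.  ``alpha`` is the gamma shape (None disables
    rate heterogeneity), ``p_inv`` the invariant-site proportion, and
    ``n_categories`` the number of discrete gamma categories.
    """

    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa1: float = 2.0
    kappa2: float = 2.0
    alpha: float | None = None
    p_inv: float = 0.0
    n_categories: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if abs(self.freqs.sum() - 1) > 1e-8 or np.any(self.freqs <= 0):
            raise ConfigError("base frequencies must be positive and sum to 1")
        if not (0 <= self.p_inv < 1):
            raise ConfigError("p_inv must lie in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ConfigError("gamma shape alpha must be positive")
        if self.n_categories < 1:
            raise ConfigError("need at least one rate category")

    @classmethod
    def from_alignment(cls, a: Alignment, **kwargs) -> "SubstitutionModel":
        """Model with empirical base frequencies from the alignment."""
        flat = a.matrix.ravel()
        counts = np.array([np.sum(flat == b) for b in BASES], dtype=float)
        return cls(freqs=counts / counts.sum(), **kwargs)

    def q_matrix(self) -> np.ndarray:
        """TN93 rate matrix normalized to mean rate 1."""
        pa, pc, pg, pt = self.freqs
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = self.freqs[j]
                pair = {i, j}
                if pair == {0, 2}:
                    rate *= self.kappa1
                elif pair == {1, 3}:
                    rate *= self.kappa2
                q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -float(np.dot(self.freqs, np.diag(q)))
        return q / mean_rate

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the +G+I mixture; weighted mean rate is 1."""
        if self.alpha is None or self.n_categories == 1:
            gamma_rates = np.array([1.0])
        else:
            gamma_rates = discrete_gamma_rates(self.alpha, self.n_categories)
        k = len(gamma_rates)
        if self.p_inv > 0:
            rates = np.concatenate([[0.0], gamma_rates / (1 - self.p_inv)])
            weights = np.concatenate(
                [[self.p_inv], np.full(k, (1 - self.p_inv) / k)]
            )
        else:
            rates = gamma_rates
            weights = np.full(k, 1.0 / k)
        return rates, weights


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability categories of Gamma(alpha, 1/alpha).

    Category boundaries are the i/k quantiles; the mean within each category
    follows from the incomplete gamma function at shape alpha+1.  The rates
    average exactly 1.
    """
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    cdf_hi = np.where(np.isinf(upper), 1.0, gammainc(alpha + 1, upper * alpha))
    cdf_lo = gammainc(alpha + 1, lower * alpha)
    return k * (cdf_hi - cdf_lo)


def _tip_partials(chars) -> np.ndarray:
    """Partial likelihoods (n_patterns, 4) for one tip's character column."""
    out = np.zeros((len(chars), 4))
    for i, c in enumerate(chars):
        out[i, list(_CHAR_STATES[c])] = 1.0
    return out


def _pattern_cache(a: Alignment):
    """Site-pattern multiplicities and per-tip partials, cached per alignment.

    The compression is model-free, so it is computed once and reused across
    repeated likelihood evaluations (branch-length optimization, NNI moves).
    """
    cached = getattr(a, "_lik_pattern_cache", None)
    if cached is not None:
        return cached
    cols = ["".join(a.matrix[:, s]) for s in range(a.length)]
    uniq, counts = np.unique(cols, return_counts=True)
    row = {sid: i for i, sid in enumerate(a.ids)}
    tip_part = {
        sid: _tip_partials([p[row[sid]] for p in uniq]) for sid in a.ids
    }
    cached = (counts.astype(float), tip_part)
    a._lik_pattern_cache = cached
    return cached


def pruning_loglik(
    tree: dendropy.Tree, a: Alignment, model: SubstitutionModel
) -> float:
    """Log-likelihood of the alignment on the tree by pruning.

    Branch lengths are expected substitutions/site.  Ambiguous characters
    contribute partial likelihood 1 for every compatible state.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if labels != set(a.ids):
        raise TreeError("tree leaf labels do not match alignment ids")
    counts, tip_part = _pattern_cache(a)
    n_pat = len(counts)

    q = model.q_matrix()
    rates, weights = model.category_rates()
    postorder = list(tree.postorder_node_iter())

    site_lik = np.zeros(n_pat)
    log_scale_total = np.zeros(n_pat)
    per_cat = []
    for rate, w in zip(rates, weights):
        partials: dict = {}
        log_scale = np.zeros(n_pat)
        for node in postorder:
            if node.is_leaf():
                partials[node] = tip_part[node.taxon.label]
                continue
            part = np.ones((n_pat, 4))
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                p_mat = expm(q * (rate * t)) if rate * t > 0 else np.eye(4)
                part *= partials[child] @ p_mat.T
            scale = part.max(axis=1)
            scale[scale == 0] = 1.0
            part /= scale[:, None]
            log_scale += np.log(scale)
            partials[node] = part
        root_lik = partials[tree.seed_node] @ model.freqs
        per_cat.append((w, root_lik, log_scale))

    # combine categories on a common log scale per pattern
    max_log = np.max([ls for _, _, ls in per_cat], axis=0)
    mix = np.zeros(n_pat)
    for w, root_lik, log_scale in per_cat:
        mix += w * root_lik * np.exp(log_scale - max_log)
    if np.any(mix <= 0):
        raise FloatingPointError("zero site likelihood after scaling")
    return float(np.dot(counts, np.log(mix) + max_log))


def optimize_branch_lengths(
    tree: dendropy.Tree,
    a: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_rounds: int = 20,
) -> tuple[dendropy.Tree, float]:
    """Optimize branch lengths by cyclic 1-D (Brent) maximization.

    Returns (tree with optimized lengths, log-likelihood).  The likelihood is
    non-decreasing across accepted updates; iteration stops when a full
    round improves the log-likelihood by less than ``tol``.
    """
    from scipy.optimize import minimize_scalar

    tree = tree.clone(depth=1)
    edges = [nd.edge for nd in tree.preorder_node_iter() if nd.parent_node]
    lnl = pruning_loglik(tree, a, model)
    for _ in range(max_rounds):
        prev = lnl
        for edge in edges:
            current = edge.length or 1e-8

            def neg(x: float, e=edge) -> float:
                e.length = np.exp(x)
                return -pruning_loglik(tree, a, model)

            res = minimize_scalar(
                neg,
                bracket=(np.log(max(current, 1e-8)) - 1, np.log(max(current, 1e-8)) + 1),
                method="brent",
                options={"xtol": 1e-4},
            )
            cand = float(np.exp(res.x))
            edge.length = cand
            new_lnl = -res.fun
            if new_lnl < lnl:  # guard: never accept a worsening step
                edge.length = current
            else:
                lnl = new_lnl
        if lnl - prev < tol:
            break
    else:
        import warnings

        warnings.warn("branch-length optimization did not converge; best kept")
    return tree, float(pruning_loglik(tree, a, model))


def _unroot_newick(tree: dendropy.Tree) -> str:
    t = tree.clone(depth=1)
    t.deroot()
    return write_newick(t)


def nni_search(
    a: Alignment,
    model: SubstitutionModel,
    seed: int = 0,
    start_tree: dendropy.Tree | None = None,
    max_iter: int = 50,
) -> tuple[dendropy.Tree, float]:
    """Greedy NNI hill-climbing under the likelihood criterion.

    The starting tree defaults to a maximum-parsimony tree (stepwise
    addition + NNI) with parsimony branch lengths, mirroring the protocol of
    seeding the ML heuristic search with MP trees.
    """
    from .parsimony import parsimony_search

    if start_tree is None:
        ps = parsimony_search(a, seed=seed)
        start_tree = ps.trees[0]
        for nd in start_tree.preorder_node_iter():
            if nd.parent_node:
                nd.edge.length = 0.05
    tree, lnl = optimize_branch_lengths(start_tree, a, model)
    for _ in range(max_iter):
        improved = False
        for alt in _nni_alternatives(tree):
            alt_tree, alt_lnl = optimize_branch_lengths(alt, a, model)
            if alt_lnl > lnl + 1e-6:
                tree, lnl = alt_tree, alt_lnl
                improved = True
                break
        if not improved:
            break
    return tree, lnl


def _nni_alternatives(tree: dendropy.Tree) -> list[dendropy.Tree]:
    """All NNI rearrangements of a tree, via its parsimony-style adjacency."""
    from .parsimony import _Topology

    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    idx = {lab: i for i, lab in enumerate(labels)}
    topo = _topology_from_tree(tree, idx)
    out = []
    for t in topo.nni_neighbours():
        nw = t.to_newick(labels)
        alt = read_newick(nw)
        for nd in alt.preorder_node_iter():
            if nd.parent_node:
                nd.edge.length = 0.05
        out.append(alt)
    return out


def _topology_from_tree(tree: dendropy.Tree, idx: dict[str, int]):
    from .parsimony import _Topology

    adj: dict[int, list[int]] = {}
    next_id = [1_000_000 + len(idx)]
    node_id: dict = {}

    def get_id(node) -> int:
        if node not in node_id:
            if node.is_leaf():
                node_id[node] = idx[node.taxon.label]
            else:
                node_id[node] = next_id[0]
                next_id[0] += 1
        return node_id[node]

    t = tree.clone(depth=1)
    t.deroot()
    for node in t.preorder_node_iter():
        nid = get_id(node)
        adj.setdefault(nid, [])
        for child in node.child_nodes():
            cid = get_id(child)
            adj[nid].append(cid)
            adj.setdefault(cid, []).append(nid)
    return _Topology(adj, len(idx))


def bootstrap_support(
    a: Alignment,
    model: SubstitutionModel,
    reps: int = 100,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Nonparametric bootstrap support for bipartitions (percent of reps).

    Each replicate resamples alignment columns with replacement and builds a
    neighbor-joining tree from uncorrected p distances (robust on resampled
    data); supports are reported for the splits of the NJ tree built from
    the original alignment.  Deterministic given the seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    ref_splits = _nj_splits(a)
    tally = {s: 0 for s in ref_splits}
    for _ in range(reps):
        cols = rng.integers(0, a.length, size=a.length)
        boot = Alignment(ids=list(a.ids), matrix=a.matrix[:, cols])
        for s in _nj_splits(boot):
            if s in tally:
                tally[s] += 1
    return {s: 100.0 * c / reps for s, c in tally.items()}


def _nj_splits(a: Alignment) -> set[frozenset]:
    """Non-trivial splits of the NJ tree on p distances."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    from .distances import pairwise_distance_matrix

    dm = pairwise_distance_matrix(a, model="p")
    sk = SkbioDM(dm.matrix, ids=dm.labels)
    tree = nj(sk)
    all_tips = frozenset(dm.labels)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            if min(all_tips) in side:
                side = all_tips - side
            splits.add(side)
    return splits
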