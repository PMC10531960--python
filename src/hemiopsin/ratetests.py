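"""Rate-constancy tests: Tajima relative rate and molecular-clock LRT.

The Tajima test compares two ingroup sequences against an outgroup
using counts of lineage-unique differences; under rate equality
(m_A - m_B)^2 / (m_A + m_B) is asymptotically chi-square with 1 df.

The clock test fits branch lengths on a fixed rooted bifurcating
topology twice — freely (2n-3 identifiable parameters) and under an
ultrametric constraint (n-1 node heights) — by coordinate ascent on
the Felsenstein-pruning log-likelihood with a JTT+gamma site model,
and refers 2*(lnL_free - lnL_clock) to chi-square with n-2 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .evodist import GammaRates, SubstitutionModel, encode_sequence, N_STATES
from .seqio import Alignment

BL_EPS = 1e-9
BL_MAX = 10.0
CONVERGENCE_TOL = 1e-6
MAX_ROUNDS = 100


@dataclass
class RateTestResult:
    m_a: int
    m_b: int
    statistic: float
    df: int
    p_value: float


def tajima_relative_rate(seq_a: str, seq_b: str, outgroup: str) -> RateTestResult:
    """Tajima's 1D relative rate test on three aligned sequences.

    Sites with a gap or X in any of the three sequences are excluded.
    Invariant sites and sites where A and B agree contribute nothing.
    """
    if not (len(seq_a) == len(seq_b) == len(outgroup)):
        raise ValueError("the three sequences must be aligned to equal length")
    a, b, o = (encode_sequence(s) for s in (seq_a, seq_b, outgroup))
    ok = (a >= 0) & (b >= 0) & (o >= 0)
    a, b, o = a[ok], b[ok], o[ok]
    m_a = int(((a != b) & (b == o)).sum())
    m_b = int(((b != a) & (a == o)).sum())
    total = m_a + m_b
    if total == 0:
        return RateTestResult(m_a, m_b, 0.0, 1, 1.0)
    stat = (m_a - m_b) ** 2 / total
    return RateTestResult(m_a, m_b, float(stat), 1, float(chi2.sf(stat, 1)))


class PruningEngine:
    """Felsenstein pruning over compressed site patterns.

    Holds a fixed topology (dendropy tree; strictly bifurcating apart
    from an optionally trifurcating root of unrooted trees) and
    evaluates the alignment log-likelihood for arbitrary branch-length
    assignments under the model's gamma mixture. Gap/X leaves get
    all-ones partials (missing data).
    """

    def __init__(
        self,
        aln: Alignment,
        tree: dendropy.Tree | str,
        model: SubstitutionModel,
        gamma: GammaRates,
    ):
        if isinstance(tree, str):
            tree = dendropy.Tree.get(
                data=tree, schema="newick", preserve_underscores=True
            )
        self.tree = tree
        self.model = model
        self.gamma = gamma

        nodes = list(tree.postorder_node_iter())
        self.nodes = nodes
        self.node_index = {id(n): i for i, n in enumerate(nodes)}
        self.root_index = self.node_index[id(tree.seed_node)]
        for n in nodes:
            kids = n.child_nodes()
            if kids and len(kids) != 2 and n is not tree.seed_node:
                raise ValueError("polytomies are not supported")
            if n is tree.seed_node and kids and len(kids) not in (2, 3):
                raise ValueError("root must have degree 2 or 3")

        leaf_names = [n.taxon.label for n in tree.leaf_node_iter()]
        missing = set(leaf_names) - set(aln.ids)
        if missing:
            raise KeyError(f"tree leaves without sequences: {sorted(missing)}")

        # compress alignment columns restricted to the tree's leaves
        codes = np.stack([encode_sequence(aln.sequence(nm)) for nm in leaf_names])
        patterns, weights = np.unique(codes, axis=1, return_counts=True)
        self.pattern_weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]

        self.leaf_partials: dict[int, np.ndarray] = {}
        for row, name in enumerate(leaf_names):
            node = next(n for n in nodes if n.is_leaf() and n.taxon.label == name)
            part = np.zeros((N_STATES, self.n_patterns))
            col = patterns[row]
            obs = col >= 0
            part[col[obs], np.nonzero(obs)[0]] = 1.0
            part[:, ~obs] = 1.0
            self.leaf_partials[self.node_index[id(node)]] = part

        # branch i = branch above node i (root excluded)
        self.parent = np.full(len(nodes), -1)
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                self.parent[i] = self.node_index[id(n.parent_node)]
        self.children = [
            [self.node_index[id(c)] for c in n.child_nodes()] for n in nodes
        ]

    def branch_lengths_from_tree(self) -> np.ndarray:
        bl = np.zeros(len(self.nodes))
        for i, n in enumerate(self.nodes):
            if n.parent_node is not None:
                bl[i] = n.edge.length or 0.0
        return bl

    def loglik(self, branch_lengths: np.ndarray) -> float:
        """Total log-likelihood, gamma mixture averaged per site."""
        if np.any(branch_lengths < -1e-12):
            raise ValueError("negative branch length")
        site_lik = np.zeros(self.n_patterns)
        pi = self.model.frequencies
        for r in self.gamma.rates:
            partials: dict[int, np.ndarray] = {}
            for i, n in enumerate(self.nodes):
                if not self.children[i]:
                    partials[i] = self.leaf_partials[i]
                else:
                    acc = np.ones((N_STATES, self.n_patterns))
                    for c in self.children[i]:
                        P = self.model.transition_matrix(max(branch_lengths[c], 0.0), r)
                        acc *= P @ partials[c]
                        partials.pop(c)
                    partials[i] = acc
            site_lik += pi @ partials[self.root_index]
        site_lik /= self.gamma.ncat
        return float(self.pattern_weights @ np.log(np.maximum(site_lik, 1e-300)))


@dataclass
class FittedTree:
    newick: str
    branch_lengths: dict[str, float]  # keyed by child clade leaf-set label
    log_likelihood: float
    node_heights: dict[str, float] | None = None
    n_parameters: int = 0


def _clade_key(node: dendropy.Node) -> str:
    return "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def _fit_free(
    engine: PruningEngine, init: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Coordinate-ascent ML branch lengths (log-transformed line searches)."""
    n = len(engine.nodes)
    bl = np.full(n, 0.1) if init is None else init.copy()
    bl[engine.root_index] = 0.0
    lnl = engine.loglik(bl)
    free_idx = [i for i in range(n) if i != engine.root_index]
    for _ in range(MAX_ROUNDS):
        for i in free_idx:
            def neg(u: float) -> float:
                trial = bl.copy()
                trial[i] = np.exp(u) - BL_EPS
                return -engine.loglik(trial)

            res = minimize_scalar(
                neg,
                bounds=(np.log(BL_EPS), np.log(BL_MAX + BL_EPS)),
                method="bounded",
                options={"xatol": 1e-7},
            )
            cand = np.exp(res.x) - BL_EPS
            trial = bl.copy()
            trial[i] = cand
            cand_lnl = engine.loglik(trial)
            if cand_lnl > lnl:
                bl, lnl = trial, cand_lnl
        new_lnl = engine.loglik(bl)
        if new_lnl - lnl < CONVERGENCE_TOL and _ > 0:
            lnl = new_lnl
            break
        lnl = new_lnl
    return bl, lnl


def _fit_clock(engine: PruningEngine) -> tuple[np.ndarray, np.ndarray, float]:
    """Coordinate-ascent ML node heights under an ultrametric constraint.

    Heights are parameterized as the root height H plus, for every
    other internal node, its height as a fraction of its parent's —
    so each coordinate has fixed bounds and a move on one node
    rescales its whole subtree, avoiding the wedging that plain
    height-by-height ascent suffers at the ordering constraints.
    Returns (branch lengths, heights per node index, lnL); tips sit at
    height zero.
    """
    n = len(engine.nodes)
    root = engine.root_index
    # internal nodes in preorder (parents before children)
    preorder = [
        engine.node_index[id(node)]
        for node in engine.tree.preorder_node_iter()
        if node.child_nodes()
    ]
    fractions = {i: 0.6 for i in preorder if i != root}
    root_height = 0.1 * max(1, n // 2)

    def heights_from_params(h_root: float, frac: dict[int, float]) -> np.ndarray:
        h = np.zeros(n)
        h[root] = h_root
        for i in preorder:
            if i != root:
                h[i] = frac[i] * h[engine.parent[i]]
        return h

    def bl_from_heights(h: np.ndarray) -> np.ndarray:
        bl = np.zeros(n)
        for i in range(n):
            p = engine.parent[i]
            if p >= 0:
                bl[i] = max(h[p] - h[i], 0.0)
        return bl

    def loglik_params(h_root: float, frac: dict[int, float]) -> float:
        return engine.loglik(bl_from_heights(heights_from_params(h_root, frac)))

    lnl = loglik_params(root_height, fractions)
    for round_no in range(MAX_ROUNDS):
        res = minimize_scalar(
            lambda h: -loglik_params(h, fractions),
            bounds=(1e-8, BL_MAX), method="bounded", options={"xatol": 1e-9},
        )
        if -res.fun > lnl:
            root_height, lnl = float(res.x), -res.fun
        for i in fractions:
            res = minimize_scalar(
                lambda f: -loglik_params(root_height, {**fractions, i: f}),
                bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-9},
            )
            if -res.fun > lnl:
                fractions[i], lnl = float(res.x), -res.fun
        new_lnl = loglik_params(root_height, fractions)
        if round_no > 0 and new_lnl - prev_lnl < CONVERGENCE_TOL:
            lnl = new_lnl
            break
        prev_lnl = lnl = new_lnl
    heights = heights_from_params(root_height, fractions)
    return bl_from_heights(heights), heights, lnl


def tree_log_likelihood(
    aln: Alignment,
    tree: dendropy.Tree | str,
    model: SubstitutionModel,
    gamma: GammaRates,
) -> float:
    """Log-likelihood of the alignment on a tree with its stored lengths."""
    engine = PruningEngine(aln, tree, model, gamma)
    return engine.loglik(engine.branch_lengths_from_tree())


def _tree_with_lengths(engine: PruningEngine, bl: np.ndarray) -> str:
    tree = engine.tree.clone(depth=1)
    # clone preserves node order in postorder iteration
    for node, orig in zip(tree.postorder_node_iter(), engine.nodes):
        i = engine.node_index[id(orig)]
        if node.parent_node is not None:
            node.edge.length = max(float(bl[i]), 0.0)
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def fit_branch_lengths(
    aln: Alignment,
    topology: dendropy.Tree | str,
    model: SubstitutionModel,
    gamma: GammaRates,
    clock: bool = False,
    init: np.ndarray | None = None,
) -> FittedTree:
    """ML branch lengths on a fixed topology, free or clock-constrained."""
    engine = PruningEngine(aln, topology, model, gamma)
    n_tips = sum(1 for c in engine.children if not c)
    if clock:
        bl, heights, lnl = _fit_clock(engine)
        node_heights = {
            _clade_key(engine.nodes[i]): float(heights[i])
            for i in range(len(engine.nodes))
            if engine.children[i]
        }
        n_par = n_tips - 1
    else:
        bl, lnl = _fit_free(engine, init=init)
        node_heights = None
        n_par = 2 * n_tips - 3
    lengths = {
        _clade_key(engine.nodes[i]): float(bl[i])
        for i in range(len(engine.nodes))
        if engine.parent[i] >= 0
    }
    return FittedTree(
        newick=_tree_with_lengths(engine, bl),
        branch_lengths=lengths,
        log_likelihood=lnl,
        node_heights=node_heights,
        n_parameters=n_par,
    )


@dataclass
class ClockTestResult:
    lnl_clock: float
    lnl_free: float
    statistic: float
    df: int
    p_value: float
    clock_fit: FittedTree | None = None
    free_fit: FittedTree | None = None


def clock_lrt(
    aln: Alignment,
    rooted_topology: dendropy.Tree | str,
    model: SubstitutionModel,
    gamma: GammaRates,
) -> ClockTestResult:
    """Likelihood ratio test of a molecular clock on a rooted topology.

    df = (2n-3) - (n-1) = n-2 for n tips. The free fit is initialized
    from the clock solution, guaranteeing lnL_free >= lnL_clock up to
    optimizer tolerance.
    """
    engine = PruningEngine(aln, rooted_topology, model, gamma)
    n_tips = sum(1 for c in engine.children if not c)
    if n_tips < 3:
        raise ValueError("clock test needs at least 3 tips")
    clock_fit = fit_branch_lengths(aln, rooted_topology, model, gamma, clock=True)
    bl_init = np.zeros(len(engine.nodes))
    for i, node in enumerate(engine.nodes):
        if engine.parent[i] >= 0:
            bl_init[i] = clock_fit.branch_lengths[_clade_key(node)]
    free_fit = fit_branch_lengths(
        aln, rooted_topology, model, gamma, clock=False, init=bl_init
    )
    stat = max(2.0 * (free_fit.log_likelihood - clock_fit.log_likelihood), 0.0)
    df = n_tips - 2
    return ClockTestResult(
        lnl_clock=clock_fit.log_likelihood,
        lnl_free=free_fit.log_likelihood,
        statistic=float(stat),
        df=df,
        p_value=float(chi2.sf(stat, df)),
        clock_fit=clock_fit,
        free_fit=free_fit,
    )
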