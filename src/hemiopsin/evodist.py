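"""JTT+gamma protein distances, clade divergence summaries, and NJ trees.

The substitution process is the standard general time-reversible
amino acid chain: Q_ij = s_ij * pi_j for i != j, with the JTT
empirical exchangeabilities s and frequencies pi, normalized so the
expected substitution rate at equilibrium is one per site. Rate
heterogeneity across sites uses the discrete gamma approximation with
k equal-probability categories whose rates are the category means
(shape alpha = 1 by default). Pairwise distances are maximum
likelihood under this model with pairwise deletion of gap/ambiguous
sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._jtt_data import AMINO_ACIDS, JTT_FREQUENCIES, JTT_LOWER_TRIANGLE
from .seqio import AMBIGUOUS, GAP, Alignment

N_STATES = 20
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

DISTANCE_LOWER = 1e-6
DISTANCE_UPPER = 10.0


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible amino acid substitution model in spectral form.

    ``rate_matrix`` is normalized to one expected substitution per
    site at equilibrium. The eigendecomposition (via the pi-symmetrized
    form, which is real-symmetric by reversibility) makes P(t) a pair
    of 20x20 matrix products instead of a matrix exponential.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    rate_matrix: np.ndarray
    _evals: np.ndarray
    _evecs: np.ndarray      # U with Q = U diag(evals) U^-1
    _evecs_inv: np.ndarray

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        P = (self._evecs * np.exp(self._evals * t * rate)) @ self._evecs_inv
        return P


def _build_model(S: np.ndarray, pi: np.ndarray) -> SubstitutionModel:
    pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    Q = Q / mu
    # symmetrize: B = D^{1/2} Q D^{-1/2} is symmetric under detailed balance
    sqrt_pi = np.sqrt(pi)
    B = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    B = (B + B.T) / 2.0
    evals, V = np.linalg.eigh(B)
    U = V / sqrt_pi[:, None]
    Uinv = V.T * sqrt_pi[None, :]
    return SubstitutionModel(
        exchangeabilities=S,
        frequencies=pi,
        rate_matrix=Q,
        _evals=evals,
        _evecs=U,
        _evecs_inv=Uinv,
    )


def jtt_model() -> SubstitutionModel:
    """The JTT empirical model, normalized to one substitution/site."""
    S = np.zeros((N_STATES, N_STATES))
    it = iter(JTT_LOWER_TRIANGLE)
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    return _build_model(S, np.asarray(JTT_FREQUENCIES, dtype=float))


@dataclass(frozen=True)
class GammaRates:
    """Discrete gamma rate categories (equal probability, mean 1)."""

    shape: float
    ncat: int
    rates: np.ndarray


def discrete_gamma(shape: float = 1.0, ncat: int = 4) -> GammaRates:
    """Equal-probability discrete gamma categories at their means.

    With X ~ Gamma(shape=a, rate=a) (mean 1), the mean of X within
    quantile band (q_{i}, q_{i+1}] is k * [I(a+1, a*q_{i+1}) - I(a+1, a*q_i)]
    where I is the regularized lower incomplete gamma function.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if ncat < 1:
        raise ValueError("need at least one rate category")
    if ncat == 1:
        return GammaRates(shape, 1, np.ones(1))
    probs = np.arange(0, ncat + 1) / ncat
    bounds = gamma_dist.ppf(probs, shape, scale=1.0 / shape)
    bounds[0], bounds[-1] = 0.0, np.inf
    upper = gammainc(shape + 1, shape * bounds[1:])
    lower = gammainc(shape + 1, shape * bounds[:-1])
    rates = ncat * (upper - lower)
    rates = rates / rates.mean()  # enforce exact mean 1
    return GammaRates(shape, ncat, rates)


def transition_probabilities(
    model: SubstitutionModel, t: float, rate: float = 1.0
) -> np.ndarray:
    """P(t) = exp(Q t rate); rows sum to one."""
    return model.transition_matrix(t, rate)


def encode_sequence(seq: str) -> np.ndarray:
    """Integer-encode an aligned protein sequence; gap/X become -1."""
    return np.array([_AA_INDEX.get(ch, -1) for ch in seq], dtype=np.int64)


@dataclass
class DistanceEstimate:
    distance: float
    se: float
    status: str = "ok"  # ok | identical | saturated
    n_sites: int = 0


def _pair_counts(seq_a: str, seq_b: str) -> np.ndarray:
    a = encode_sequence(seq_a)
    b = encode_sequence(seq_b)
    ok = (a >= 0) & (b >= 0)
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (a[ok], b[ok]), 1.0)
    return counts


def pair_log_likelihood(
    counts: np.ndarray, model: SubstitutionModel, gamma: GammaRates, d: float
) -> float:
    """Log-likelihood of a pairwise count table at distance ``d``.

    L(site i->j) = pi_i * mean_c P(d * r_c)_ij; the gamma mixture is
    averaged per site, matching the independent-rates assumption.
    """
    mix = np.zeros((N_STATES, N_STATES))
    for r in gamma.rates:
        mix += model.transition_matrix(d, r)
    mix /= gamma.ncat
    joint = model.frequencies[:, None] * mix
    with np.errstate(divide="ignore"):
        logj = np.log(np.maximum(joint, 1e-300))
    return float((counts * logj).sum())


def pairwise_ml_distance(
    seq_a: str,
    seq_b: str,
    model: SubstitutionModel,
    gamma: GammaRates,
    counts: np.ndarray | None = None,
) -> DistanceEstimate:
    """ML distance between two aligned sequences (pairwise deletion)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    if counts is None:
        counts = _pair_counts(seq_a, seq_b)
    # reversibility makes the likelihood invariant to the direction of
    # comparison; symmetrizing the counts enforces that exactly
    counts = (counts + counts.T) / 2.0
    n = int(round(counts.sum()))
    if n == 0:
        raise ValueError("no comparable (non-gap) sites between sequences")
    n_diff = n - int(np.trace(counts))
    if n_diff == 0:
        return DistanceEstimate(distance=0.0, se=0.0, status="identical", n_sites=n)

    res = minimize_scalar(
        lambda d: -pair_log_likelihood(counts, model, gamma, d),
        bounds=(DISTANCE_LOWER, DISTANCE_UPPER),
        method="bounded",
        options={"xatol": 1e-8},
    )
    d_hat = float(res.x)
    status = "saturated" if d_hat > DISTANCE_UPPER - 1e-3 else "ok"
    # SE from the observed curvature of the log-likelihood
    h = max(1e-4, 1e-3 * d_hat)
    ll = lambda d: pair_log_likelihood(counts, model, gamma, d)
    curv = (ll(d_hat + h) - 2.0 * ll(d_hat) + ll(max(d_hat - h, DISTANCE_LOWER / 2))) / h**2
    se = float(1.0 / np.sqrt(-curv)) if curv < 0 else float("nan")
    return DistanceEstimate(distance=d_hat, se=se, status=status, n_sites=n)


def distance_matrix(
    aln: Alignment, model: SubstitutionModel, gamma: GammaRates
) -> tuple[np.ndarray, list[str], dict[tuple[str, str], str]]:
    """Symmetric pairwise ML distance matrix over all records.

    Returns (matrix, labels, flags); flags records any pair whose
    estimate was not a clean interior optimum (identical sequences are
    unflagged, with distance 0).
    """
    if aln.nseq < 2:
        raise ValueError("need at least two sequences")
    labels = list(aln.ids)
    n = len(labels)
    D = np.zeros((n, n))
    flags: dict[tuple[str, str], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            est = pairwise_ml_distance(
                aln.sequence(labels[i]), aln.sequence(labels[j]), model, gamma
            )
            D[i, j] = D[j, i] = est.distance
            if est.status == "saturated":
                flags[(labels[i], labels[j])] = est.status
    return D, labels, flags


@dataclass
class DivergenceSummary:
    group_a: str
    group_b: str
    mean: float
    se: float
    n_pairs: int


def mean_clade_divergence(
    aln: Alignment,
    group_a: Sequence[str],
    group_b: Sequence[str],
    model: SubstitutionModel,
    gamma: GammaRates,
    bootstrap_reps: int = 100,
    seed: int | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> DivergenceSummary:
    """Mean pairwise ML distance between two groups, site-bootstrap SE.

    Each bootstrap replicate resamples alignment columns with
    replacement and re-estimates every between-group distance; the SE
    is the standard deviation of the replicate means.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    pairs = [(a, b) for a in group_a for b in group_b]

    def mean_over_pairs(col_idx: np.ndarray | None) -> float:
        vals = []
        for a, b in pairs:
            sa, sb = aln.sequence(a), aln.sequence(b)
            if col_idx is not None:
                sa = "".join(sa[c] for c in col_idx)
                sb = "".join(sb[c] for c in col_idx)
            vals.append(pairwise_ml_distance(sa, sb, model, gamma).distance)
        return float(np.mean(vals))

    point = mean_over_pairs(None)
    se = float("nan")
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        reps = [
            mean_over_pairs(rng.integers(0, aln.length, size=aln.length))
            for _ in range(bootstrap_reps)
        ]
        se = float(np.std(reps, ddof=1))
    return DivergenceSummary(
        group_a=label_a, group_b=label_b, mean=point, se=se, n_pairs=len(pairs)
    )


def neighbor_joining(matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Neighbor-joining tree (newick) from a symmetric distance matrix.

    Negative branch lengths are clamped to zero. NaN entries are
    rejected.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    matrix = np.asarray(matrix, dtype=float)
    if np.isnan(matrix).any():
        raise ValueError("distance matrix contains NaN entries")
    if matrix.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = DistanceMatrix(matrix, ids=list(labels))
    tree = nj(dm, neg_as_zero=True)
    return str(tree).strip()
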