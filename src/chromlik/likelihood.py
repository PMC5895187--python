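"""Pruning likelihood for discrete-state models on phylogenies.

The probability of the tip observations given a tree and a generator Q is
computed with Felsenstein's pruning recursion: each tip carries a 0/1
conditioning vector, each internal node the elementwise product over its
children of ``P(t_child) @ child_partial`` with ``P(t) = exp(Q t)``, and the
root sums the final partial against a root prior.  Partials are rescaled by
their maximum at every node, with the log factors accumulated, so trees
with thousands of tips do not underflow.

Matrix exponentials dominate the cost: one per *unique* branch length per
parameter evaluation.  They are computed from a single eigendecomposition of
Q (one ``eig`` plus two small matrix products per branch), verified against
the row-stochasticity invariant, with a fall back to scaling-and-squaring
(`scipy.linalg.expm`) per branch whenever the spectral route loses accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .errors import DataError, InvalidArgumentError, ModelDefinitionError
from .models import RateMatrix
from .statespace import StateSpace
from .treeio import Phylogeny, TipObservations, observation_to_vector

__all__ = ["RootPrior", "NegLogLik", "ZeroLikelihoodWarning",
           "transition_probabilities", "stationary_distribution", "negloglik"]


class ZeroLikelihoodWarning(UserWarning):
    """The data have probability zero under the supplied model."""


# ---------------------------------------------------------------------------
# Root prior
# ---------------------------------------------------------------------------

def stationary_distribution(Q: np.ndarray | RateMatrix) -> np.ndarray:
    """Stationary distribution pi of a generator: pi Q = 0, sum(pi) = 1."""
    Qd = Q.dense() if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    n = Qd.shape[0]
    # Least squares on [Q^T; 1] x = [0; 1]: robust to the rank-deficiency.
    A = np.vstack([Qd.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    total = pi.sum()
    if total <= 0:
        raise ModelDefinitionError("stationary distribution is degenerate")
    return pi / total


@dataclass(frozen=True)
class RootPrior:
    """Distribution over states at the root.

    ``mode`` is one of ``uniform`` (default for all inference in this
    package), ``stationary`` (of the current Q) or ``custom`` with an
    explicit probability vector.
    """

    mode: str = "uniform"
    vector: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("uniform", "stationary", "custom"):
            raise InvalidArgumentError(f"unknown root prior mode {self.mode!r}")
        if self.mode == "custom":
            if self.vector is None:
                raise InvalidArgumentError("custom root prior needs a vector")
            v = np.asarray(self.vector, dtype=float)
            if v.min() < 0 or abs(v.sum() - 1.0) > 1e-12:
                raise InvalidArgumentError(
                    "custom root prior must be nonnegative and sum to 1 "
                    "within 1e-12")
            object.__setattr__(self, "vector", v)

    @classmethod
    def uniform(cls) -> "RootPrior":
        return cls("uniform")

    @classmethod
    def stationary(cls) -> "RootPrior":
        return cls("stationary")

    @classmethod
    def custom(cls, vector: Sequence[float]) -> "RootPrior":
        return cls("custom", np.asarray(vector, dtype=float))

    def probabilities(self, Q: np.ndarray, n_states: int) -> np.ndarray:
        if self.mode == "uniform":
            return np.full(n_states, 1.0 / n_states)
        if self.mode == "stationary":
            return stationary_distribution(Q)
        assert self.vector is not None
        if len(self.vector) != n_states:
            raise InvalidArgumentError(
                f"root prior has {len(self.vector)} entries for {n_states} states")
        return self.vector


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

_ROW_SUM_TOL = 1e-10


def transition_probabilities(Q: RateMatrix | np.ndarray, t: float) -> np.ndarray:
    """Row-stochastic matrix ``P = exp(Q t)`` for a branch of length ``t``."""
    if t < 0:
        raise InvalidArgumentError(f"branch length must be >= 0, got {t}")
    Qd = Q.dense() if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    n = Qd.shape[0]
    if t == 0:
        return np.eye(n)
    P = scipy.linalg.expm(Qd * t)
    if not np.all(np.isfinite(P)):
        raise ArithmeticError("non-finite entries in exp(Qt)")
    row_err = np.abs(P.sum(axis=1) - 1.0).max()
    if row_err > _ROW_SUM_TOL:
        raise ArithmeticError(
            f"exp(Qt) rows deviate from stochasticity by {row_err:.3e}")
    return np.clip(P, 0.0, 1.0)


class _Propagator:
    """Apply exp(Q t) to vectors from one eigendecomposition of Q.

    The pruning recursion only ever needs ``P(t) @ v``, so on the fast path
    the full transition matrix is never formed: each application costs two
    small matrix-vector products against the (cached) eigenvector factors.
    The decomposition is verified per evaluation by reconstructing P at the
    longest and shortest branch lengths and checking row-stochasticity; if
    the spectral route loses accuracy (nearly defective Q), the engine falls
    back to dense scaling-and-squaring per unique branch length.

    The spectral route carries an *absolute* error around machine epsilon
    times the conditioning of the eigenvector basis, so very small
    transition probabilities lose relative accuracy.  That is harmless
    inside an optimizer but not for reference likelihood values, which is
    why the engine's default route is scaling-and-squaring.
    """

    def __init__(self, Qd: np.ndarray):
        self.Q = Qd
        self.n = Qd.shape[0]
        self._spectral = None
        self._ew: dict[float, np.ndarray] = {}
        try:
            w, V = scipy.linalg.eig(Qd)
            Vinv = np.linalg.inv(V)
            if np.isfinite(w).all() and np.isfinite(Vinv).all():
                self._spectral = (w, V, Vinv)
        except np.linalg.LinAlgError:
            pass

    def spectral_ok(self, check_ts, tol: float) -> bool:
        """Reconstruct P at the given lengths and test stochasticity."""
        if self._spectral is None:
            return False
        w, V, Vinv = self._spectral
        for t in check_ts:
            P = np.real((V * np.exp(w * t)) @ Vinv)
            if (np.abs(P.sum(axis=1) - 1.0).max() > tol
                    or P.min() < -tol):
                return False
        return True

    def apply(self, t: float, v: np.ndarray) -> np.ndarray:
        """``exp(Q t) @ v`` via the spectral factors, clipped nonnegative."""
        w, V, Vinv = self._spectral
        ew = self._ew.get(t)
        if ew is None:
            ew = self._ew[t] = np.exp(w * t)
        return np.clip(np.real(V @ (ew * (Vinv @ v))), 0.0, None)

    def apply_batch(self, ts: np.ndarray, U: np.ndarray) -> np.ndarray:
        """Columnwise ``exp(Q ts[j]) @ U[:, j]`` in two batched products."""
        w, V, Vinv = self._spectral
        W = (Vinv @ U) * np.exp(np.multiply.outer(w, ts))
        return np.clip(np.real(V @ W), 0.0, None)


class _Uniformizer:
    """``exp(Q t) @ v`` by uniformization (Jensen's method).

    With uniformization rate Lambda = max exit rate, ``exp(Qt) v`` is the
    Poisson-weighted sum over k of ``M^k v`` with the stochastic matrix
    ``M = I + Q/Lambda``.  Every operation involves only nonnegative
    numbers, so small transition probabilities keep full relative accuracy
    — this is the method of choice when Q is defective (e.g. near-zero
    loss and doubling rates turn a trait block into a pure birth chain,
    one giant Jordan block) and the spectral route breaks down.  Cost
    scales with Lambda * t, so stiff parameter proposals are routed to
    scaling-and-squaring instead.
    """

    #: Poisson tail truncation: terms beyond a + 10 sqrt(a) + 20 are < 1e-13.
    @staticmethod
    def n_terms(a: float) -> float:
        return a + 10.0 * np.sqrt(a) + 20.0

    def __init__(self, Qd: np.ndarray):
        self.lam = float(max(-np.diag(Qd).min(), 0.0))
        n = Qd.shape[0]
        self.M = (np.eye(n) + Qd / self.lam) if self.lam > 0 else np.eye(n)

    def apply(self, t: float, v: np.ndarray) -> np.ndarray:
        a = self.lam * t
        if a == 0.0:
            return v
        k_max = int(self.n_terms(a))
        weight = np.exp(-a)
        acc = weight * v
        vk = v
        for k in range(1, k_max + 1):
            vk = self.M @ vk
            weight *= a / k
            acc += weight * vk
            if k > a and weight < 1e-16:
                break
        return acc

    def apply_batch(self, ts: np.ndarray, U: np.ndarray) -> np.ndarray:
        """Columnwise ``exp(Q ts[j]) @ U[:, j]``, one shared power series."""
        a = self.lam * np.asarray(ts, dtype=float)
        a_max = float(a.max(initial=0.0))
        if a_max == 0.0:
            return U.copy()
        k_max = int(self.n_terms(a_max))
        weight = np.exp(-a)
        acc = U * weight
        Uk = U
        for k in range(1, k_max + 1):
            Uk = self.M @ Uk
            weight = weight * (a / k)
            acc += Uk * weight
            if k > a_max and weight.max() < 1e-16:
                break
        return acc



# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

@dataclass
class NegLogLik:
    """Negative log-likelihood with evaluation metadata."""

    value: float
    expm_calls: int = 0
    cache_hits: int = 0

    def __float__(self) -> float:
        return float(self.value)


def _unique_length_key(t: float) -> float:
    """Cache key: branch length rounded to 12 significant digits."""
    return float(f"{t:.12g}")


def _level_schedule(tree: Phylogeny):
    """Group internal nodes into levels whose children are all resolved.

    Level L holds the internal nodes whose deepest child subtree has height
    L - 1, so processing levels in increasing order lets every level's
    child partials be propagated in one batched operation.  The schedule
    depends only on topology and is cached on the tree.
    """
    cached = getattr(tree, "_pruning_schedule", None)
    if cached is not None:
        return cached
    level = np.zeros(tree.n_nodes, dtype=np.int64)
    for i in range(tree.n_nodes):  # postorder: children before parents
        if tree.children[i]:
            level[i] = 1 + max(level[c] for c in tree.children[i])
    schedule = []
    for L in range(1, int(level.max()) + 1):
        parents = [i for i in range(tree.n_nodes)
                   if level[i] == L and tree.children[i]]
        child_idx = [c for p in parents for c in tree.children[p]]
        counts = [len(tree.children[p]) for p in parents]
        schedule.append((parents, np.array(child_idx, dtype=np.int64), counts))
    tree._pruning_schedule = schedule
    return schedule


def _tip_vectors(tree: Phylogeny, data: TipObservations,
                 space: StateSpace) -> dict[int, np.ndarray]:
    """Conditioning vectors for every tip, cached on the observations."""
    items = tuple(sorted(data.observations.items()))
    cached = getattr(data, "_tip_vector_cache", None)
    if cached is not None:
        key, vectors = cached
        if key == (id(tree), id(space), items):
            return vectors
    vectors = {i: observation_to_vector(data[label], space, taxon=label)
               for i, label in tree.tip_label.items()}
    data._tip_vector_cache = ((id(tree), id(space), items), vectors)
    return vectors


#: Stochasticity tolerance for the fast spectral route; its absolute error
#: is orders of magnitude below any optimizer stopping tolerance.
_SPECTRAL_TOL = 1e-6


def negloglik(tree: Phylogeny, data: TipObservations,
              builder: Callable[[np.ndarray, StateSpace], RateMatrix],
              log_params: Sequence[float], space: StateSpace,
              root: RootPrior | None = None, *, scale: bool = True,
              method: str = "expm") -> NegLogLik:
    """Negative log-likelihood of tip observations under a Q-builder.

    ``log_params`` are natural-log rates; they are exponentiated before the
    builder is called, which both enforces positivity and matches the
    optimizer's parameterization.  The builder's output is validated (row
    sums, nonnegative off-diagonals) before use, so arbitrary user-supplied
    builders are safe to pass.

    ``method`` selects the branch propagation route.  ``"expm"`` (default)
    computes one scaling-and-squaring exponential per unique branch length
    and is the reference-accuracy path.  ``"fast"`` never forms transition
    matrices: it propagates partial vectors through a single
    eigendecomposition of Q when that is well conditioned, switches to
    uniformization when Q is (near-)defective but the event rates are
    moderate, and falls back to ``"expm"`` for stiff proposals — an order
    of magnitude faster on large trees, with absolute error well below
    1e-6.  Optimization uses ``"fast"``; reported likelihood values use
    the default.

    Set ``scale=False`` only to demonstrate underflow; all inference uses
    the rescaled recursion.
    """
    if method not in ("expm", "fast", "spectral"):
        raise InvalidArgumentError(f"unknown propagation method {method!r}")
    tips = set(tree.tip_labels)
    taxa = data.taxa
    if tips != taxa:
        missing = sorted(tips - taxa)[:5]
        extra = sorted(taxa - tips)[:5]
        raise DataError(
            f"tree tips and data taxa differ (tips without data: {missing}, "
            f"data without tips: {extra})")

    theta = np.exp(np.asarray(log_params, dtype=float))
    rate_matrix = builder(theta, space)
    if not isinstance(rate_matrix, RateMatrix):
        raise ModelDefinitionError(
            "builder must return a RateMatrix, got "
            f"{type(rate_matrix).__name__}")
    rate_matrix.validate(tol=1e-9)
    Qd = rate_matrix.dense()
    n = space.n_states

    # One propagator solve per unique branch length (root edge excluded).
    branch_nodes = [i for i in range(tree.n_nodes) if i != tree.root]
    keys = [_unique_length_key(tree.edge_length[i]) for i in branch_nodes]
    unique = sorted(set(keys))
    nonzero = [k for k in unique if k > 0.0]
    route = "expm"
    prop = None
    if method in ("fast", "spectral") and nonzero:
        prop = _Propagator(Qd)
        if prop.spectral_ok((nonzero[-1], nonzero[0]), _SPECTRAL_TOL):
            route = "spectral"
        else:
            uni = _Uniformizer(Qd)
            total_terms = sum(
                uni.n_terms(uni.lam * tree.edge_length[i])
                for i in branch_nodes)
            if uni.lam * nonzero[-1] < 600 and total_terms < 50_000:
                prop, route = uni, "uniformization"
    P_cache: dict[float, np.ndarray] = {}
    if route == "expm" and nonzero:
        # One stacked scaling-and-squaring call for all unique lengths.
        stack = scipy.linalg.expm(
            Qd[None, :, :] * np.asarray(nonzero)[:, None, None])
        if not np.all(np.isfinite(stack)):
            raise ArithmeticError("non-finite entries in exp(Qt)")
        stack = np.clip(stack, 0.0, 1.0)
        P_cache = {k: stack[j] for j, k in enumerate(nonzero)}
    # One solve per unique nonzero length; repeats are cache hits and
    # zero-length branches are served by the identity without a solve.
    expm_calls = len(nonzero)
    cache_hits = len(keys) - len(unique)

    prior = (root or RootPrior.uniform()).probabilities(Qd, n)
    log_rescale = 0.0
    partial = np.empty((tree.n_nodes, n))
    for i, vec in _tip_vectors(tree, data, space).items():
        partial[i] = vec

    # Level-batched pruning: propagate all child partials of a level in one
    # batched operation, then combine per parent.
    for parents, child_idx, counts in _level_schedule(tree):
        ts = tree.edge_length[child_idx]
        U = partial[child_idx].T
        if route == "expm":
            Y = np.empty_like(U)
            for j, c in enumerate(child_idx):
                t = _unique_length_key(tree.edge_length[c])
                Y[:, j] = U[:, j] if t == 0.0 else P_cache[t] @ U[:, j]
        else:
            Y = prop.apply_batch(ts, U)
        pos = 0
        for p, cnt in zip(parents, counts):
            acc = Y[:, pos]
            for j in range(1, cnt):
                acc = acc * Y[:, pos + j]
            pos += cnt
            m = acc.max()
            if m <= 0.0:
                warnings.warn(
                    f"zero partial likelihood at internal node {p}; the data "
                    "have probability 0 under this model",
                    ZeroLikelihoodWarning, stacklevel=2)
                return NegLogLik(np.inf, expm_calls, cache_hits)
            if scale:
                acc = acc / m
                log_rescale += np.log(m)
            partial[p] = acc

    lik = float(prior @ partial[tree.root])
    if lik <= 0.0 or not np.isfinite(lik):
        warnings.warn(
            "zero likelihood at the root; the data have probability 0 "
            "under this model", ZeroLikelihoodWarning, stacklevel=2)
        return NegLogLik(np.inf, expm_calls, cache_hits)
    return NegLogLik(-(np.log(lik) + log_rescale), expm_calls, cache_hits)
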