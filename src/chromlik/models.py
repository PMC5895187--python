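"""Infinitesimal rate matrices (Q) for chromosome-number evolution models.

Each builder maps a parameter set onto a sparse generator over a
:class:`~chromlik.statespace.StateSpace`.  Off-diagonal entries are
instantaneous event rates; the diagonal closes every row to zero, the
defining property of a continuous-time Markov chain generator.  Multiple
events sharing a source/target cell accumulate additively (competing
exponentials), e.g. from count 1 a single gain and a doubling both land on
count 2, so that cell carries ``lambda + rho``.

Models
------
``bichrom``
    Ten-parameter trait-linked model: chromosome gain (lambda0, lambda1),
    loss (mu0, mu1), doubling (rho0, rho1), binary-trait transitions
    (q01, q10) and trait transitions in the LARGE catch-all states
    (eps0, eps1).
``bichrom_reduced``
    The nested null model with a single shared doubling rate rho.
``chromevol_m3``
    Single-trait model with constant gain, loss, doubling and demiploidy
    (1.5x) rates.
``solanum`` / ``solanum_reduced``
    Six- (five-) parameter doubling/demiploidy model on the enumerated
    space {12,18,24,36,48} x {herbaceous, woody}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import InvalidArgumentError, ModelDefinitionError
from .statespace import (LARGE, SOLANUM_COUNTS, StateSpace, build_state_space,
                         solanum_state_space)

#: Absolute tolerance on generator row sums.
ROW_SUM_TOL = 1e-12


# ---------------------------------------------------------------------------
# Rate matrix container
# ---------------------------------------------------------------------------

class RateMatrix:
    """Sparse infinitesimal generator over a state space.

    Only structurally allowed transitions are stored; the diagonal is the
    negated off-diagonal row sum.  Use :meth:`dense` for numerical work
    (state spaces here are small, ~10-100 states).
    """

    def __init__(self, space: StateSpace, matrix: sp.spmatrix):
        self.space = space
        self.matrix = sp.csr_matrix(matrix)
        if self.matrix.shape != (space.n_states, space.n_states):
            raise ModelDefinitionError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{space.n_states} states")

    @property
    def n_states(self) -> int:
        return self.space.n_states

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def n_transitions(self) -> int:
        """Number of stored off-diagonal entries (the sparsity budget)."""
        coo = self.matrix.tocoo()
        return int(np.sum(coo.row != coo.col))

    def __getitem__(self, key) -> float:
        i, j = key
        return float(self.matrix[i, j])

    def rate(self, source, target) -> float:
        """Rate of the transition ``source -> target`` given as states."""
        return self[self.space.index_of(*source), self.space.index_of(*target)]

    def validate(self, tol: float = ROW_SUM_TOL) -> None:
        """Raise :class:`ModelDefinitionError` on an invalid generator."""
        dense = self.dense()
        if not np.all(np.isfinite(dense)):
            bad = int(np.argwhere(~np.isfinite(dense))[0, 0])
            raise ModelDefinitionError(f"non-finite entry in row {bad}")
        off = dense - np.diag(np.diag(dense))
        if off.min() < 0:
            bad = int(np.argwhere(off < 0)[0, 0])
            raise ModelDefinitionError(
                f"negative off-diagonal rate in row {bad} "
                f"(state {self.space.states[bad]!r})")
        sums = dense.sum(axis=1)
        worst = int(np.argmax(np.abs(sums)))
        if abs(sums[worst]) > tol:
            raise ModelDefinitionError(
                f"row {worst} (state {self.space.states[worst]!r}) sums to "
                f"{sums[worst]:.3e}, expected 0 within {tol:g}")

    def __repr__(self) -> str:
        return (f"RateMatrix(n_states={self.n_states}, "
                f"n_transitions={self.n_transitions()})")


def _assemble(space: StateSpace, entries: Mapping[tuple[int, int], float]) -> RateMatrix:
    """Build a RateMatrix from accumulated off-diagonal entries."""
    n = space.n_states
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for (i, j), r in entries.items():
        if i == j or r == 0.0:
            continue
        rows.append(i)
        cols.append(j)
        vals.append(r)
        diag[i] -= r
    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return RateMatrix(space, mat)


def _check_rates(**rates: float) -> None:
    for name, value in rates.items():
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            raise InvalidArgumentError(f"rate {name} must be finite, got {value!r}")
        if value < 0:
            raise InvalidArgumentError(f"rate {name} must be >= 0, got {value!r}")


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

class _RateParams:
    """Mixin: validation plus array/dict conversion in field order."""

    def __post_init__(self):
        _check_rates(**{f.name: getattr(self, f.name) for f in fields(self)})

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]):
        values = list(values)
        names = cls.names()
        if len(values) != len(names):
            raise InvalidArgumentError(
                f"{cls.__name__} takes {len(names)} rates, got {len(values)}")
        return cls(*[float(v) for v in values])

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


@dataclass(frozen=True)
class BiChroMParams(_RateParams):
    """Ten rates of the trait-linked BiChroM model (events per unit time)."""

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    rho0: float
    rho1: float
    q01: float
    q10: float
    eps0: float
    eps1: float


@dataclass(frozen=True)
class ReducedBiChroMParams(_RateParams):
    """BiChroM with a single shared doubling rate rho (9 rates)."""

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    rho: float
    q01: float
    q10: float
    eps0: float
    eps1: float

    def expand(self) -> BiChroMParams:
        """The equivalent full-model parameter set with rho0 = rho1 = rho."""
        return BiChroMParams(self.lambda0, self.lambda1, self.mu0, self.mu1,
                             self.rho, self.rho, self.q01, self.q10,
                             self.eps0, self.eps1)


@dataclass(frozen=True)
class SolanumParams(_RateParams):
    """Six rates of the Solanum doubling/demiploidy growth-form model."""

    rhoH: float
    rhoW: float
    epsH: float
    epsW: float
    qHW: float
    qWH: float


@dataclass(frozen=True)
class ReducedSolanumParams(_RateParams):
    """Solanum model with a shared doubling rate rho (5 rates)."""

    rho: float
    epsH: float
    epsW: float
    qHW: float
    qWH: float

    def expand(self) -> SolanumParams:
        return SolanumParams(self.rho, self.rho, self.epsH, self.epsW,
                             self.qHW, self.qWH)


@dataclass(frozen=True)
class ChromEvolParams(_RateParams):
    """Constant-rate single-trait model: gain, loss, doubling, demiploidy."""

    gain: float
    loss: float
    doubling: float
    demiploidy: float


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _require_bichrom_space(space: StateSpace) -> None:
    if len(space.traits) != 2 or not space.has_large or space.c_max is None:
        raise InvalidArgumentError(
            "BiChroM needs a two-trait bounded space with a LARGE state "
            "(see build_state_space)")


def build_q_bichrom(params: BiChroMParams, space: StateSpace) -> RateMatrix:
    """Generator of the full BiChroM model.

    For trait block j with count ``1 <= i <= c_max``: gain ``i -> i+1`` at
    lambda_j (into LARGE_j when i = c_max); loss ``i -> i-1`` at mu_j for
    i >= 2; doubling ``i -> 2i`` at rho_j (into LARGE_j when 2i > c_max);
    trait flip ``(i, j) -> (i, 1-j)`` at q01 or q10.  LARGE states only flip
    trait, at eps_j: once the count has left the explicit range the model
    tracks no further count changes.
    """
    if not isinstance(params, BiChroMParams):
        params = BiChroMParams.from_array(np.asarray(params, dtype=float))
    _require_bichrom_space(space)
    c_max = space.c_max
    t0, t1 = space.traits
    per_trait = {
        t0: (params.lambda0, params.mu0, params.rho0, params.q01, params.eps0, t1),
        t1: (params.lambda1, params.mu1, params.rho1, params.q10, params.eps1, t0),
    }
    entries: dict[tuple[int, int], float] = {}

    def add(src: int, dst: int, rate: float) -> None:
        if rate > 0.0:
            entries[(src, dst)] = entries.get((src, dst), 0.0) + rate

    for trait, (lam, mu, rho, q_flip, eps, other) in per_trait.items():
        large = space.index_of(LARGE, trait)
        for i in range(1, c_max + 1):
            src = space.index_of(i, trait)
            add(src, space.index_of(i + 1, trait) if i < c_max else large, lam)
            if i >= 2:
                add(src, space.index_of(i - 1, trait), mu)
            add(src, space.index_of(2 * i, trait) if 2 * i <= c_max else large, rho)
            add(src, space.index_of(i, other), q_flip)
        add(large, space.index_of(LARGE, other), eps)
    return _assemble(space, entries)


def build_q_bichrom_reduced(params: ReducedBiChroMParams,
                            space: StateSpace) -> RateMatrix:
    """Generator of the reduced BiChroM model (rho0 = rho1 = rho)."""
    if not isinstance(params, ReducedBiChroMParams):
        params = ReducedBiChroMParams.from_array(np.asarray(params, dtype=float))
    return build_q_bichrom(params.expand(), space)


def build_q_solanum(params: SolanumParams,
                    space: StateSpace | None = None) -> RateMatrix:
    """Generator of the Solanum doubling/demiploidy model.

    On the enumerated space {12,18,24,36,48} x {H,W}: doubling 12->24,
    18->36, 24->48 at rho_s; demiploidy (1.5x) 12->18, 24->36 at eps_s;
    growth-form flips at qHW / qWH for every count.  Transitions whose
    arithmetic target (27, 54, 72, 96) falls outside the observed count set
    are absent: the model is restricted to the counts that occur in the
    data.
    """
    if not isinstance(params, SolanumParams):
        params = SolanumParams.from_array(np.asarray(params, dtype=float))
    if space is None:
        space = solanum_state_space()
    if set(space.traits) != {"H", "W"} or space.counts != SOLANUM_COUNTS:
        raise InvalidArgumentError(
            "the Solanum builder needs the {12,18,24,36,48} x {H,W} space")
    count_set = set(space.counts)
    per_trait = {
        "H": (params.rhoH, params.epsH, "W", params.qHW),
        "W": (params.rhoW, params.epsW, "H", params.qWH),
    }
    entries: dict[tuple[int, int], float] = {}

    def add(src: int, dst: int, rate: float) -> None:
        if rate > 0.0:
            entries[(src, dst)] = entries.get((src, dst), 0.0) + rate

    for trait, (rho, eps, other, q_flip) in per_trait.items():
        for c in space.counts:
            src = space.index_of(c, trait)
            if 2 * c in count_set:
                add(src, space.index_of(2 * c, trait), rho)
            demi = c + c // 2  # exact 1.5x (all observed counts are even)
            if demi in count_set:
                add(src, space.index_of(demi, trait), eps)
            add(src, space.index_of(c, other), q_flip)
    return _assemble(space, entries)


def build_q_solanum_reduced(params: ReducedSolanumParams,
                            space: StateSpace | None = None) -> RateMatrix:
    """Solanum generator with a shared doubling rate (rhoH = rhoW = rho)."""
    if not isinstance(params, ReducedSolanumParams):
        params = ReducedSolanumParams.from_array(np.asarray(params, dtype=float))
    return build_q_solanum(params.expand(), space)


def build_q_chromevol(params: ChromEvolParams, space: StateSpace) -> RateMatrix:
    """Generator of the constant-rate single-trait model.

    Gain ``i -> i+1``, loss ``i -> i-1``, doubling ``i -> 2i`` (into LARGE on
    overflow) and demiploidy ``i -> 1.5i``.  For odd counts 1.5i is not an
    integer; the demiploidy rate is split equally between floor(1.5i) and
    ceil(1.5i).  Demiploidy targets above c_max overflow to LARGE; a
    demiploidy half-rate whose target equals the source (count 1, floor
    target 1) is dropped as a non-event.
    """
    if not isinstance(params, ChromEvolParams):
        params = ChromEvolParams.from_array(np.asarray(params, dtype=float))
    if len(space.traits) != 1 or not space.has_large or space.c_max is None:
        raise InvalidArgumentError(
            "the ChromEvol-style builder needs a one-trait bounded space")
    c_max = space.c_max
    (trait,) = space.traits
    large = space.index_of(LARGE, trait)
    entries: dict[tuple[int, int], float] = {}

    def add(src: int, target_count: int, rate: float) -> None:
        if rate <= 0.0 or target_count == 0:
            return
        dst = (space.index_of(target_count, trait)
               if target_count <= c_max else large)
        if dst != src:
            entries[(src, dst)] = entries.get((src, dst), 0.0) + rate

    for i in range(1, c_max + 1):
        src = space.index_of(i, trait)
        add(src, i + 1, params.gain)
        if i >= 2:
            add(src, i - 1, params.loss)
        add(src, 2 * i, params.doubling)
        if i % 2 == 0:
            add(src, 3 * i // 2, params.demiploidy)
        else:
            add(src, (3 * i) // 2, params.demiploidy / 2.0)
            add(src, (3 * i) // 2 + 1, params.demiploidy / 2.0)
    return _assemble(space, entries)


# ---------------------------------------------------------------------------
# Model registry: vector-parameterized builders for the likelihood engine
# ---------------------------------------------------------------------------

QBuilder = Callable[[np.ndarray, StateSpace], RateMatrix]


@dataclass(frozen=True)
class Model:
    """A named model: parameter order, Q-builder and default state space."""

    name: str
    param_names: tuple[str, ...]
    build: QBuilder
    space_factory: Callable[..., StateSpace]
    reduced_of: str | None = None  # full model this one nests inside

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def default_space(self, c_max: int = 25) -> StateSpace:
        return self.space_factory(c_max)


def _space_bichrom(c_max: int) -> StateSpace:
    return build_state_space(c_max, (0, 1))


def _space_single(c_max: int) -> StateSpace:
    return build_state_space(c_max, ("x",))


def _space_solanum(c_max: int = 25) -> StateSpace:  # c_max ignored: enumerated
    return solanum_state_space()


MODELS: dict[str, Model] = {
    "bichrom": Model(
        "bichrom", BiChroMParams.names(),
        lambda theta, space: build_q_bichrom(BiChroMParams.from_array(theta), space),
        _space_bichrom),
    "bichrom_reduced": Model(
        "bichrom_reduced", ReducedBiChroMParams.names(),
        lambda theta, space: build_q_bichrom_reduced(
            ReducedBiChroMParams.from_array(theta), space),
        _space_bichrom, reduced_of="bichrom"),
    "chromevol_m3": Model(
        "chromevol_m3", ChromEvolParams.names(),
        lambda theta, space: build_q_chromevol(ChromEvolParams.from_array(theta), space),
        _space_single),
    "solanum": Model(
        "solanum", SolanumParams.names(),
        lambda theta, space: build_q_solanum(SolanumParams.from_array(theta), space),
        _space_solanum),
    "solanum_reduced": Model(
        "solanum_reduced", ReducedSolanumParams.names(),
        lambda theta, space: build_q_solanum_reduced(
            ReducedSolanumParams.from_array(theta), space),
        _space_solanum, reduced_of="solanum"),
}


def get_model(name: str) -> Model:
    try:
        return MODELS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown model {name!r}; available: {sorted(MODELS)}") from None
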