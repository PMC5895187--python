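"""State spaces for chromosome-number Markov models.

A state is a pair ``(count, trait)`` where ``count`` is a positive haploid
chromosome number or the :data:`LARGE` sentinel (a catch-all for counts above
the explicit maximum ``c_max``), and ``trait`` is a categorical label such as
``0``/``1`` or ``"H"``/``"W"``.

Two families of spaces exist:

* *bounded* spaces enumerate counts ``1..c_max`` plus one LARGE state per
  trait (used by the BiChroM and ChromEvol-style models);
* *enumerated* spaces list an explicit set of observed counts with no LARGE
  state (used by the Solanum model).

State ordering is fixed and documented: the block for the first trait
(counts ascending, then LARGE if present), then the block for the second
trait.  All semantics go through :meth:`StateSpace.index_of`, so the ordering
is an implementation detail that downstream code must never assume.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence, Tuple, Union

from .errors import InvalidArgumentError


class _LargeSentinel:
    """Singleton marker for 'more chromosomes than the explicit maximum'."""

    _instance = None

    def __new__(cls) -> "_LargeSentinel":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "LARGE"

    def __reduce__(self):
        return (_LargeSentinel, ())


#: Catch-all count category for counts exceeding ``c_max``.
LARGE = _LargeSentinel()

Count = Union[int, _LargeSentinel]
State = Tuple[Count, object]


class StateSpace:
    """Ordered set of ``(count, trait)`` states with a bijective index.

    Parameters
    ----------
    states
        Ordered iterable of ``(count, trait)`` pairs; counts are positive
        integers or :data:`LARGE`.
    traits
        Ordered trait labels (length 1 or 2).
    c_max
        Maximum explicit haploid count for bounded spaces; ``None`` for
        enumerated spaces.
    """

    def __init__(self, states: Iterable[State], traits: Sequence[object],
                 c_max: int | None = None):
        self.states: tuple[State, ...] = tuple((c, t) for c, t in states)
        self.traits: tuple[object, ...] = tuple(traits)
        self.c_max = c_max
        if not 1 <= len(self.traits) <= 2:
            raise InvalidArgumentError(
                f"a state space needs 1 or 2 trait labels, got {len(self.traits)}")
        if len(set(self.traits)) != len(self.traits):
            raise InvalidArgumentError("trait labels must be distinct")
        self._index: dict[State, int] = {s: i for i, s in enumerate(self.states)}
        if len(self._index) != len(self.states):
            raise InvalidArgumentError("duplicate states in state space")
        counts: list[int] = []
        for c, _ in self.states:
            if c is not LARGE:
                if not (isinstance(c, int) and c >= 1):
                    raise InvalidArgumentError(f"counts must be positive integers, got {c!r}")
                if c not in counts:
                    counts.append(c)
        self.counts: tuple[int, ...] = tuple(counts)

    # -- mapping ---------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[State]:
        return iter(self.states)

    def index_of(self, count: Count, trait: object) -> int:
        """Return the 0-based index of state ``(count, trait)``.

        Raises :class:`KeyError` if the state is not in the space.
        """
        return self._index[(count, trait)]

    def __contains__(self, state: State) -> bool:
        return state in self._index

    @property
    def has_large(self) -> bool:
        return any(c is LARGE for c, _ in self.states)

    def states_of_trait(self, trait: object) -> list[int]:
        """Indices of every state carrying ``trait``, in state order."""
        return [i for i, (_, t) in enumerate(self.states) if t == trait]

    def __repr__(self) -> str:
        kind = f"c_max={self.c_max}" if self.c_max is not None else "enumerated"
        return (f"StateSpace(n_states={self.n_states}, traits={self.traits!r}, "
                f"{kind})")

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, StateSpace) and self.states == other.states
                and self.traits == other.traits and self.c_max == other.c_max)

    def __hash__(self) -> int:
        return hash((self.states, self.traits, self.c_max))


def build_state_space(c_max: int, traits: Sequence[object]) -> StateSpace:
    """Build a bounded space with counts ``1..c_max`` plus LARGE per trait.

    For two traits this yields ``2 * (c_max + 1)`` states; for one trait
    ``c_max + 1``.  Ordering: first-trait block (counts ascending, then
    LARGE), then the second-trait block.
    """
    if not isinstance(c_max, int) or isinstance(c_max, bool) or c_max < 2:
        raise InvalidArgumentError(f"c_max must be an integer >= 2, got {c_max!r}")
    traits = tuple(traits)
    if not 1 <= len(traits) <= 2:
        raise InvalidArgumentError(
            f"expected 1 or 2 trait labels, got {len(traits)}")
    states: list[State] = []
    for t in traits:
        states.extend((c, t) for c in range(1, c_max + 1))
        states.append((LARGE, t))
    return StateSpace(states, traits, c_max=c_max)


def enumerated_state_space(counts: Sequence[int], traits: Sequence[object]) -> StateSpace:
    """Build a space from an explicit count list with no LARGE state."""
    counts = tuple(counts)
    if len(counts) < 2:
        raise InvalidArgumentError("an enumerated space needs at least 2 counts")
    if len(set(counts)) != len(counts):
        raise InvalidArgumentError("counts must be distinct")
    traits = tuple(traits)
    states: list[State] = []
    for t in traits:
        states.extend((c, t) for c in counts)
    return StateSpace(states, traits, c_max=None)


#: Haploid counts observed in the Solanum growth-form data set.
SOLANUM_COUNTS: tuple[int, ...] = (12, 18, 24, 36, 48)
#: Growth-form labels: herbaceous, woody.
SOLANUM_TRAITS: tuple[str, str] = ("H", "W")


def solanum_state_space() -> StateSpace:
    """The 10-state space {12,18,24,36,48} x {H,W} for the Solanum model."""
    return enumerated_state_space(SOLANUM_COUNTS, SOLANUM_TRAITS)
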