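"""Phylogeny and tip-observation I/O.

Newick parsing and serialization are delegated to :mod:`dendropy`; this
module wraps the parsed tree in an array-indexed structure suited to fast
post-order likelihood passes, and handles the observation side: delimited
tip tables, the woody/largest-count coding rules for raw multi-valued
records, and the conversion of a (count, trait) observation into a 0/1
state-likelihood vector over a model's state space.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgumentError, NewickParseError
from .statespace import LARGE, StateSpace


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """Rooted tree with branch lengths, indexed for post-order traversal.

    Nodes are integer-indexed in post-order (every child precedes its
    parent; the root is last).  ``edge_length[i]`` is the length of the edge
    above node ``i`` (0.0 for the root).
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        nodes = list(dtree.postorder_node_iter())
        self._nodes = nodes
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.edge_length = np.zeros(n, dtype=float)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.tip_label: dict[int, str] = {}
        root = dtree.seed_node
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                if nd.edge.length is None:
                    raise NewickParseError(
                        "missing branch length on an edge below the root "
                        f"(node {nd.taxon.label if nd.taxon else '<internal>'!r})")
                length = float(nd.edge.length)
                if not np.isfinite(length) or length < 0:
                    raise InvalidArgumentError(
                        f"branch lengths must be finite and >= 0, got {length}")
                self.edge_length[i] = length
            else:
                self.edge_length[i] = float(nd.edge.length or 0.0)
            if nd.is_leaf():
                if nd.taxon is None or not (nd.taxon.label or "").strip():
                    raise NewickParseError("every tip must carry a nonempty label")
                self.tip_label[i] = nd.taxon.label
        self.root = index[id(root)]
        self.postorder = np.arange(n, dtype=np.int64)
        labels = list(self.tip_label.values())
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickParseError(f"duplicate tip labels: {dup}")

    # -- basic queries ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_label)

    @property
    def tip_labels(self) -> list[str]:
        return [self.tip_label[i] for i in sorted(self.tip_label)]

    def is_tip(self, i: int) -> bool:
        return i in self.tip_label

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root edge excluded)."""
        depth = np.zeros(self.n_nodes)
        for i in reversed(range(self.n_nodes)):  # preorder: root first
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.edge_length[i]
        return depth

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        depths = self.node_depths()
        return float(max(depths[i] for i in self.tip_label))

    def preorder(self) -> Iterator[int]:
        return iter(reversed(range(self.n_nodes)))

    # -- construction / serialization -----------------------------------
    @classmethod
    def from_newick(cls, source: str | os.PathLike) -> "Phylogeny":
        return read_newick(source)

    def to_newick(self) -> str:
        return write_newick(self)

    def scaled(self, factor: float) -> "Phylogeny":
        """A copy with every branch length multiplied by ``factor``."""
        if not np.isfinite(factor) or factor <= 0:
            raise InvalidArgumentError(f"scale factor must be > 0, got {factor}")
        clone = self._dtree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Phylogeny(clone)

    def __repr__(self) -> str:
        return f"Phylogeny(n_tips={self.n_tips}, height={self.height:.4g})"


def read_newick(source: str | os.PathLike,
                normalize_underscores: bool = False) -> Phylogeny:
    """Parse a Newick string or file into a :class:`Phylogeny`.

    Quoted labels and polytomies are accepted; unlabeled internal nodes are
    tolerated.  Underscores in labels are kept verbatim unless
    ``normalize_underscores`` converts them to spaces (the classic Newick
    convention).
    """
    if isinstance(source, os.PathLike) or (
            isinstance(source, str) and "(" not in source and os.path.exists(source)):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            preserve_underscores=not normalize_underscores,
            suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return Phylogeny(dtree)


def write_newick(tree: Phylogeny) -> str:
    """Serialize with branch lengths; labels containing spaces are quoted."""
    text = tree._dtree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
        preserve_spaces=True, real_value_format_specifier=".12g")
    return text.strip() + "\n"


# ---------------------------------------------------------------------------
# Tip observations
# ---------------------------------------------------------------------------

@dataclass
class TipObservations:
    """Mapping taxon -> (haploid count or None, trait label or None)."""

    observations: dict[str, tuple[int | None, object | None]] = field(
        default_factory=dict)

    def __post_init__(self):
        for taxon, (count, _) in self.observations.items():
            if count is not None and (not isinstance(count, int) or count < 1):
                raise DataError(
                    f"count for taxon {taxon!r} must be a positive integer, "
                    f"got {count!r}")

    def __getitem__(self, taxon: str) -> tuple[int | None, object | None]:
        return self.observations[taxon]

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def items(self):
        return self.observations.items()

    @property
    def taxa(self) -> set[str]:
        return set(self.observations)

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, c, tr) for t, (c, tr) in self.observations.items()]
        frame = pd.DataFrame(rows, columns=["taxon", "count", "trait"])
        frame["count"] = frame["count"].astype("Int64")  # keep ints, allow NA
        return frame

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def _clean_cell(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    return text or None


def read_tip_table(path: str | os.PathLike, count_column: str = "count",
                   trait_column: str = "trait", taxon_column: str = "taxon",
                   delimiter: str = ",") -> TipObservations:
    """Read a delimited tip table (header row, one row per taxon).

    Empty cells become missing observations; duplicate taxa and nonpositive
    counts are errors.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in (taxon_column, count_column, trait_column):
        if col not in df.columns:
            raise DataError(f"column {col!r} not found in {path}")
    obs: dict[str, tuple[int | None, object | None]] = {}
    for _, row in df.iterrows():
        taxon = _clean_cell(row[taxon_column])
        if taxon is None:
            raise DataError("blank taxon name in tip table")
        if taxon in obs:
            raise DataError(f"duplicate taxon {taxon!r} in tip table")
        raw_count = _clean_cell(row[count_column])
        if raw_count is None:
            count = None
        else:
            try:
                count = int(raw_count)
            except ValueError:
                raise DataError(
                    f"count for taxon {taxon!r} is not an integer: {raw_count!r}")
            if count < 1:
                raise DataError(
                    f"count for taxon {taxon!r} must be >= 1, got {count}")
        trait = _clean_cell(row[trait_column])
        obs[taxon] = (count, trait)
    return TipObservations(obs)


def read_multivalue_table(path: str | os.PathLike, count_column: str = "counts",
                          trait_column: str = "forms", taxon_column: str = "taxon",
                          delimiter: str = ",", value_sep: str = ";"
                          ) -> dict[str, tuple[list[int], list[str]]]:
    """Read a raw table whose cells hold semicolon-separated value lists."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    raw: dict[str, tuple[list[int], list[str]]] = {}
    for _, row in df.iterrows():
        taxon = _clean_cell(row[taxon_column])
        if taxon is None:
            raise DataError("blank taxon name in raw table")
        if taxon in raw:
            raise DataError(f"duplicate taxon {taxon!r} in raw table")
        counts_cell = _clean_cell(row[count_column])
        forms_cell = _clean_cell(row[trait_column])
        counts = ([int(v) for v in counts_cell.split(value_sep) if v.strip()]
                  if counts_cell else [])
        forms = ([v.strip() for v in forms_cell.split(value_sep) if v.strip()]
                 if forms_cell else [])
        raw[taxon] = (counts, forms)
    return raw


def code_observations(raw: Mapping[str, tuple[Sequence[int], Sequence[str]]],
                      woody_label: str = "woody",
                      herbaceous_label: str = "herbaceous") -> TipObservations:
    """Collapse multi-valued records into single observations.

    A taxon recorded as both woody and herbaceous is coded woody; with
    multiple chromosome counts, the largest is used.  Empty lists become
    missing observations.
    """
    obs: dict[str, tuple[int | None, object | None]] = {}
    for taxon, (counts, forms) in raw.items():
        count = max(int(c) for c in counts) if len(counts) else None
        if len(forms) == 0:
            trait = None
        elif woody_label in forms:
            trait = woody_label
        else:
            unknown = sorted(set(forms) - {herbaceous_label})
            if unknown:
                raise DataError(
                    f"unknown growth form(s) {unknown} for taxon {taxon!r}")
            trait = herbaceous_label
        obs[taxon] = (count, trait)
    return TipObservations(obs)


# ---------------------------------------------------------------------------
# Observation -> state-likelihood vector
# ---------------------------------------------------------------------------

def _match_trait(trait, space: StateSpace):
    """Resolve an observed trait against the space's labels (str-tolerant)."""
    if trait in space.traits:
        return trait
    for label in space.traits:
        if str(label) == str(trait):
            return label
    return None


def observation_to_vector(obs: tuple[int | None, object | None],
                          space: StateSpace, taxon: str | None = None
                          ) -> np.ndarray:
    """0/1 conditioning vector over states for one tip observation.

    Fully observed tips are one-hot (counts above ``c_max`` map onto the
    LARGE state of the observed trait); a missing trait puts mass on that
    count under every trait; a missing count puts mass on every state of the
    observed trait; a fully missing observation is all ones.
    """
    count, trait = obs
    who = f" for taxon {taxon!r}" if taxon else ""
    vec = np.zeros(space.n_states)

    if trait is not None:
        matched = _match_trait(trait, space)
        if matched is None:
            raise DataError(
                f"trait {trait!r}{who} not among state-space traits "
                f"{space.traits!r}")
        trait = matched

    if count is None and trait is None:
        vec[:] = 1.0
        return vec
    if count is None:
        vec[space.states_of_trait(trait)] = 1.0
        return vec

    def count_key(c: int):
        if space.has_large and c > space.c_max:
            return LARGE
        if c in space.counts:
            return c
        raise DataError(
            f"count {c}{who} is not a state of this space "
            f"(counts {space.counts!r}"
            + (f", LARGE above {space.c_max}" if space.has_large else "") + ")")

    key = count_key(count)
    traits = [trait] if trait is not None else list(space.traits)
    for t in traits:
        vec[space.index_of(key, t)] = 1.0
    return vec
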