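"""Pure-birth tree simulation, CTMC character simulation and power studies.

The power driver reproduces, at user-chosen sizes, the standard study
design for testing trait-linked chromosome-doubling rates: simulate Yule
trees, evolve (count, trait) states along them under the full BiChroM
generator, fit full and reduced models to every replicate, and summarize
how often the likelihood-ratio test rejects the shared-rate null.

Three named scenarios are built in.  All share eight nuisance rates
(lambda0 = 0.01, lambda1 = 0.005, mu0 = 0.01, mu1 = 0.005, q01 = 0.01,
q10 = 0.005, eps0 = eps1 = 1e-6) and differ in the doubling rates:

* S1 — rho0 = rho1 = 0.01 (the null is true; rejections are type-I errors);
* S2 — rho0 = 0.01, rho1 = 0.002 (a five-fold difference; easy power case);
* S3 — rho0 = 0.01, rho1 = 0.008 (a 20% difference; hard power case).

Tree heights are set so a root-to-tip lineage expects about two
chromosome-number events, the midpoint of the zero-to-four design range:
with trait-0 event rates summing to 0.04 per unit time, height 50 gives
0.04 x 50 = 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .errors import InvalidArgumentError
from .inference import FitResult, LRTResult, fit_mle, lrt
from .likelihood import RootPrior
from .models import (BiChroMParams, MODELS, RateMatrix, build_q_bichrom)
from .statespace import LARGE, StateSpace, build_state_space
from .treeio import Phylogeny, TipObservations, read_newick

__all__ = ["simulate_yule_tree", "rescale_height", "simulate_tips",
           "Scenario", "PowerReport", "run_power_experiment",
           "NUISANCE_RATES", "scenario", "SCENARIO_RHO"]

#: The eight BiChroM rates held fixed in every simulation scenario.
NUISANCE_RATES: dict[str, float] = {
    "lambda0": 0.01, "lambda1": 0.005, "mu0": 0.01, "mu1": 0.005,
    "q01": 0.01, "q10": 0.005, "eps0": 1e-6, "eps1": 1e-6,
}

#: Doubling rates (rho0, rho1) for the three named scenarios.
SCENARIO_RHO: dict[str, tuple[float, float]] = {
    "S1": (0.01, 0.01),
    "S2": (0.01, 0.002),
    "S3": (0.01, 0.008),
}

#: Tree height giving ~2 expected count events per root-to-tip lineage.
DEFAULT_HEIGHT: float = 50.0


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_yule_tree(n_taxa: int, seed, birth_rate: float = 1.0) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree with exactly ``n_taxa`` tips.

    Starting from two lineages at the root, each speciation waits an
    exponential time with rate ``k * birth_rate`` (k = current lineage
    count) and splits a uniformly chosen lineage.  After the last
    speciation one further exponential interval is appended so pendant
    edges have positive length.  The tree is binary and ultrametric, with
    tips labeled ``t1..tn``; identical seeds give identical trees.
    """
    if n_taxa < 2:
        raise InvalidArgumentError(f"n_taxa must be >= 2, got {n_taxa}")
    if birth_rate <= 0:
        raise InvalidArgumentError(f"birth rate must be > 0, got {birth_rate}")
    rng = np.random.default_rng(seed)

    next_id = [0]

    def new_node(start: float) -> dict:
        node = {"id": next_id[0], "start": start, "children": [], "end": None}
        next_id[0] += 1
        return node

    t = 0.0
    root = new_node(0.0)
    root["end"] = 0.0
    active = [new_node(0.0), new_node(0.0)]
    root["children"] = list(active)
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = rng.integers(len(active))
        parent = active.pop(int(k))
        parent["end"] = t
        kids = [new_node(t), new_node(t)]
        parent["children"] = kids
        active.extend(kids)
    t += rng.exponential(1.0 / (birth_rate * n_taxa))
    for i, leaf in enumerate(active):
        leaf["end"] = t

    tip_counter = [0]

    def newick(node: dict) -> str:
        length = node["end"] - node["start"]
        if node["children"]:
            inner = ",".join(newick(c) for c in node["children"])
            return f"({inner}):{length:.12g}"
        tip_counter[0] += 1
        return f"t{tip_counter[0]}:{length:.12g}"

    text = ",".join(newick(c) for c in root["children"])
    return read_newick(f"({text});")


def rescale_height(tree: Phylogeny, target_height: float) -> Phylogeny:
    """Multiply all branch lengths so the root-to-tip height hits the target."""
    if target_height <= 0:
        raise InvalidArgumentError(
            f"target height must be > 0, got {target_height}")
    h = tree.height
    if h <= 0:
        raise InvalidArgumentError("cannot rescale a zero-height tree")
    return tree.scaled(target_height / h)


# ---------------------------------------------------------------------------
# Character simulation
# ---------------------------------------------------------------------------

def simulate_tips(tree: Phylogeny, Q: RateMatrix, space: StateSpace | None = None,
                  root_state=None, seed=0, return_history: bool = False):
    """Evolve states along the tree by Gillespie simulation.

    From the state at each node, waiting times to the next event are
    exponential with rate ``-Q[s, s]`` and the jump target is drawn in
    proportion to the off-diagonal row.  A state with exit rate 0 simply
    persists.  The root state may be a state tuple, an index, a
    :class:`RootPrior` to draw from, or ``None`` (uniform draw).

    Returns a :class:`TipObservations`; a tip sitting in a LARGE state is
    recorded with count ``c_max + 1`` (any value above ``c_max`` conditions
    the likelihood on the same LARGE state).  With ``return_history=True``
    also returns per-node end-state indices and per-branch event counts.
    """
    space = space or Q.space
    rng = np.random.default_rng(seed)
    Qd = Q.dense()
    n = space.n_states
    exit_rate = -np.diag(Qd)

    if root_state is None:
        root_idx = int(rng.integers(n))
    elif isinstance(root_state, RootPrior):
        probs = root_state.probabilities(Qd, n)
        root_idx = int(rng.choice(n, p=probs))
    elif isinstance(root_state, tuple):
        root_idx = space.index_of(*root_state)
    else:
        root_idx = int(root_state)
        if not 0 <= root_idx < n:
            raise InvalidArgumentError(f"root state index {root_idx} out of range")

    state = np.empty(tree.n_nodes, dtype=np.int64)
    events = np.zeros(tree.n_nodes, dtype=np.int64)
    jump_probs: dict[int, np.ndarray] = {}
    for i in tree.preorder():
        if i == tree.root:
            state[i] = root_idx
            continue
        s = int(state[tree.parent[i]])
        remaining = tree.edge_length[i]
        while exit_rate[s] > 0:
            wait = rng.exponential(1.0 / exit_rate[s])
            if wait >= remaining:
                break
            remaining -= wait
            if s not in jump_probs:
                row = Qd[s].copy()
                row[s] = 0.0
                jump_probs[s] = row / row.sum()
            s = int(rng.choice(n, p=jump_probs[s]))
            events[i] += 1
        state[i] = s

    obs: dict[str, tuple[int | None, object | None]] = {}
    for i, label in tree.tip_label.items():
        count, trait = space.states[state[i]]
        if count is LARGE:
            count = (space.c_max or 0) + 1
        obs[label] = (int(count), trait)
    tips = TipObservations(obs)
    if return_history:
        return tips, {"state": state, "events": events}
    return tips


def mean_root_to_tip_events(tree: Phylogeny, events: np.ndarray) -> float:
    """Average number of simulated events along root-to-tip paths."""
    totals = np.zeros(tree.n_nodes)
    for i in reversed(range(tree.n_nodes)):
        p = tree.parent[i]
        if p >= 0:
            totals[i] = totals[p] + events[i]
    return float(np.mean([totals[i] for i in tree.tip_label]))


# ---------------------------------------------------------------------------
# Scenarios and the power experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """One simulation condition for the type-I-error / power study."""

    name: str
    params: dict[str, float]
    n_taxa: int
    height: float = DEFAULT_HEIGHT
    replicates: int = 100
    seed: int = 0
    alpha: float = 0.05
    root_state: tuple | None = None  # None: uniform draw per replicate

    def __post_init__(self):
        if self.n_taxa < 3:
            raise InvalidArgumentError(f"n_taxa must be >= 3, got {self.n_taxa}")
        if self.replicates < 1:
            raise InvalidArgumentError("replicates must be >= 1")
        if self.height <= 0:
            raise InvalidArgumentError("height must be > 0")
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError(f"alpha must be in (0, 1), got {self.alpha}")
        missing = set(BiChroMParams.names()) - set(self.params)
        if missing:
            raise InvalidArgumentError(
                f"scenario is missing rates {sorted(missing)}")

    def true_params(self) -> BiChroMParams:
        return BiChroMParams(**{k: self.params[k] for k in BiChroMParams.names()})

    def to_dict(self) -> dict:
        return {"name": self.name, "params": dict(self.params),
                "n_taxa": self.n_taxa, "height": self.height,
                "replicates": self.replicates, "seed": self.seed,
                "alpha": self.alpha,
                "root_state": list(self.root_state) if self.root_state else None}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        d = dict(d)
        root = d.get("root_state")
        return cls(name=d["name"], params=dict(d["params"]),
                   n_taxa=int(d["n_taxa"]),
                   height=float(d.get("height", DEFAULT_HEIGHT)),
                   replicates=int(d.get("replicates", 100)),
                   seed=int(d.get("seed", 0)),
                   alpha=float(d.get("alpha", 0.05)),
                   root_state=tuple(root) if root else None)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def scenario(name: str, n_taxa: int, replicates: int = 100, seed: int = 0,
             height: float = DEFAULT_HEIGHT, alpha: float = 0.05) -> Scenario:
    """Build one of the named scenarios S1/S2/S3 at a chosen size."""
    if name not in SCENARIO_RHO:
        raise InvalidArgumentError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIO_RHO)}")
    rho0, rho1 = SCENARIO_RHO[name]
    params = {**NUISANCE_RATES, "rho0": rho0, "rho1": rho1}
    return Scenario(name=name, params=params, n_taxa=n_taxa, height=height,
                    replicates=replicates, seed=seed, alpha=alpha)


@dataclass
class PowerReport:
    """Per-replicate fits plus the aggregate rejection proportion."""

    scenario: Scenario
    records: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    @property
    def n_completed(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return sum(1 for r in self.records if r["reject"])

    @property
    def rejection_proportion(self) -> float:
        if not self.records:
            return float("nan")
        return self.n_rejected / self.n_completed

    def rejection_interval(self, confidence: float = 0.95) -> tuple[float, float]:
        """Exact (Clopper-Pearson) binomial interval for the rejection rate."""
        ci = scipy.stats.binomtest(
            self.n_rejected, self.n_completed).proportion_ci(
                confidence_level=confidence, method="exact")
        return float(ci.low), float(ci.high)

    def mles(self, model: str, name: str) -> np.ndarray:
        """Across replicates, the MLE of one parameter under one model."""
        key = f"{model}_{name}"
        return np.array([r[key] for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def summary(self) -> dict:
        lo, hi = (self.rejection_interval() if self.records
                  else (float("nan"), float("nan")))
        return {
            "scenario": self.scenario.to_dict(),
            "n_completed": self.n_completed,
            "n_failed": len(self.failures),
            "n_rejected": self.n_rejected,
            "rejection_proportion": self.rejection_proportion,
            "rejection_ci95": [lo, hi],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary(), indent=2, **kwargs)


#: Optimizer options used per replicate.  Simulated data are generated at
#: rates on the scale of the default init, so multistart is unnecessary;
#: a single quasi-Newton run per model with a stopping tolerance far below
#: the LRT's resolution keeps large experiments tractable.
_POWER_FIT_OPTIONS: dict = {"restarts": 0, "maxiter": 200, "ftol": 1e-7}


def _reduced_init_from_full(full: FitResult) -> dict[str, float]:
    """Warm start for the reduced fit: shared rho at the geometric mean."""
    params = full.params()
    init = {k: v for k, v in params.items() if k not in ("rho0", "rho1")}
    init["rho"] = float(np.sqrt(params["rho0"] * params["rho1"]))
    return init


def fit_replicate(tree: Phylogeny, tips: TipObservations, space: StateSpace,
                  alpha: float = 0.05, options: Mapping | None = None,
                  seed: int = 0) -> tuple[FitResult, FitResult, LRTResult]:
    """Fit full and reduced BiChroM to one data set and run the LRT.

    The reduced fit is warm-started from the full MLE.  If the reduced fit
    nevertheless ends below the full fit (a full-model optimizer failure:
    the models are nested, so that is impossible at the true optima), the
    full model is refit from the reduced solution, which restores nesting.
    """
    opts = {**_POWER_FIT_OPTIONS, **dict(options or {})}
    full_model = MODELS["bichrom"]
    red_model = MODELS["bichrom_reduced"]
    full = fit_mle(tree, tips, full_model.build, space, full_model.param_names,
                   model_name="bichrom", options=opts, seed=seed)
    reduced = fit_mle(tree, tips, red_model.build, space, red_model.param_names,
                      init=_reduced_init_from_full(full),
                      model_name="bichrom_reduced", options=opts, seed=seed)
    if reduced.nll < full.nll - 1e-9:
        params = reduced.params()
        rescue = fit_mle(
            tree, tips, full_model.build, space, full_model.param_names,
            init={**{k: v for k, v in params.items() if k != "rho"},
                  "rho0": params["rho"], "rho1": params["rho"]},
            model_name="bichrom", options=opts, seed=seed)
        if rescue.nll < full.nll:
            full = rescue
    return full, reduced, lrt(full, reduced, alpha=alpha)


def run_power_experiment(scn: Scenario, *, c_max: int = 25,
                         options: Mapping | None = None,
                         progress: Callable[[int, dict], None] | None = None
                         ) -> PowerReport:
    """Run the scenario end to end and aggregate the rejection proportion.

    Per replicate ``r``: a Yule tree with ``seed + r`` is grown and rescaled
    to the scenario height, (count, trait) data are simulated under the true
    full-model generator, both models are fitted with every non-focal
    parameter free, and the LRT is evaluated at the scenario's alpha.
    Replicates whose fits fail are recorded under ``failures`` and excluded
    from the rejection denominator.
    """
    space = build_state_space(c_max, (0, 1))
    theta_true = scn.true_params().to_array()
    Q_true = build_q_bichrom(scn.true_params(), space)
    root_state = scn.root_state
    report = PowerReport(scenario=scn)

    for r in range(scn.replicates):
        seed_r = scn.seed + r
        record: dict = {"replicate": r, "seed": seed_r}
        try:
            tree = rescale_height(simulate_yule_tree(scn.n_taxa, seed_r),
                                  scn.height)
            tips = simulate_tips(tree, Q_true, space, root_state=root_state,
                                 seed=[seed_r, 1])
            full, reduced, test = fit_replicate(
                tree, tips, space, alpha=scn.alpha, options=options,
                seed=seed_r)
        except Exception as exc:  # replicate-level failure, not fatal
            warnings.warn(f"replicate {r} failed: {exc}", UserWarning,
                          stacklevel=2)
            report.failures.append({"replicate": r, "seed": seed_r,
                                    "error": str(exc)})
            continue
        for name, value in full.mle.items():
            record[f"full_{name}"] = value
        for name, value in reduced.mle.items():
            record[f"reduced_{name}"] = value
        record.update(nll_full=full.nll, nll_reduced=reduced.nll,
                      converged_full=full.converged,
                      converged_reduced=reduced.converged,
                      D=test.D, p_value=test.p_value, reject=test.reject)
        report.records.append(record)
        if progress is not None:
            progress(r, record)
    return report
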