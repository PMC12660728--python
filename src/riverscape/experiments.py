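"""Standardized validation experiments for the DEC engine.

Three self-contained experiments, each driven entirely by the synthetic
generator and a single seed:

* an exhaustive *joint-state* likelihood oracle for tiny instances — the
  likelihood summed explicitly over every assignment of range states to
  internal nodes, with branch transition matrices taken straight from
  ``scipy.linalg.expm`` — against which the pruning implementation is
  compared;
* a parameter-recovery experiment (simulate ranges at known rates on
  birth-death trees, refit by ML, summarize bias/RMSE);
* a model-selection experiment (simulate under a two-slice LEM whose
  connectivity switches at 10 Ma, fit both the true stratified model and a
  single-slice stepping-stone, count AIC preferences).

The recovery and model-selection study conditions (rates, tree sizes,
LEM shapes) are fixed here as module constants so tests and scripts run
the same experiment.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .dec import (
    DECParams,
    build_q,
    cladogenesis_table,
    fit_ml,
    StateSpace,
    _branch_segments,
)
from .geography import LEMSpec, RangeState, build_lem, stepping_stone_chain
from .phylo import TimeTree
from .simulate import simulate_dec_history, simulate_tree

# -- study conditions ----------------------------------------------------

RECOVERY_TRUTH = DECParams(delta=0.05, e=0.01)
RECOVERY_BIRTH = 0.14  # per Myr: ~30 Ma root ages at these tip counts
MODEL_SELECTION_TRUTH = DECParams(delta=0.08, e=0.01)


def recovery_lem() -> LEMSpec:
    """The 4-region stepping-stone chain used by the recovery experiment."""
    return stepping_stone_chain(list("ABCD"), name="chain4")


def model_selection_lems() -> tuple[LEMSpec, LEMSpec]:
    """(true two-slice LEM, rival single-slice LEM).

    Connectivity is a linear chain before 10 Ma and a complete graph after
    — a strong, river-capture-like rearrangement at the slice boundary.
    """
    n = 4
    chain = [[1.0 if abs(i - j) == 1 else 0.0 for j in range(n)] for i in range(n)]
    full = [[0.0 if i == j else 1.0 for j in range(n)] for i in range(n)]
    two = build_lem(
        {
            "name": "two_slice",
            "regions": list("ABCD"),
            "slices": [
                {"start_age": "inf", "end_age": 10, "matrix": chain},
                {"start_age": 10, "end_age": 0, "matrix": full},
            ],
        }
    )
    one = build_lem({"name": "chain", "regions": list("ABCD"), "adjacency": chain})
    return two, one


# -- brute-force joint-state oracle --------------------------------------


def _oracle_branch_matrix(
    lem: LEMSpec, params: DECParams, older: float, younger: float, root_age: float
) -> np.ndarray:
    """Branch transition matrix straight from expm, composed per slice."""
    P = None
    for slice_idx, dt in _branch_segments(lem, older, younger, root_age):
        step = expm(build_q(lem, slice_idx, params).Q * dt)
        P = step if P is None else P @ step
    if P is None:
        P = np.eye(StateSpace.for_lem(lem).n)
    return P


def bruteforce_joint_loglik(
    tree: TimeTree,
    tip_ranges: Mapping[str, RangeState],
    lem: LEMSpec,
    params: DECParams,
) -> float:
    """Log-likelihood by explicit summation over all joint assignments of
    non-null range states to internal nodes (uniform non-null root prior).

    Independent of the pruning implementation: no rescaling, dict-based
    cladogenesis lookup, expm branch matrices, itertools joint enumeration.
    Exponential in the number of internal nodes — tiny instances only.
    """
    space = StateSpace.for_lem(lem)
    ages = tree.node_ages()
    root_age = ages[tree.root.riverscape_id]
    nodes = list(tree.postorder())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    non_null = list(range(1, space.n))

    P = {}  # child node -> branch matrix above it
    for nd in nodes:
        if nd.parent_node is not None:
            P[id(nd)] = _oracle_branch_matrix(
                lem, params,
                ages[nd.parent_node.riverscape_id], ages[nd.riverscape_id],
                root_age,
            )
    clado = {
        a: [
            (space.index_of(ev.left), space.index_of(ev.right), ev.prob)
            for ev in cladogenesis_table(space.states[a], lem)
        ]
        for a in non_null
    }

    prior = 1.0 / len(non_null)
    total = 0.0
    for assignment in itertools.product(non_null, repeat=len(internal)):
        state_of = {id(nd): s for nd, s in zip(internal, assignment)}
        weight = prior
        for nd in internal:
            a = state_of[id(nd)]
            c1, c2 = nd.child_nodes()
            s1 = (state_of[id(c1)] if not c1.is_leaf()
                  else space.index_of(tip_ranges[c1.taxon.label]))
            s2 = (state_of[id(c2)] if not c2.is_leaf()
                  else space.index_of(tip_ranges[c2.taxon.label]))
            term = sum(
                p * P[id(c1)][l, s1] * P[id(c2)][r, s2]
                for l, r, p in clado[a]
            )
            weight *= term
            if weight == 0.0:
                break
        total += weight
    if total <= 0:
        return float("-inf")  # data impossible under these parameters
    return math.log(total)


def bruteforce_joint_marginals(
    tree: TimeTree,
    tip_ranges: Mapping[str, RangeState],
    lem: LEMSpec,
    params: DECParams,
) -> dict[str, np.ndarray]:
    """Marginal state posteriors at internal nodes by the same joint
    enumeration (normalized per node); keyed by node id."""
    space = StateSpace.for_lem(lem)
    ages = tree.node_ages()
    root_age = ages[tree.root.riverscape_id]
    nodes = list(tree.postorder())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    non_null = list(range(1, space.n))
    P = {}
    for nd in nodes:
        if nd.parent_node is not None:
            P[id(nd)] = _oracle_branch_matrix(
                lem, params,
                ages[nd.parent_node.riverscape_id], ages[nd.riverscape_id],
                root_age,
            )
    clado = {
        a: [
            (space.index_of(ev.left), space.index_of(ev.right), ev.prob)
            for ev in cladogenesis_table(space.states[a], lem)
        ]
        for a in non_null
    }
    acc = {nd.riverscape_id: np.zeros(space.n) for nd in internal}
    for assignment in itertools.product(non_null, repeat=len(internal)):
        state_of = {id(nd): s for nd, s in zip(internal, assignment)}
        weight = 1.0 / len(non_null)
        for nd in internal:
            a = state_of[id(nd)]
            c1, c2 = nd.child_nodes()
            s1 = (state_of[id(c1)] if not c1.is_leaf()
                  else space.index_of(tip_ranges[c1.taxon.label]))
            s2 = (state_of[id(c2)] if not c2.is_leaf()
                  else space.index_of(tip_ranges[c2.taxon.label]))
            weight *= sum(
                p * P[id(c1)][l, s1] * P[id(c2)][r, s2] for l, r, p in clado[a]
            )
        for nd, s in zip(internal, assignment):
            acc[nd.riverscape_id][s] += weight
    for k in acc:
        acc[k] /= acc[k].sum()
    return acc


def random_oracle_instance(rng: np.random.Generator):
    """A random tiny (tree, tip ranges, LEM, params) instance for the
    pruning-vs-oracle comparison: 2-4 tips, 2-3 areas, random multipliers,
    a 1- or 2-slice LEM, log-uniform rates."""
    n_tips = int(rng.integers(2, 5))
    n_areas = int(rng.integers(2, 4))
    # random ultrametric topology by sequential random joins
    groups = [(f"T{i+1}", 0.0) for i in range(n_tips)]
    age = 0.0
    while len(groups) > 1:
        age += float(rng.uniform(0.5, 3.0))
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        (na, aa), (nb, ab) = groups[i], groups[j]
        merged = (f"({na}:{age - aa:.6f},{nb}:{age - ab:.6f})", age)
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
    tree = TimeTree.from_newick(groups[0][0] + ";")

    def rand_matrix():
        m = rng.uniform(0.0, 1.0, size=(n_areas, n_areas))
        m[rng.uniform(size=m.shape) < 0.2] = 0.0  # some closed corridors
        np.fill_diagonal(m, 0.0)
        return m.tolist()

    regions = [chr(ord("A") + i) for i in range(n_areas)]
    if rng.random() < 0.5:
        lem = build_lem({"name": "one", "regions": regions,
                         "slices": [{"start_age": "inf", "end_age": 0,
                                     "matrix": rand_matrix()}]})
    else:
        boundary = float(rng.uniform(0.2, 0.8)) * age
        lem = build_lem({"name": "two", "regions": regions,
                         "slices": [
                             {"start_age": "inf", "end_age": boundary,
                              "matrix": rand_matrix()},
                             {"start_age": boundary, "end_age": 0,
                              "matrix": rand_matrix()}]})
    space = StateSpace.for_lem(lem)
    tips = {
        lbl: space.states[int(rng.integers(1, space.n))] for lbl in tree.tip_labels
    }
    params = DECParams(
        delta=float(np.exp(rng.uniform(np.log(1e-3), np.log(0.5)))),
        e=float(np.exp(rng.uniform(np.log(1e-3), np.log(0.5)))),
    )
    return tree, tips, lem, params


def pruning_vs_oracle_max_error(n_draws: int, seed: int) -> float:
    """Max |pruning lnL - joint-enumeration lnL| over random tiny instances.

    Random closed corridors can make a drawn dataset genuinely impossible
    (likelihood exactly zero); both routes must then agree on impossibility,
    which counts as zero error.  Disagreement (one route zero, the other
    finite) reports an infinite error.
    """
    from .dec import DECLikelihood
    from .errors import UnderflowError

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    worst = 0.0
    for _ in range(n_draws):
        tree, tips, lem, params = random_oracle_instance(rng)
        try:
            lnl = DECLikelihood(tree, tips, lem).loglik(params)
        except UnderflowError:
            lnl = float("-inf")
        oracle = bruteforce_joint_loglik(tree, tips, lem, params)
        if math.isinf(lnl) and math.isinf(oracle):
            continue  # both report impossibility: agreement
        worst = max(worst, abs(lnl - oracle))
    return worst


# -- parameter recovery --------------------------------------------------


def run_recovery(
    n_tips: int,
    n_reps: int,
    seed: int,
    truth: DECParams = RECOVERY_TRUTH,
) -> pd.DataFrame:
    """Simulate + refit ``n_reps`` replicates at ``n_tips``; one row each.

    Trees are pure-birth at the experiment's fixed birth rate; ranges
    evolve under the 4-region chain; fits use the survival-conditioned
    likelihood (matching the generator, which conditions on observable
    tips).
    """
    lem = recovery_lem()
    ss = np.random.SeedSequence(int(seed))
    rows = []
    for rep, child in enumerate(ss.spawn(n_reps)):
        s1, s2 = [int(s) for s in child.generate_state(2) >> 1]
        tree = simulate_tree(RECOVERY_BIRTH, 0.0, n_tips, s1)
        hist = simulate_dec_history(tree, lem, truth, s2)
        fit = fit_ml(tree, hist.tip_ranges, lem, condition_on_survival=True)
        rows.append(
            {"rep": rep, "n_tips": n_tips, "delta_hat": fit.delta_hat,
             "e_hat": fit.e_hat, "lnL": fit.lnL}
        )
    return pd.DataFrame(rows)


def recovery_summary(fits: pd.DataFrame, truth: DECParams = RECOVERY_TRUTH) -> dict:
    """Median estimates and linear-scale RMSEs against the generating rates."""
    return {
        "median_delta": float(fits["delta_hat"].median()),
        "median_e": float(fits["e_hat"].median()),
        "rmse_delta": float(np.sqrt(((fits["delta_hat"] - truth.delta) ** 2).mean())),
        "rmse_e": float(np.sqrt(((fits["e_hat"] - truth.e) ** 2).mean())),
    }


# -- model selection -----------------------------------------------------


def run_model_selection(n_reps: int, n_tips: int, seed: int) -> pd.DataFrame:
    """Simulate under the two-slice LEM; fit it and the single-slice rival;
    one row per replicate with both AICs and the preference flag."""
    lem_two, lem_one = model_selection_lems()
    ss = np.random.SeedSequence(int(seed))
    rows = []
    for rep, child in enumerate(ss.spawn(n_reps)):
        s1, s2 = [int(s) for s in child.generate_state(2) >> 1]
        tree = simulate_tree(RECOVERY_BIRTH, 0.0, n_tips, s1)
        hist = simulate_dec_history(tree, lem_two, MODEL_SELECTION_TRUTH, s2)
        f2 = fit_ml(tree, hist.tip_ranges, lem_two)
        f1 = fit_ml(tree, hist.tip_ranges, lem_one)
        rows.append(
            {"rep": rep, "aic_two_slice": f2.AIC, "aic_single_slice": f1.AIC,
             "prefers_truth": f2.AIC < f1.AIC}
        )
    return pd.DataFrame(rows)
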