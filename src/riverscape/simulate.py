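"""Synthetic data with known ground truth for every pipeline input.

The generator emulates the study system end to end at desk scale: a
birth-death chronogram stands in for the time-calibrated phylogeny; tip
ranges are evolved forward under a known LEM and known (delta, e) by an
exact event-driven (Gillespie) jump process, so the DEC likelihood being
fitted is exactly the generating process; river-segment tables follow
Horton's geometric laws (segment counts shrinking, lengths growing by fixed
ratios per order) with optional lognormal noise; and occurrence records are
drawn from per-species stream-order niches (a discretized Gaussian around a
modal order), optionally salted with planted duplicates and out-of-bounds
records to exercise the QC stage.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``, so a full bundle is bit-reproducible.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .dec import DECParams, cladogenesis_table, StateSpace
from .errors import SimulationError, ValidationError
from .geography import LEMSpec, RangeState, range_label
from .phylo import TimeTree


# -- trees ---------------------------------------------------------------


def simulate_tree(
    birth: float,
    death: float,
    n_tips: int,
    seed: int,
    max_attempts: int = 10_000,
) -> TimeTree:
    """Ultrametric birth-death tree conditioned on ``n_tips`` extant tips.

    Simulate-and-retain: the process is run forward (dendropy's birth-death
    simulator) until a replicate reaches ``n_tips`` without going extinct.
    Tips are labeled ``T1..Tn``.
    """
    if not birth > death >= 0:
        raise ValidationError(f"need birth > death >= 0, got ({birth}, {death})")
    if n_tips < 2:
        raise ValidationError(f"n_tips must be >= 2, got {n_tips}")
    rng = random.Random(int(seed))
    dtree = None
    last_exc: Exception | None = None
    for _ in range(max_attempts):
        try:
            dtree = treesim.birth_death_tree(
                birth_rate=birth,
                death_rate=death,
                num_extant_tips=n_tips,
                rng=rng,
                repeat_until_success=False,
            )
            break
        except Exception as exc:  # total-extinction rejection
            last_exc = exc
    if dtree is None:
        raise SimulationError(
            f"birth-death simulation failed after {max_attempts} attempts: {last_exc}"
        ) from last_exc
    dtree.seed_node.edge.length = None  # drop the stem edge: crown chronogram
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"T{i}"
    return TimeTree(dtree)


# -- DEC histories -------------------------------------------------------


@dataclass
class DECHistory:
    """Ground truth of one simulated range history."""

    tip_ranges: dict[str, RangeState]
    node_ranges: dict[str, RangeState]  # state at each internal node (pre-split)
    events: pd.DataFrame  # lineage, age, event, area
    root_state: RangeState
    any_null: bool


def _gillespie_branch(
    state: RangeState,
    segments: Sequence[tuple[int, float]],
    lem: LEMSpec,
    params: DECParams,
    rng: np.random.Generator,
    age_start: float,
    events: list,
    lineage: str,
):
    """Evolve a range down one branch (piecewise-constant rates per slice)."""
    age = age_start
    for slice_idx, dt in segments:
        m = lem.slices[slice_idx].multipliers
        remaining = dt
        while remaining > 0 and not state.is_null:
            areas = sorted(state.areas)
            moves: list[tuple[str, int, float]] = []
            if state.size < lem.max_range_size:
                for j in range(lem.n_areas):
                    if j in state:
                        continue
                    rate = params.delta * sum(m[i, j] for i in areas)
                    if rate > 0:
                        moves.append(("gain", j, rate))
            if params.e > 0:
                for i in areas:
                    moves.append(("loss", i, params.e))
            total = sum(r for _, _, r in moves)
            if total == 0:
                break
            wait = rng.exponential(1.0 / total)
            if wait >= remaining:
                break
            remaining -= wait
            age -= wait
            u = rng.random() * total
            acc = 0.0
            for kind, area, rate in moves:
                acc += rate
                if u <= acc:
                    state = state.add(area) if kind == "gain" else state.remove(area)
                    events.append((lineage, age, kind, area))
                    break
        age -= remaining
    return state


def simulate_dec_history(
    tree: TimeTree,
    lem: LEMSpec,
    params: DECParams,
    seed: int,
    null_handling: str = "resimulate-branch",
    max_attempts: int = 500,
) -> DECHistory:
    """Forward-simulate a DEC range history along a chronogram.

    The root range is drawn uniformly from the non-null states; anagenetic
    gains/losses are exact CTMC jumps with slice-appropriate rates; at each
    node a cladogenetic event is drawn from the equal-weights event table.

    A lineage hitting the absorbing null range is unobservable at the tips,
    so ``null_handling`` controls what happens:

    * ``"resimulate-branch"`` (default) — redraw just the offending branch,
      conditioning each branch on survival; tip data are always complete.
    * ``"reject-replicate"`` — redraw the whole history (exact but
      infeasible when the expected number of null hits per history is
      large).
    * ``"keep"`` — keep nulls and flag them (for observability studies).
    """
    if null_handling not in ("resimulate-branch", "reject-replicate", "keep"):
        raise ValidationError(f"unknown null_handling {null_handling!r}")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    space = StateSpace.for_lem(lem)
    ages = tree.node_ages()
    from .dec import _branch_segments  # shared slice segmentation

    root_age = ages[tree.root.riverscape_id]
    for attempt in range(max_attempts):
        events: list = []
        tip_ranges: dict[str, RangeState] = {}
        node_ranges: dict[str, RangeState] = {}
        root_state = space.states[int(rng.integers(1, space.n))]
        any_null = False
        rejected = False
        # stack of (node, state at the node itself)
        stack = [(tree.root, root_state)]
        while stack and not rejected:
            node, state = stack.pop()
            nid = node.riverscape_id
            if node.is_leaf():
                tip_ranges[nid] = state
                if state.is_null:
                    any_null = True
                continue
            node_ranges[nid] = state
            if state.is_null:
                any_null = True
                for child in node.child_nodes():
                    stack.append((child, state))
                continue
            table = cladogenesis_table(state, lem)
            probs = np.array([ev.prob for ev in table])
            ev = table[int(rng.choice(len(table), p=probs / probs.sum()))]
            for child, daughter in zip(node.child_nodes(), (ev.left, ev.right)):
                segs = _branch_segments(
                    lem, ages[nid], ages[child.riverscape_id], root_age
                )
                branch_tries = 100 if null_handling == "resimulate-branch" else 1
                for _ in range(branch_tries):
                    branch_events: list = []
                    end_state = _gillespie_branch(
                        daughter, segs, lem, params, rng, ages[nid],
                        branch_events, child.riverscape_id,
                    )
                    if not end_state.is_null or null_handling != "resimulate-branch":
                        break
                events.extend(branch_events)
                if end_state.is_null:
                    if null_handling != "keep":
                        rejected = True
                        break
                    any_null = True
                stack.append((child, end_state))
        if rejected:
            continue
        ev_df = pd.DataFrame(events, columns=["lineage", "age", "event", "area"])
        return DECHistory(
            tip_ranges=tip_ranges,
            node_ranges=node_ranges,
            events=ev_df,
            root_state=root_state,
            any_null=any_null,
        )
    raise SimulationError(
        f"all {max_attempts} attempts hit the null range under "
        f"null_handling={null_handling!r}; lower e or use "
        "null_handling='resimulate-branch'"
    )


# -- riverscapes ---------------------------------------------------------


def simulate_riverscape(
    n_orders: int,
    bifurcation_ratio: float = 4.0,
    length_ratio: float = 2.0,
    seed: int = 0,
    width_ratio: float = 1.9,
    depth_ratio: float = 1.8,
    noise_sigma: float = 0.3,
    first_order_length_km: float = 1.0,
    first_order_width_km: float = 0.005,
    first_order_depth_km: float = 0.0005,
    basin: str = "basin1",
) -> pd.DataFrame:
    """Horton-law river network as a segment attribute table.

    Segment counts fall by ``bifurcation_ratio`` and mean lengths grow by
    ``length_ratio`` per stream order (geometric Horton scaling); channel
    width and depth grow by their own ratios, giving surface area
    (length x width) and volume (area x depth) power laws.  Per-segment
    lengths carry mean-preserving lognormal noise of scale ``noise_sigma``
    (0 gives the exact geometric series).
    """
    if not 2 <= n_orders <= 10:
        raise ValidationError(f"n_orders must be in [2, 10], got {n_orders}")
    for name, r in (("bifurcation_ratio", bifurcation_ratio),
                    ("length_ratio", length_ratio),
                    ("width_ratio", width_ratio),
                    ("depth_ratio", depth_ratio)):
        if not r > 1:
            raise ValidationError(f"{name} must be > 1, got {r}")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    rows = []
    sid = 0
    for k in range(1, n_orders + 1):
        count = max(1, round(bifurcation_ratio ** (n_orders - k)))
        mean_len = first_order_length_km * length_ratio ** (k - 1)
        width = first_order_width_km * width_ratio ** (k - 1)
        depth = first_order_depth_km * depth_ratio ** (k - 1)
        if noise_sigma > 0:
            lengths = mean_len * rng.lognormal(
                -0.5 * noise_sigma**2, noise_sigma, size=count
            )
        else:
            lengths = np.full(count, mean_len)
        for L in lengths:
            sid += 1
            rows.append(
                {
                    "segment_id": f"seg{sid}",
                    "basin": basin,
                    "stream_order": k,
                    "length_km": float(L),
                    "area_km2": float(L * width),
                    "volume_km3": float(L * width * depth),
                }
            )
    return pd.DataFrame(rows)


# -- occurrences ---------------------------------------------------------


@dataclass
class SpeciesNiche:
    """Stream-order preference of one species: modal order and breadth (in
    order units; 0 = strictly at the modal order)."""

    species: str
    modal_order: int
    breadth: float


def make_species_pool(
    n_species: int,
    n_orders: int,
    seed: int,
    breadth_range: tuple[float, float] = (0.5, 2.5),
) -> list[SpeciesNiche]:
    """Random pool: modal orders uniform over [1, n_orders], breadths uniform
    over ``breadth_range``."""
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    pool = []
    for i in range(1, n_species + 1):
        pool.append(
            SpeciesNiche(
                species=f"T{i}",
                modal_order=int(rng.integers(1, n_orders + 1)),
                breadth=float(rng.uniform(*breadth_range)),
            )
        )
    return pool


_BASIN_BOXES = {  # default synthetic bounding boxes (lat_min, lat_max, lon_min, lon_max)
    "basin1": (-10.0, 0.0, -70.0, -60.0),
}


def simulate_occurrences(
    species_pool: Sequence[SpeciesNiche],
    riverscape: pd.DataFrame,
    n_records: int,
    seed: int,
    planted_duplicates: int = 0,
    planted_out_of_bounds: int = 0,
    basin_boxes: Mapping[str, tuple[float, float, float, float]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Occurrence records over a simulated riverscape.

    Records are assigned species uniformly, then a stream order from the
    species' discretized-Gaussian niche over the orders present in the
    riverscape; coordinates are uniform in the record's basin box.  Planted
    duplicates (exact copies of existing rows) and out-of-bounds records
    (outside every basin box) are appended for QC exercises; the returned
    truth dict records what was planted.
    """
    if not species_pool:
        raise ValidationError("species pool is empty")
    if n_records < 1:
        raise ValidationError("n_records must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    boxes = dict(basin_boxes or _BASIN_BOXES)
    orders = np.sort(riverscape["stream_order"].unique())
    basins = sorted(riverscape["basin"].unique())
    rows = []
    for _ in range(n_records):
        sp = species_pool[int(rng.integers(len(species_pool)))]
        if sp.breadth == 0:
            k = sp.modal_order
        else:
            w = np.exp(-0.5 * ((orders - sp.modal_order) / sp.breadth) ** 2)
            k = int(rng.choice(orders, p=w / w.sum()))
        basin = basins[int(rng.integers(len(basins)))]
        lat_min, lat_max, lon_min, lon_max = boxes.get(
            basin, next(iter(boxes.values()))
        )
        rows.append(
            {
                "species": sp.species,
                "lat": float(rng.uniform(lat_min, lat_max)),
                "lon": float(rng.uniform(lon_min, lon_max)),
                "basin": basin,
                "stream_order": int(k),
            }
        )
    df = pd.DataFrame(rows)
    truth = {"n_base": len(df), "n_duplicates": 0, "n_out_of_bounds": 0}
    if planted_duplicates > 0:
        dup_idx = rng.choice(len(df), size=min(planted_duplicates, len(df)),
                             replace=False)
        dups = df.iloc[np.sort(dup_idx)].copy()
        truth["n_duplicates"] = len(dups)
        df = pd.concat([df, dups], ignore_index=True)
    if planted_out_of_bounds > 0:
        oob = []
        for _ in range(planted_out_of_bounds):
            sp = species_pool[int(rng.integers(len(species_pool)))]
            oob.append(
                {
                    "species": sp.species,
                    "lat": float(rng.uniform(40.0, 60.0)),  # far outside all boxes
                    "lon": float(rng.uniform(0.0, 20.0)),
                    "basin": basins[0],
                    "stream_order": int(rng.choice(orders)),
                }
            )
        truth["n_out_of_bounds"] = len(oob)
        df = pd.concat([df, pd.DataFrame(oob)], ignore_index=True)
    truth["boxes"] = boxes
    return df, truth


# -- whole bundles -------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset bundle."""

    seed: int = 1
    n_tips: int = 100
    birth: float = 0.14  # per Myr; ~30 Ma root ages at 100-200 tips
    death: float = 0.0
    lem: LEMSpec | None = None  # default: 4-region stepping-stone chain
    params: DECParams = field(default_factory=lambda: DECParams(0.05, 0.01))
    n_orders: int = 8
    bifurcation_ratio: float = 4.0
    length_ratio: float = 2.0
    n_records: int = 1466
    planted_duplicates: int = 0
    planted_out_of_bounds: int = 0


def simulate_bundle(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a complete synthetic input bundle + ground truth to ``outdir``.

    Files: ``tree.nwk``, ``ranges.csv``, ``lem.yaml``, ``occurrences.csv``,
    ``segments.csv``, ``truth.json``.  Returns a manifest dict.
    """
    from .geography import stepping_stone_chain, write_range_matrix

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    lem = config.lem or stepping_stone_chain(list("ABCD"), name="chain4")
    ss = np.random.SeedSequence(int(config.seed))
    seeds = [int(s) for s in ss.generate_state(4) >> 1]  # keep below 2^31

    tree = simulate_tree(config.birth, config.death, config.n_tips, seeds[0])
    hist = simulate_dec_history(tree, lem, config.params, seeds[1])
    segments = simulate_riverscape(
        config.n_orders, config.bifurcation_ratio, config.length_ratio, seeds[2]
    )
    pool = make_species_pool(config.n_tips, config.n_orders, seeds[3])
    occ, occ_truth = simulate_occurrences(
        pool, segments, config.n_records, seeds[3],
        planted_duplicates=config.planted_duplicates,
        planted_out_of_bounds=config.planted_out_of_bounds,
    )

    tree.to_newick(out / "tree.nwk")
    write_range_matrix(hist.tip_ranges, lem, out / "ranges.csv")
    lem.to_yaml(out / "lem.yaml")
    occ.to_csv(out / "occurrences.csv", index=False)
    segments.to_csv(out / "segments.csv", index=False)
    truth = {
        "seed": config.seed,
        "delta": config.params.delta,
        "e": config.params.e,
        "lem": lem.name,
        "root_state": range_label(hist.root_state, lem),
        "node_ranges": {k: range_label(v, lem) for k, v in hist.node_ranges.items()},
        "n_events": len(hist.events),
        "occurrences": occ_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    hist.events.to_csv(out / "events.csv", index=False)
    return {
        "outdir": str(out),
        "files": ["tree.nwk", "ranges.csv", "lem.yaml", "occurrences.csv",
                  "segments.csv", "truth.json", "events.csv"],
        "n_tips": config.n_tips,
    }
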