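"""Network efficiency, network flux and the combination score.

Network efficiency (NE) of a weighted digraph G is the sum of reciprocal
weighted shortest-path lengths over ordered node pairs:

    NE = sum_{i != j in G} 1 / d_ij        (1/inf := 0 for unreachable pairs)

Network flux (NF) restricts the sum to pairs whose destination is an exit
(terminal) node, so damage close to the pathway's final event counts for
more:

    NF = sum_{i != j, j in exits} 1 / d_ij

Raising edge weights (inhibiting a target) can only lengthen shortest paths,
so NE and NF fall monotonically under attack.  Per-compound effects are
reported as percentage decreases from the uniform-weight baseline, and the
headline efficacy score is the geometric mean of the NE and NF decreases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from pathflux.errors import ConfigurationError, ValidationError
from pathflux.network import PathwayNetwork, detect_exits
from pathflux.perturbation import ScoreMatrix, apply_profile, build_profile

PAIR_MODES = ("ordered", "unordered")


def shortest_path_lengths(net: PathwayNetwork) -> dict[tuple[str, str], float]:
    """All-pairs weighted shortest directed distances (Dijkstra).

    Returns a map over ordered pairs (i, j), i != j, containing only the
    finite distances; an absent pair is unreachable (d = inf).  All weights
    must be positive.
    """
    for u, v, data in net.graph.edges(data=True):
        if not data.get("weight", 0) > 0:
            raise ValidationError(f"edge {u!r}->{v!r}: nonpositive weight")
    out: dict[tuple[str, str], float] = {}
    for source, dists in nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"):
        for target, d in dists.items():
            if target != source:
                out[(source, target)] = d
    return out


def _efficiency_from_lengths(
    lengths: Mapping[tuple[str, str], float],
    pair_mode: str,
    exits: frozenset[str] | None = None,
) -> float:
    if pair_mode not in PAIR_MODES:
        raise ConfigurationError(f"pair_mode must be one of {PAIR_MODES}")
    if pair_mode == "ordered":
        return sum(
            1.0 / d
            for (i, j), d in lengths.items()
            if exits is None or j in exits
        )
    # unordered: one term per pair {i, j}, using the shorter direction
    best: dict[frozenset[str], float] = {}
    for (i, j), d in lengths.items():
        if exits is not None and j not in exits:
            continue
        key = frozenset((i, j))
        if d < best.get(key, math.inf):
            best[key] = d
    return sum(1.0 / d for d in best.values())


def network_efficiency(net: PathwayNetwork, pair_mode: str = "ordered") -> float:
    """NE: sum of 1/d_ij over node pairs, zero contribution when unreachable.

    ``pair_mode='ordered'`` (default) sums over ordered pairs (i, j), i != j,
    following edge direction; ``'unordered'`` sums once per pair {i, j} using
    the shorter of the two directions.
    """
    return _efficiency_from_lengths(shortest_path_lengths(net), pair_mode)


def network_flux(
    net: PathwayNetwork,
    exits: Iterable[str] | None = None,
    pair_mode: str = "ordered",
) -> float:
    """NF: the NE sum restricted to destinations in the exit set.

    ``exits`` defaults to :func:`detect_exits`.  With exits = all nodes, NF
    equals NE.
    """
    exit_set = frozenset(exits) if exits is not None else detect_exits(net)
    if not exit_set:
        raise ConfigurationError("empty exit set; network flux is undefined")
    missing = exit_set - set(net.graph)
    if missing:
        raise ConfigurationError(f"exit nodes not in network: {sorted(missing)}")
    return _efficiency_from_lengths(shortest_path_lengths(net), pair_mode, exit_set)


def relative_decrease(baseline: float, perturbed: float) -> float:
    """Percentage drop from ``baseline`` to ``perturbed``: 100·(b−p)/b."""
    if not baseline > 0:
        raise ValidationError(f"baseline must be positive, got {baseline}")
    return 100.0 * (baseline - perturbed) / baseline


def combination_score(ne_decrease: float, nf_decrease: float) -> float:
    """Geometric mean of the two percentage decreases.

    Negative decreases (efficiency that rose under perturbation) are clamped
    to zero here, and only here, so the square root stays defined; callers
    keep the raw signed decreases for diagnostics.
    """
    return math.sqrt(max(ne_decrease, 0.0) * max(nf_decrease, 0.0))


@dataclass(frozen=True)
class CompoundMetrics:
    """NE/NF of the perturbed network for one compound, plus derived scores.

    ``ne_relative``/``nf_relative`` are percent of the uniform-weight
    baseline (100 = untouched); decreases are their complements to 100;
    ``combination`` is the geometric mean of the decreases.
    """

    compound: str
    ne: float
    nf: float
    ne_relative: float
    nf_relative: float
    ne_decrease: float
    nf_decrease: float
    combination: float


def evaluate_compound(
    net: PathwayNetwork,
    matrix: ScoreMatrix,
    compound: str,
    exits: Iterable[str] | None = None,
    pair_mode: str = "ordered",
    constant: float = 2.30,
    baseline_ne: float | None = None,
    baseline_nf: float | None = None,
) -> CompoundMetrics:
    """Full per-compound pipeline: profile → reweight → NE/NF → decreases.

    ``baseline_ne``/``baseline_nf`` may be passed to avoid recomputing the
    compound-free baseline when scoring many compounds.
    """
    exit_set = frozenset(exits) if exits is not None else detect_exits(net)
    if baseline_ne is None:
        baseline_ne = network_efficiency(net, pair_mode)
    if baseline_nf is None:
        baseline_nf = network_flux(net, exit_set, pair_mode)
    profile = build_profile(matrix, compound, constant=constant,
                            floor=net.weight_floor, cap=net.weight_cap)
    attacked = apply_profile(net, profile)
    lengths = shortest_path_lengths(attacked)
    ne = _efficiency_from_lengths(lengths, pair_mode)
    nf = _efficiency_from_lengths(lengths, pair_mode, exit_set)
    ne_dec = relative_decrease(baseline_ne, ne)
    nf_dec = relative_decrease(baseline_nf, nf)
    return CompoundMetrics(
        compound=compound,
        ne=ne,
        nf=nf,
        ne_relative=100.0 - ne_dec,
        nf_relative=100.0 - nf_dec,
        ne_decrease=ne_dec,
        nf_decrease=nf_dec,
        combination=combination_score(ne_dec, nf_dec),
    )


def evaluate_all(
    net: PathwayNetwork,
    matrix: ScoreMatrix,
    compounds: Sequence[str] | None = None,
    exits: Iterable[str] | None = None,
    pair_mode: str = "ordered",
    constant: float = 2.30,
) -> list[CompoundMetrics]:
    """Score every compound (or the given subset) against one network."""
    exit_set = frozenset(exits) if exits is not None else detect_exits(net)
    base_lengths = shortest_path_lengths(net)
    baseline_ne = _efficiency_from_lengths(base_lengths, pair_mode)
    baseline_nf = _efficiency_from_lengths(base_lengths, pair_mode, exit_set)
    return [
        evaluate_compound(
            net, matrix, c, exit_set, pair_mode, constant,
            baseline_ne=baseline_ne, baseline_nf=baseline_nf,
        )
        for c in (compounds if compounds is not None else matrix.compounds)
    ]
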