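"""Seeded generators for pathway-like networks and docking-score matrices,
plus loaders for the bundled fixtures.

``generate_network`` emulates the statistical shape of a curated signalling
pathway: a directed acyclic graph with a designated receptor (source) layer,
a terminal exit layer of pure sinks, guaranteed receptor→exit reachability
for every node, and heavy-tailed out-degrees from preferential attachment.
``generate_scores`` plants known multi-target binders into an otherwise
noisy compound × target docking matrix, so that rank-recovery of the planted
potencies can be tested end to end.

Bundled fixtures: the 19-target reference-ligand docking scores, the
21-compound activity table (fractional inhibition at 34 µM with NE/NF
decreases, the printed and the recomputed combination score, and
glycoside/drug flags), and a curated 64-node/91-edge platelet-aggregation
network.  The network fixture is a synthetic curation: a best-effort
approximation of the published platelet pathway assembled from public
pathway knowledge under the 64/91 count constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pathflux.errors import ConfigurationError, LookupMismatchError, ValidationError
from pathflux.metrics import combination_score
from pathflux.network import NodeRecord, PathwayNetwork, read_network
from pathflux.perturbation import ScoreMatrix
from pathflux.screening import ActivityTable

FIXTURES = ("targets_table1", "compounds_table2", "platelet_network")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic pathway/score generators.

    Defaults mirror the curated platelet network's size (64 nodes, 91
    edges), a handful of agonist receptors feeding one terminal aggregation
    event, and a docking-score noise of 0.25 score units (a realistic
    rescoring scatter for a ~5 kcal/mol-scale scoring function).
    """

    node_count: int = 64
    edge_count: int = 91
    receptor_count: int = 6
    exit_count: int = 1
    attachment_bias: float = 1.0
    score_noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.node_count < 3:
            raise ConfigurationError("need at least 3 nodes")
        if self.receptor_count < 1 or self.exit_count < 1:
            raise ConfigurationError("need at least one receptor and one exit")
        if self.receptor_count + self.exit_count >= self.node_count:
            raise ConfigurationError(
                "receptor_count + exit_count must be smaller than node_count"
            )
        if self.edge_count < self.node_count - 1:
            raise ConfigurationError(
                f"edge_count {self.edge_count} below the reachability budget "
                f"(node_count - 1 = {self.node_count - 1})"
            )
        if not self.attachment_bias > 0:
            raise ConfigurationError("attachment_bias must be positive")
        if self.score_noise_sd < 0:
            raise ConfigurationError("score_noise_sd must be nonnegative")
        # forward DAG capacity: u -> v with u non-exit, v non-receptor, u < v
        n, r, e = self.node_count, self.receptor_count, self.exit_count
        capacity = sum(
            max(0, n - max(u + 1, r)) for u in range(n - e)
        )
        if self.edge_count > capacity:
            raise ConfigurationError(
                f"edge_count {self.edge_count} exceeds DAG capacity {capacity}"
            )
        return self


def _node_ids(cfg: GeneratorConfig) -> list[str]:
    r, e = cfg.receptor_count, cfg.exit_count
    k = cfg.node_count - r - e
    return (
        [f"R{i + 1}" for i in range(r)]
        + [f"N{i + 1}" for i in range(k)]
        + [f"X{i + 1}" for i in range(e)]
    )


def generate_network(cfg: GeneratorConfig) -> PathwayNetwork:
    """Seeded scale-free-ish directed pathway with receptor sources and sinks.

    Construction: a backbone path R1 → N1 → … → Nk → X1 plus one out-link per
    extra receptor and one in-link per extra exit (every node ends up on a
    receptor→exit path), then extra forward edges whose sources are drawn
    with probability proportional to out-degree + ``attachment_bias``.
    The result is acyclic, its only sinks are the exit layer, and identical
    configs yield identical edge lists.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ids = _node_ids(cfg)
    n, r, e = cfg.node_count, cfg.receptor_count, cfg.exit_count
    k = n - r - e
    if k < 1:
        raise ConfigurationError("need at least one intermediate node")

    backbone = [ids[0]] + ids[r : r + k] + [ids[r + k]]
    edges: list[tuple[str, str]] = list(zip(backbone, backbone[1:]))
    edge_set = set(edges)
    index = {node: i for i, node in enumerate(ids)}

    def add(u: str, v: str) -> bool:
        if u == v or (u, v) in edge_set:
            return False
        edges.append((u, v))
        edge_set.add((u, v))
        return True

    # each extra receptor feeds a random intermediate
    for receptor in ids[1:r]:
        add(receptor, ids[r + int(rng.integers(k))])
    # each extra exit drains from a random non-exit node
    for exit_node in ids[r + k + 1 :]:
        while not add(ids[int(rng.integers(n - e))], exit_node):
            pass
    if len(edges) > cfg.edge_count:
        raise ConfigurationError(
            f"edge_count {cfg.edge_count} too small for the connectivity "
            f"scaffold ({len(edges)} edges)"
        )

    out_degree = {node: 0.0 for node in ids}
    for u, _ in edges:
        out_degree[u] += 1.0
    sources = ids[: n - e]  # exits stay sinks
    while len(edges) < cfg.edge_count:
        weights = np.array([out_degree[u] + cfg.attachment_bias for u in sources])
        u = sources[int(rng.choice(len(sources), p=weights / weights.sum()))]
        lo = max(index[u] + 1, r)  # forward, never into the receptor layer
        candidates = [v for v in ids[lo:] if (u, v) not in edge_set and v != u]
        if not candidates:
            continue
        v = candidates[int(rng.integers(len(candidates)))]
        add(u, v)
        out_degree[u] += 1.0

    nodes = (
        [NodeRecord(i, kind="protein") for i in ids[: r + k]]
        + [NodeRecord(i, kind="event") for i in ids[r + k :]]
    )
    return PathwayNetwork.from_records(nodes, edges, exit_nodes=ids[r + k :])


def generate_scores(
    net: PathwayNetwork,
    n_compounds: int,
    planted: Mapping[str, tuple[Sequence[str], float]] | None = None,
    cfg: GeneratorConfig | None = None,
    n_targets: int = 19,
) -> ScoreMatrix:
    """Compound × target docking matrix with planted multi-target binders.

    Targets are the planted targets plus a seeded draw of further non-exit
    nodes up to ``n_targets``; reference scores are drawn from the bundled
    19 reference-ligand docking scores.  A planted compound scores
    ``potency · reference + N(0, score_noise_sd)`` on its targets; every
    other cell is pure noise.  Scores are floored at 0.
    """
    cfg = (cfg or GeneratorConfig()).validate()
    planted = dict(planted or {})
    rng = np.random.default_rng(cfg.seed + 1)

    exit_set = frozenset(net.exit_nodes) or frozenset(
        v for v in net.graph if net.graph.out_degree(v) == 0
    )
    planted_targets: list[str] = []
    for compound, (tset, potency) in planted.items():
        if not 0.0 <= potency <= 1.0:
            raise ValidationError(f"{compound}: potency {potency} outside [0, 1]")
        for t in tset:
            if t not in net.graph:
                raise LookupMismatchError(f"planted target {t!r} not in network")
            if t not in planted_targets:
                planted_targets.append(t)
    pool = sorted(set(net.graph) - exit_set - set(planted_targets))
    extra = max(0, min(n_targets, len(pool) + len(planted_targets)) - len(planted_targets))
    targets = planted_targets + [
        pool[i] for i in sorted(rng.choice(len(pool), size=extra, replace=False))
    ]

    table1 = load_fixture("targets_table1")
    ref_pool = table1["score"].to_numpy(float)
    references = {
        t: float(ref_pool[int(rng.integers(len(ref_pool)))]) for t in targets
    }

    compounds = list(planted)
    compounds += [f"C{i + 1:03d}" for i in range(n_compounds - len(compounds))]
    if len(compounds) != n_compounds:
        raise ConfigurationError("n_compounds smaller than the planted set")

    scores = np.zeros((n_compounds, len(targets)))
    for i, compound in enumerate(compounds):
        tset, potency = planted.get(compound, ((), 0.0))
        hit = set(tset)
        for j, t in enumerate(targets):
            base = potency * references[t] if t in hit else 0.0
            noise = rng.normal(0.0, cfg.score_noise_sd) if cfg.score_noise_sd else 0.0
            scores[i, j] = max(0.0, base + noise)
    return ScoreMatrix(compounds, targets, scores, references)


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("pathflux.data") / name


def load_fixture(name: str):
    """Load a bundled fixture.

    ``targets_table1`` → DataFrame of the 19 docking targets with their
    reference-ligand scores; ``compounds_table2`` → DataFrame of the 21
    assayed compounds (inhibition, NE/NF decreases, printed combination
    score plus a ``combination_recomputed`` column from the geometric-mean
    rule, flags); ``platelet_network`` → the curated
    :class:`PathwayNetwork`.
    """
    if name == "targets_table1":
        return pd.read_csv(_data_path("table1_targets.csv"))
    if name == "compounds_table2":
        df = pd.read_csv(_data_path("table2_compounds.csv"))
        df["combination_recomputed"] = [
            combination_score(a, b)
            for a, b in zip(df["ne_decrease"], df["nf_decrease"])
        ]
        return df
    if name == "platelet_network":
        with resources.as_file(_data_path("platelet_network.tsv")) as p:
            return read_network(p, format="tsv")
    raise LookupMismatchError(f"unknown fixture {name!r}; choose from {FIXTURES}")


def reference_scores() -> dict[str, float]:
    """Target id → reference-ligand docking score from the bundled table."""
    df = load_fixture("targets_table1")
    return dict(zip(df["target"], df["score"].astype(float)))


def activity_fixture() -> ActivityTable:
    """The 21-compound activity table as an :class:`ActivityTable`."""
    df = load_fixture("compounds_table2")
    return ActivityTable(df[["compound", "inhibition", "glycoside", "is_drug"]])
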