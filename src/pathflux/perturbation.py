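"""Docking-score → edge-weight perturbation.

A compound's docking score against a pathway target is converted into an
edge value (EV) for every edge leaving that target:

    EV = clamp(10 ** (constant * score / reference_score), floor, cap)

with constant 2.30, floor 10 and cap 99999 by default.  A compound scoring
exactly as well as the target's reference ligand therefore sets the target's
outgoing edges to 10**2.30 ≈ 199.5 (twenty-fold the baseline weight of 10);
weaker binders decay exponentially toward the floor, where they leave the
network untouched.  Higher docking score = stronger predicted binding =
heavier (more blocked) downstream edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pathflux.errors import LookupMismatchError, ValidationError
from pathflux.network import DEFAULT_WEIGHT, WEIGHT_CAP, WEIGHT_FLOOR, PathwayNetwork

logger = logging.getLogger(__name__)

EXPONENT_CONSTANT = 2.30


@dataclass
class ScoreMatrix:
    """Compound × target docking scores plus per-target reference scores.

    ``scores[i, j]`` is the docking score of ``compounds[i]`` against
    ``targets[j]`` (dimensionless; higher = stronger predicted binding).
    NaN marks a missing score.  ``reference_scores`` holds the docking score
    of each target's reference ligand (co-crystallised ligand or known
    inhibitor) and must be strictly positive.
    """

    compounds: list[str]
    targets: list[str]
    scores: np.ndarray
    reference_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.compounds), len(self.targets)):
            raise ValidationError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.compounds)} compounds x {len(self.targets)} targets"
            )
        if len(set(self.compounds)) != len(self.compounds):
            raise ValidationError("duplicate compound ids")
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError("duplicate target ids")
        for t in self.targets:
            ref = self.reference_scores.get(t)
            if ref is None:
                raise ValidationError(f"target {t!r} has no reference score")
            if not ref > 0:
                raise ValidationError(f"target {t!r}: reference score {ref} must be > 0")

    @classmethod
    def from_csv(cls, scores_path: str | Path, refs_path: str | Path) -> "ScoreMatrix":
        """Load from a scores CSV (first column compound id, one column per
        target) and a reference CSV with ``target`` and ``score`` columns."""
        df = pd.read_csv(scores_path, index_col=0)
        refs = pd.read_csv(refs_path)
        if not {"target", "score"} <= set(refs.columns):
            raise ValidationError(f"{refs_path}: needs 'target' and 'score' columns")
        reference = dict(zip(refs["target"].astype(str), refs["score"].astype(float)))
        return cls(
            compounds=[str(c) for c in df.index],
            targets=[str(t) for t in df.columns],
            scores=df.to_numpy(dtype=float),
            reference_scores=reference,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.compounds, columns=self.targets)

    def row(self, compound: str) -> dict[str, float]:
        try:
            i = self.compounds.index(compound)
        except ValueError:
            raise LookupMismatchError(f"unknown compound {compound!r}") from None
        return dict(zip(self.targets, self.scores[i]))


@dataclass(frozen=True)
class PerturbationProfile:
    """Per-compound map target id → edge value for the target's out-edges."""

    compound: str
    edge_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, ev in self.edge_values.items():
            if not (WEIGHT_FLOOR <= ev <= WEIGHT_CAP):
                raise ValidationError(
                    f"{self.compound}: EV for {t!r} = {ev} outside "
                    f"[{WEIGHT_FLOOR}, {WEIGHT_CAP}]"
                )


def edge_value(
    score: float,
    reference_score: float,
    constant: float = EXPONENT_CONSTANT,
    floor: float = WEIGHT_FLOOR,
    cap: float = WEIGHT_CAP,
) -> float:
    """Edge value for a single (score, reference) pair.

    Monotone nondecreasing in ``score``; equal to ``floor`` whenever
    score/reference <= log10(floor)/constant (~0.4348 at defaults).
    """
    if not reference_score > 0:
        raise ValidationError(f"reference score must be positive, got {reference_score}")
    raw = 10.0 ** (constant * score / reference_score)
    return min(max(raw, floor), cap)


def build_profile(
    matrix: ScoreMatrix,
    compound: str,
    constant: float = EXPONENT_CONSTANT,
    floor: float = WEIGHT_FLOOR,
    cap: float = WEIGHT_CAP,
) -> PerturbationProfile:
    """One edge value per matrix target for ``compound``.

    Missing (NaN) scores are treated as 0 — no predicted binding, hence an
    EV at the floor — and logged.
    """
    row = matrix.row(compound)
    evs: dict[str, float] = {}
    for target, score in row.items():
        if np.isnan(score):
            logger.info("compound %s: missing score for %s treated as 0", compound, target)
            score = 0.0
        evs[target] = edge_value(score, matrix.reference_scores[target], constant, floor, cap)
    return PerturbationProfile(compound, evs)


def apply_profile(
    net: PathwayNetwork,
    profile: PerturbationProfile,
    initial_weight: float = DEFAULT_WEIGHT,
) -> PathwayNetwork:
    """Reweight a copy of ``net`` according to ``profile``.

    Every edge whose source node is a profiled target carries that target's
    edge value; every other edge carries ``initial_weight``.  Topology is
    untouched and the input network is not modified.  A profiled target
    absent from the network raises :class:`LookupMismatchError` — silently
    dropping it would bias the efficiency statistics.
    """
    missing = [t for t in profile.edge_values if t not in net.graph]
    if missing:
        raise LookupMismatchError(
            f"profile targets not in network: {sorted(missing)}"
        )
    out = net.copy()
    for u, v in out.graph.edges:
        ev = profile.edge_values.get(u)
        out.graph[u][v]["weight"] = float(ev) if ev is not None else float(initial_weight)
    return out.validate()
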