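"""Compound ranking and correlation against experimental activity.

Compounds are ranked by the decrease they cause in network efficiency,
network flux, or the combination score — the larger the decrease, the more
potent the predicted inhibitor.  Predictions are validated by the Pearson
correlation (with least-squares slope and intercept) between a predictor
column and measured fractional inhibition of platelet aggregation, over all
compounds or over the nonglycoside subset (glycosides carry flexible sugar
moieties that degrade docking-score reliability and are flagged in the
activity table).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pathflux.errors import (
    ConfigurationError,
    LookupMismatchError,
    ValidationError,
    ZeroVarianceError,
)
from pathflux.metrics import CompoundMetrics
from pathflux.perturbation import ScoreMatrix

RANKING_KEYS = ("ne_decrease", "nf_decrease", "combination")
SUBSETS = ("all", "nonglycoside")

METRICS_COLUMNS = [
    "compound", "ne", "nf", "ne_relative", "nf_relative",
    "ne_decrease", "nf_decrease", "combination",
]


@dataclass
class ActivityTable:
    """Experimental activity: fractional inhibition plus compound flags."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compound", "inhibition", "glycoside", "is_drug"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"activity table missing columns {sorted(missing)}")
        df = self.frame.copy()
        df["compound"] = df["compound"].astype(str)
        df["glycoside"] = df["glycoside"].astype(bool)
        df["is_drug"] = df["is_drug"].astype(bool)
        if df["compound"].duplicated().any():
            dups = df.loc[df["compound"].duplicated(), "compound"].tolist()
            raise ValidationError(f"duplicate compound ids in activity table: {dups}")
        bad = df[(df["inhibition"] < 0) | (df["inhibition"] > 1)]
        if len(bad):
            raise ValidationError(
                f"inhibition outside [0, 1] for {bad['compound'].tolist()}"
            )
        self.frame = df

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivityTable":
        return cls(pd.read_csv(path))

    def subset(self, which: str = "all") -> pd.DataFrame:
        if which not in SUBSETS:
            raise ConfigurationError(f"subset must be one of {SUBSETS}")
        if which == "nonglycoside":
            return self.frame[~self.frame["glycoside"]].reset_index(drop=True)
        return self.frame.copy()


@dataclass(frozen=True)
class CorrelationRecord:
    predictor: str
    subset: str
    n: int
    pearson_r: float
    slope: float
    intercept: float


@dataclass
class ScreeningReport:
    """Ranked metrics table plus any correlation records computed."""

    ranking: pd.DataFrame
    key: str
    correlations: list[CorrelationRecord] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "key": self.key,
                "ranking": self.ranking.to_dict(orient="records"),
                "correlations": [asdict(c) for c in self.correlations],
            },
            indent=2,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.ranking.to_csv(path, sep="\t", index=False, float_format="%.4f")


def _metrics_frame(metrics: Sequence[CompoundMetrics] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(metrics, pd.DataFrame):
        if "compound" not in metrics.columns:
            raise ValidationError("metrics table needs a 'compound' column")
        df = metrics.copy()
        df["compound"] = df["compound"].astype(str)
        return df
    return pd.DataFrame([asdict(m) for m in metrics], columns=METRICS_COLUMNS)


def rank_compounds(
    metrics: Sequence[CompoundMetrics] | pd.DataFrame,
    key: str = "combination",
) -> ScreeningReport:
    """Stable descending sort by ``key``; ties broken by compound id."""
    if key not in RANKING_KEYS:
        raise ConfigurationError(f"ranking key must be one of {RANKING_KEYS}")
    df = _metrics_frame(metrics)
    if df.empty:
        raise ValidationError("cannot rank an empty metrics list")
    if key not in df.columns:
        raise ConfigurationError(f"metrics table has no column {key!r}")
    ranked = df.sort_values(
        by=[key, "compound"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ScreeningReport(ranking=ranked, key=key)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; the r of the least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r needs two equal-length 1-d vectors")
    if len(x) < 3:
        raise ValidationError(f"need at least 3 points, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y)[0])


def _correlate_vectors(
    x: np.ndarray, y: np.ndarray, predictor: str, subset: str
) -> CorrelationRecord:
    if len(x) < 3:
        raise ValidationError(
            f"need at least 3 compounds after subsetting, got {len(x)}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    fit = stats.linregress(x, y)
    return CorrelationRecord(
        predictor=predictor,
        subset=subset,
        n=int(len(x)),
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def correlate(
    metrics: Sequence[CompoundMetrics] | pd.DataFrame,
    activity: ActivityTable,
    predictor: str = "combination",
    subset: str = "all",
) -> CorrelationRecord:
    """Pearson r (and least-squares fit) of a predictor vs inhibition.

    Joins the metrics table to the activity table on compound id; every
    metrics compound must be present in the activity table.
    """
    df = _metrics_frame(metrics)
    if predictor not in df.columns:
        raise ConfigurationError(f"metrics table has no predictor column {predictor!r}")
    act = activity.subset(subset)
    merged = df[["compound", predictor]].merge(act, on="compound", how="inner")
    unmatched = sorted(set(df["compound"]) - set(activity.frame["compound"]))
    if unmatched:
        raise LookupMismatchError(f"compounds missing from activity table: {unmatched}")
    return _correlate_vectors(
        merged[predictor].to_numpy(float),
        merged["inhibition"].to_numpy(float),
        predictor,
        subset,
    )


def single_target_correlation(
    matrix: ScoreMatrix,
    activity: ActivityTable,
    target: str,
    subset: str = "all",
) -> CorrelationRecord:
    """Baseline: correlate one target's raw docking scores with inhibition.

    This is the single-target alternative the network statistics are
    compared against; no network is involved.
    """
    if target not in matrix.targets:
        raise LookupMismatchError(f"unknown target {target!r}")
    col = matrix.to_frame()[target]
    act = activity.subset(subset)
    merged = act.merge(
        col.rename("score"), left_on="compound", right_index=True, how="inner"
    )
    if len(merged) < len(act):
        missing = sorted(set(act["compound"]) - set(col.index))
        raise LookupMismatchError(f"compounds missing from score matrix: {missing}")
    return _correlate_vectors(
        merged["score"].to_numpy(float),
        merged["inhibition"].to_numpy(float),
        f"docking:{target}",
        subset,
    )
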