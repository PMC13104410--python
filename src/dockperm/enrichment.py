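"""Enrichment factor and ROC-AUC evaluation of docking/scoring combinations.

A seeded database (known actives mixed into a decoy set) is ranked by each
docking/scoring combination.  Two complementary measures quantify how well
the combination discriminates:

* **Enrichment factor** at a top fraction f:

      EF = (Hits_sel / Hits_tot) × (NC_tot / NC_sel),

  where ``NC_sel = floor(f × NC_tot)`` compounds are selected and
  ``Hits_sel`` of the ``Hits_tot`` actives land in the selection.  Its
  ceiling, reached when the selection is exactly the actives, is
  ``NC_tot / Hits_tot``.

* **ROC-AUC**, the probability that a randomly chosen active outscores a
  randomly chosen decoy.  Computed here by the rank-sum (pairwise
  concordance) formulation with ties credited ½, which equals the
  trapezoidal area under the tie-aware ROC curve.  The standard error uses
  the Hanley–McNeil formula; significance against AUC = 0.5 uses the normal
  approximation to the Mann–Whitney statistic.  Quality bands: ≥ 0.9
  excellent, [0.8, 0.9) good, [0.7, 0.8) fair, [0.5, 0.7) poor, < 0.5
  failure.

Compounds with a missing score for a combination are excluded from that
combination's ranking and from its NC_tot (a compound a docking run never
retrieved is not a scored member of that run's database).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up, significance_stars
from .pose_io import LabeledScoreTable, ScoreTableError

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "ROCResult",
    "rank",
    "enrichment_factor",
    "max_enrichment_factor",
    "roc_auc",
    "auc_band",
    "EnrichmentScreen",
    "EnrichmentScreenResults",
]

AUC_BANDS = (  # closed lower bound, per-band label, checked top-down
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "fair"),
    (0.5, "poor"),
)


def auc_band(auc: float) -> str:
    for lo, label in AUC_BANDS:
        if auc >= lo:
            return label
    return "failure"


@dataclass
class RankedList:
    """A database ranked by one combination, best score first.

    ``scores`` are orientation-adjusted (larger = better) and aligned with
    ``ids``/``labels``; ``unscored_ids`` are compounds without a score for
    this combination, excluded from the ranking.
    """

    ids: list[str]
    labels: list[str]
    scores: np.ndarray
    combination: str
    orientation: str
    unscored_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_actives(self) -> int:
        return sum(lab == "active" for lab in self.labels)

    @property
    def n_decoys(self) -> int:
        return sum(lab == "decoy" for lab in self.labels)


def rank(
    table: LabeledScoreTable,
    combination: str,
    orientation: str | None = None,
) -> RankedList:
    """Rank scored compounds by one combination; ties keep input order."""
    if combination not in table.score_columns:
        raise KeyError(f"no score column {combination!r}")
    orientation = orientation or table.orientations.get(combination, "higher")
    col = table.data[combination]
    scored = col.notna()
    unscored_ids = list(col.index[~scored])
    values = col[scored].to_numpy(dtype=float)
    adjusted = values if orientation == "higher" else -values
    order = np.argsort(-adjusted, kind="stable")  # stable: ties keep input order
    ids = list(col.index[scored][order])
    labels = list(table.data.loc[scored, "label"].iloc[order])
    if "active" not in labels:
        raise ScoreTableError(
            f"no scored actives for combination {combination!r}"
        )
    return RankedList(
        ids=ids,
        labels=labels,
        scores=adjusted[order],
        combination=combination,
        orientation=orientation,
        unscored_ids=unscored_ids,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment factor at a top fraction, with all its counts."""

    combination: str
    fraction: float
    hits_sel: int
    hits_tot: int
    nc_tot: int
    nc_sel: int

    @property
    def ef(self) -> float:
        return (self.hits_sel / self.hits_tot) * (self.nc_tot / self.nc_sel)

    @property
    def ef_rounded(self) -> float:
        """1-decimal reporting value."""
        return round_half_up(self.ef, 1)

    @property
    def ef_max(self) -> float:
        return self.nc_tot / self.hits_tot


def enrichment_factor(ranked: RankedList, fraction: float = 0.10) -> EnrichmentResult:
    """EF over the top ``floor(fraction × NC_tot)`` of the ranked database."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    nc_tot = len(ranked)
    nc_sel = math.floor(fraction * nc_tot)
    if nc_sel == 0:
        raise ValueError(
            f"selection of fraction {fraction} of {nc_tot} compounds is empty"
        )
    hits_tot = ranked.n_actives
    if hits_tot == 0 or ranked.n_decoys == 0:
        raise ScoreTableError("enrichment needs at least one active and one decoy")
    hits_sel = sum(lab == "active" for lab in ranked.labels[:nc_sel])
    return EnrichmentResult(
        combination=ranked.combination,
        fraction=fraction,
        hits_sel=hits_sel,
        hits_tot=hits_tot,
        nc_tot=nc_tot,
        nc_sel=nc_sel,
    )


def max_enrichment_factor(nc_tot: int, hits_tot: int) -> float:
    """Ceiling EF: all actives recovered in a selection of exactly that size."""
    if hits_tot < 1:
        raise ValueError("need at least one active")
    if hits_tot > nc_tot:
        raise ValueError("more actives than compounds")
    return nc_tot / hits_tot


@dataclass
class ROCResult:
    """Tie-aware ROC curve with AUC, Hanley–McNeil SE and null p-value."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    se: float
    p_vs_half: float
    n_actives: int
    n_decoys: int
    combination: str = ""

    @property
    def band(self) -> str:
        return auc_band(self.auc)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_vs_half)


def _hanley_mcneil_se(auc: float, n_a: int, n_d: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_a - 1) * (q1 - auc * auc)
        + (n_d - 1) * (q2 - auc * auc)
    ) / (n_a * n_d)
    return math.sqrt(max(var, 0.0))


def roc_auc(ranked: RankedList) -> ROCResult:
    """ROC curve and AUC for one ranked database.

    AUC comes from midranks (Mann–Whitney U / n_a·n_d, ties ½); the curve
    points come from scikit-learn's tie-aware ``roc_curve`` and integrate
    (trapezoid) to the same number.
    """
    from sklearn.metrics import roc_curve

    y = np.array([lab == "active" for lab in ranked.labels], dtype=int)
    n_a = int(y.sum())
    n_d = int(y.size - n_a)
    if n_a == 0 or n_d == 0:
        raise ScoreTableError("ROC needs at least one active and one decoy")
    scores = np.asarray(ranked.scores, dtype=float)
    ranks = stats.rankdata(scores)  # midranks
    auc = (ranks[y == 1].sum() - n_a * (n_a + 1) / 2.0) / (n_a * n_d)
    se = _hanley_mcneil_se(auc, n_a, n_d)
    mwu = stats.mannwhitneyu(
        scores[y == 1], scores[y == 0], alternative="two-sided", method="asymptotic"
    )
    fpr, tpr, _ = roc_curve(y, scores)
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        auc=float(auc),
        se=float(se),
        p_vs_half=float(mwu.pvalue),
        n_actives=n_a,
        n_decoys=n_d,
        combination=ranked.combination,
    )


class EnrichmentScreen:
    """Model: a seeded actives+decoys database screened by several combinations.

    Parameters
    ----------
    table
        Labelled score table; one score column per docking/scoring
        combination, NaN for compounds a run did not retrieve.
    fraction
        Top fraction for the enrichment factor (default 0.10).
    """

    def __init__(self, table: LabeledScoreTable, fraction: float = 0.10) -> None:
        table.require_both_classes()
        self.table = table
        self.fraction = float(fraction)

    def fit(self) -> "EnrichmentScreenResults":
        ranked = {c: rank(self.table, c) for c in self.table.score_columns}
        efs = {c: enrichment_factor(r, self.fraction) for c, r in ranked.items()}
        rocs = {c: roc_auc(r) for c, r in ranked.items()}
        return EnrichmentScreenResults(self.fraction, ranked, efs, rocs)


class EnrichmentScreenResults:
    """Per-combination EF and ROC results with a report table."""

    def __init__(
        self,
        fraction: float,
        ranked: dict[str, RankedList],
        efs: dict[str, EnrichmentResult],
        rocs: dict[str, ROCResult],
    ) -> None:
        self.fraction = fraction
        self.ranked = ranked
        self.efs = efs
        self.rocs = rocs

    @property
    def combinations(self) -> list[str]:
        return list(self.ranked)

    def summary(self) -> pd.DataFrame:
        """One row per combination: EF, max EF, AUC ± SE, stars, band, n."""
        pct = int(round(self.fraction * 100))
        rows = {}
        for c in self.combinations:
            ef, roc = self.efs[c], self.rocs[c]
            rows[c] = {
                f"EF {pct}%": ef.ef_rounded,
                "max EF": round_half_up(ef.ef_max, 1),
                "ROC-AUC": round_half_up(roc.auc, 2),
                "SE": round_half_up(roc.se, 2),
                "p": roc.p_vs_half,
                "sig": roc.stars,
                "band": roc.band,
                "n": len(self.ranked[c]),
            }
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "combination"
        return frame
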