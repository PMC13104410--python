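"""Protocol selection: declare docking/scoring combinations valid, call hits.

A combination is retained for virtual screening when its validation results
clear configurable thresholds; the default — and most stringent — criterion
is an "excellent" ROC-AUC band (AUC ≥ 0.9).  Optional additional criteria:
minimum redocking success rate and minimum enrichment factor.

A screened compound is called a hit when it is flagged by *any* validated
combination under *either* docking algorithm (union rule, fail-closed: with
no validated combination the pipeline refuses to call hits).  "Flagged" is
operationally defined here as membership of the top-fraction selection used
for the enrichment factor (default top 10%); this per-compound affinity rule
is configurable because validation thresholds, not the flagging rule, are
the part of the protocol that is fixed by the benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, ROCResult
from .redock import SuccessRate

__all__ = [
    "ValidationCriteria",
    "ComboVerdict",
    "HitList",
    "validate_combo",
    "top_fraction_ids",
    "flag_above_threshold",
    "select_hits",
]

_BAND_ORDER = {"failure": 0, "poor": 1, "fair": 2, "good": 3, "excellent": 4}


@dataclass(frozen=True)
class ValidationCriteria:
    """Thresholds a combination must clear to be used for screening."""

    required_band: str = "excellent"
    min_success_rate: float | None = None  # percent
    min_ef: float | None = None

    def __post_init__(self) -> None:
        if self.required_band not in _BAND_ORDER:
            raise ValueError(f"unknown band {self.required_band!r}")


@dataclass
class ComboVerdict:
    """Outcome of validating one docking/scoring combination."""

    combination: str
    valid: bool
    auc: float
    auc_band: str
    ef: float | None = None
    success_rate: float | None = None
    average_rmsd: float | None = None
    reasons: list[str] = field(default_factory=list)


def validate_combo(
    combination: str,
    roc: ROCResult,
    enr: EnrichmentResult | None = None,
    summary_success_rate: SuccessRate | float | None = None,
    average_rmsd: float | None = None,
    criteria: ValidationCriteria = ValidationCriteria(),
) -> ComboVerdict:
    """Apply the validation thresholds to one combination's results.

    The ROC result is mandatory; enrichment and redocking summaries are only
    consulted when the corresponding optional criterion is configured.  All
    threshold outcomes are recorded in ``reasons``.
    """
    for obj, what in ((roc, "ROC"), (enr, "enrichment")):
        if obj is not None and obj.combination and obj.combination != combination:
            raise ValueError(
                f"{what} result is for {obj.combination!r}, not {combination!r}"
            )
    reasons: list[str] = []
    ok = True

    band = roc.band
    band_ok = _BAND_ORDER[band] >= _BAND_ORDER[criteria.required_band]
    reasons.append(
        f"ROC-AUC {roc.auc:.2f} band '{band}' "
        f"{'meets' if band_ok else 'below'} required '{criteria.required_band}'"
    )
    ok &= band_ok

    sr_pct: float | None = None
    if summary_success_rate is not None:
        sr_pct = float(summary_success_rate)
    if criteria.min_success_rate is not None:
        if sr_pct is None:
            raise ValueError("success-rate criterion configured but no value given")
        sr_ok = sr_pct >= criteria.min_success_rate
        reasons.append(
            f"success rate {sr_pct:.0f}% "
            f"{'≥' if sr_ok else '<'} {criteria.min_success_rate:.0f}%"
        )
        ok &= sr_ok

    ef_val = enr.ef if enr is not None else None
    if criteria.min_ef is not None:
        if ef_val is None:
            raise ValueError("EF criterion configured but no enrichment result given")
        ef_ok = ef_val >= criteria.min_ef
        reasons.append(f"EF {ef_val:.1f} {'≥' if ef_ok else '<'} {criteria.min_ef:.1f}")
        ok &= ef_ok

    return ComboVerdict(
        combination=combination,
        valid=bool(ok),
        auc=roc.auc,
        auc_band=band,
        ef=ef_val,
        success_rate=sr_pct,
        average_rmsd=average_rmsd,
        reasons=reasons,
    )


def top_fraction_ids(
    scores: pd.Series,
    fraction: float = 0.10,
    orientation: str = "higher",
) -> list[str]:
    """Ids in the top ``floor(fraction × n)`` of a screening score column.

    NaN scores are excluded; ties keep input order, mirroring the ranking
    used for the enrichment factor.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    col = scores.dropna()
    n_sel = math.floor(fraction * len(col))
    if n_sel == 0:
        raise ValueError("empty top-fraction selection")
    adjusted = col.to_numpy(dtype=float)
    if orientation == "lower":
        adjusted = -adjusted
    order = np.argsort(-adjusted, kind="stable")
    return list(col.index[order][:n_sel])


def flag_above_threshold(
    scores: pd.Series,
    threshold: float,
    orientation: str = "higher",
) -> list[str]:
    """Ids whose score clears an affinity threshold (alternative flag rule).

    With ``orientation='higher'`` a compound is flagged when score ≥
    threshold; with 'lower', when score ≤ threshold.  Typical use: threshold
    set at the reference ligand's own score.  NaN scores are never flagged.
    """
    col = scores.dropna()
    if orientation == "lower":
        mask = col <= threshold
    else:
        mask = col >= threshold
    return list(col.index[mask])


@dataclass
class HitList:
    """Compounds called as receptor binders, with per-hit provenance."""

    hits: dict[str, list[str]]  # compound id -> validated combinations flagging it

    @property
    def ids(self) -> list[str]:
        return sorted(self.hits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.ids,
                "combinations": ["; ".join(self.hits[i]) for i in self.ids],
            }
        )


def select_hits(
    flagged: Mapping[str, Iterable[str]],
    verdicts: Sequence[ComboVerdict],
) -> HitList:
    """Union of flagged compounds over the validated combinations.

    ``flagged`` maps combination name -> compound ids that combination
    flags (e.g. from :func:`top_fraction_ids`).  Compounds flagged only by
    invalid combinations are excluded.  Raises if no combination is valid.
    """
    valid = {v.combination for v in verdicts if v.valid}
    if not valid:
        raise ValueError("no validated combination: refusing to call hits")
    hits: dict[str, list[str]] = {}
    for combo, ids in flagged.items():
        if combo not in valid:
            continue
        for cid in ids:
            hits.setdefault(cid, []).append(combo)
    return HitList(hits=hits)
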