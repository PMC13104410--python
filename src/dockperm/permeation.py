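"""Franz diffusion cell permeation analysis.

Excised tissue is mounted between a donor chamber (volume ``V_d``, compound
concentration ``C0``) and an acceptor chamber (volume ``V_a``).  At each
sampling time the *entire* acceptor volume is withdrawn for assay and
replaced with fresh buffer, so the cumulative amount permeated by the n-th
sample is simply the running sum of withdrawn amounts:

    Q(t_n) = V_a × Σ_{i≤n} C_i        [µg]

(no back-dilution correction is needed; a partial-withdrawal mode with the
correction term is supported but off by default).  Under sink conditions
Q(t) is linear in t; the steady-state flux dQ/dt is the least-squares slope,
and the apparent permeability coefficient is

    P_app = (dQ/dt) / (A × C0)        [cm/s]

with the diffusion area A in cm² and C0 in µg/cm³ (≡ µg/mL).  Percentage
transport is Q(final) / dose × 100 with dose = C0 × V_d; tissue retention is
the assayed amount in the lysate as a percentage of dose.

Replicates are fitted independently and reported as mean ± sd, matching the
usual n = 6 diffusion-cell design.  A low-permeability marker (e.g. Lucifer
Yellow) gates membrane integrity; benchmark compounds of known permeability
(e.g. acyclovir, atenolol) anchor a coarse low / low-moderate /
moderate-high classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FranzExperiment",
    "FluxFit",
    "cumulative_amount",
    "steady_state_flux",
    "apparent_permeability",
    "percent_transport",
    "donor_concentration_from_extract",
    "tissue_content_percent",
    "integrity_check",
    "classify_permeability",
    "DEFAULT_BENCHMARKS",
    "FranzPermeation",
    "FranzPermeationResults",
]

#: Benchmark Papp values (cm/s) anchoring the permeability classes: an
#: integrity/exclusion marker, a low-to-moderate and a moderate-to-high
#: permeability model drug.
DEFAULT_BENCHMARKS: dict[str, float] = {
    "low": 2.92e-6,
    "low-moderate": 12.4e-6,
    "moderate-high": 47.3e-6,
}

#: Default integrity threshold for the marker Papp, cm/s (order of magnitude
#: of an intact-epithelium exclusion-marker permeability).
DEFAULT_INTEGRITY_THRESHOLD = 5e-6


@dataclass
class FranzExperiment:
    """One Franz-cell time course: sampling times and acceptor concentrations.

    ``acceptor_conc`` has shape (n_replicates, n_times) in µg/mL; times are
    minutes, strictly increasing and positive.  Volumes in mL, area in cm²,
    donor concentration in µg/mL.
    """

    times_min: np.ndarray
    acceptor_conc: np.ndarray
    c0_donor: float
    area_cm2: float
    v_acceptor_ml: float = 2.0
    v_donor_ml: float = 1.0
    withdrawal: str = "full"
    withdrawal_volume_ml: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.acceptor_conc = np.atleast_2d(np.asarray(self.acceptor_conc, dtype=float))
        if self.times_min.ndim != 1 or self.times_min.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(self.times_min <= 0) or np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        if self.acceptor_conc.shape[1] != self.times_min.size:
            raise ValueError("one concentration per sampling time per replicate")
        if np.any(self.acceptor_conc < 0):
            raise ValueError("concentrations must be non-negative")
        for value, what in (
            (self.c0_donor, "donor concentration"),
            (self.area_cm2, "diffusion area"),
            (self.v_acceptor_ml, "acceptor volume"),
            (self.v_donor_ml, "donor volume"),
        ):
            if value <= 0:
                raise ValueError(f"{what} must be positive")
        if self.withdrawal not in ("full", "partial"):
            raise ValueError("withdrawal must be 'full' or 'partial'")

    @property
    def n_replicates(self) -> int:
        return self.acceptor_conc.shape[0]

    @property
    def dose_ug(self) -> float:
        return self.c0_donor * self.v_donor_ml


def cumulative_amount(exp: FranzExperiment) -> np.ndarray:
    """Cumulative amount permeated Q, µg, shape (n_replicates, n_times).

    Full withdrawal: each sample's amount (V_a × C_i) leaves the cell, so
    Q is the running sum.  Partial withdrawal: the sampled volume V_w is
    replaced, so earlier samples only removed V_w × C_i and
    Q(t_n) = V_a × C_n + V_w × Σ_{i<n} C_i.
    """
    c = exp.acceptor_conc
    if exp.withdrawal == "full":
        return exp.v_acceptor_ml * np.cumsum(c, axis=1)
    if exp.withdrawal_volume_ml is None:
        raise ValueError("partial withdrawal requires a withdrawal volume")
    removed_before = exp.withdrawal_volume_ml * np.cumsum(c, axis=1)
    removed_before = np.concatenate(
        [np.zeros((c.shape[0], 1)), removed_before[:, :-1]], axis=1
    )
    return exp.v_acceptor_ml * c + removed_before


@dataclass(frozen=True)
class FluxFit:
    """Least-squares line through Q vs t: slope in µg/s plus diagnostics."""

    flux_ug_per_s: float
    intercept_ug: float
    r_squared: float
    n_points: int
    first_point: int  # index of the first time point in the fit window


_SECONDS_PER = {"s": 1.0, "min": 60.0, "h": 3600.0}


def steady_state_flux(
    q_ug: Sequence[float],
    times: Sequence[float],
    window: str = "all",
    r2_min: float = 0.95,
    time_unit: str = "min",
) -> FluxFit:
    """Steady-state flux dQ/dt from a linear fit of Q against time.

    ``window='all'`` fits every point; ``window='post-lag'`` drops leading
    points one at a time until the fit reaches R² ≥ ``r2_min`` or only three
    points remain, accommodating a permeation lag.  The slope is always
    returned in µg/s regardless of ``time_unit`` ('s', 'min' or 'h').
    """
    if time_unit not in _SECONDS_PER:
        raise ValueError("time_unit must be 's', 'min' or 'h'")
    q = np.asarray(q_ug, dtype=float)
    t = np.asarray(times, dtype=float)
    if q.size != t.size:
        raise ValueError("Q and time arrays must align")
    if q.size < 3:
        raise ValueError("need at least 3 points for a flux fit")
    if np.ptp(t) == 0:
        raise ValueError("zero time span")
    if window not in ("all", "post-lag"):
        raise ValueError("window must be 'all' or 'post-lag'")
    start = 0
    while True:
        res = stats.linregress(t[start:], q[start:])
        r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 1.0
        if window == "all" or r2 >= r2_min or q.size - (start + 1) < 3:
            return FluxFit(
                flux_ug_per_s=float(res.slope) / _SECONDS_PER[time_unit],
                intercept_ug=float(res.intercept),
                r_squared=r2,
                n_points=int(q.size - start),
                first_point=start,
            )
        start += 1


def apparent_permeability(flux_ug_per_s: float, area_cm2: float, c0_ug_per_ml: float) -> float:
    """P_app = flux / (A × C0), cm/s; C0 in µg/mL ≡ µg/cm³."""
    if area_cm2 <= 0 or c0_ug_per_ml <= 0:
        raise ValueError("area and donor concentration must be positive")
    return flux_ug_per_s / (area_cm2 * c0_ug_per_ml)


def percent_transport(q_final_ug: float, dose_ug: float) -> float:
    """Final cumulative amount as a percentage of the applied dose."""
    if dose_ug <= 0:
        raise ValueError("dose must be positive")
    return 100.0 * q_final_ug / dose_ug


def donor_concentration_from_extract(
    extract_conc_mg_per_ml: float, content_percent: float
) -> float:
    """Component donor concentration (µg/mL) from extract strength × content %.

    E.g. a 20 mg/mL extract working solution containing 3.465 % of a
    component gives 693 µg/mL of that component.
    """
    if extract_conc_mg_per_ml <= 0 or content_percent <= 0:
        raise ValueError("extract concentration and content must be positive")
    if content_percent > 100:
        raise ValueError("content cannot exceed 100 %")
    return extract_conc_mg_per_ml * 1000.0 * content_percent / 100.0


def tissue_content_percent(amount_in_lysate_ug: float, dose_ug: float) -> float:
    """Amount recovered from the lysed tissue as a percentage of the dose."""
    if dose_ug <= 0:
        raise ValueError("dose must be positive")
    if amount_in_lysate_ug < 0:
        raise ValueError("lysate amount must be non-negative")
    return 100.0 * amount_in_lysate_ug / dose_ug


def integrity_check(
    papp_marker: float, threshold: float = DEFAULT_INTEGRITY_THRESHOLD
) -> bool:
    """Membrane integrity: marker Papp at or below the threshold passes.

    Closed bound: a marker Papp exactly at the threshold still passes.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return papp_marker <= threshold


def classify_permeability(
    papp: float, benchmarks: Mapping[str, float] | None = None
) -> tuple[str, dict[str, tuple[float, float]]]:
    """Nearest-benchmark permeability class with the interval bounds used.

    ``benchmarks`` maps class label -> benchmark Papp (cm/s) in increasing
    order of permeability.  Class intervals are delimited by midpoints
    between adjacent benchmarks; returns (label, intervals).
    """
    bm = dict(benchmarks or DEFAULT_BENCHMARKS)
    labels = list(bm)
    values = np.array([bm[k] for k in labels], dtype=float)
    if np.any(np.diff(values) <= 0):
        raise ValueError("benchmarks must be strictly increasing")
    mids = (values[:-1] + values[1:]) / 2.0
    bounds = np.concatenate([[0.0], mids, [np.inf]])
    intervals = {
        labels[k]: (float(bounds[k]), float(bounds[k + 1]))
        for k in range(len(labels))
    }
    idx = int(np.searchsorted(mids, papp, side="right"))
    return labels[idx], intervals


class FranzPermeation:
    """Model: one compound's Franz-cell permeation experiment.

    Per-replicate cumulative amounts are fitted for flux, converted to
    P_app, and aggregated as mean ± sd; :meth:`fit` returns a
    :class:`FranzPermeationResults`.
    """

    def __init__(
        self,
        experiment: FranzExperiment,
        window: str = "all",
        r2_min: float = 0.95,
    ) -> None:
        self.experiment = experiment
        self.window = window
        self.r2_min = float(r2_min)

    def fit(self) -> "FranzPermeationResults":
        exp = self.experiment
        q = cumulative_amount(exp)
        fits = [
            steady_state_flux(q[r], exp.times_min, self.window, self.r2_min)
            for r in range(exp.n_replicates)
        ]
        papp = np.array(
            [
                apparent_permeability(f.flux_ug_per_s, exp.area_cm2, exp.c0_donor)
                for f in fits
            ]
        )
        transport = np.array(
            [percent_transport(q[r, -1], exp.dose_ug) for r in range(exp.n_replicates)]
        )
        return FranzPermeationResults(
            experiment=exp, q_ug=q, fits=fits, papp=papp, transport_percent=transport
        )


@dataclass
class FranzPermeationResults:
    """Per-replicate and aggregate permeation estimates."""

    experiment: FranzExperiment
    q_ug: np.ndarray
    fits: list[FluxFit]
    papp: np.ndarray
    transport_percent: np.ndarray
    tissue_percent: np.ndarray | None = None

    @property
    def flux_ug_per_s(self) -> np.ndarray:
        return np.array([f.flux_ug_per_s for f in self.fits])

    @property
    def papp_mean(self) -> float:
        return float(self.papp.mean())

    @property
    def papp_sd(self) -> float:
        return float(self.papp.std(ddof=1)) if self.papp.size > 1 else 0.0

    @property
    def transport_mean(self) -> float:
        return float(self.transport_percent.mean())

    @property
    def transport_sd(self) -> float:
        return (
            float(self.transport_percent.std(ddof=1))
            if self.transport_percent.size > 1
            else 0.0
        )

    def with_tissue_assay(
        self, lysate_conc_ug_per_ml: Sequence[float], lysate_volume_ml: float = 5.0
    ) -> "FranzPermeationResults":
        """Attach tissue-retention percentages from a lysate assay."""
        amounts = np.asarray(lysate_conc_ug_per_ml, dtype=float) * lysate_volume_ml
        self.tissue_percent = np.array(
            [tissue_content_percent(a, self.experiment.dose_ug) for a in amounts]
        )
        return self

    def integrity(self, threshold: float = DEFAULT_INTEGRITY_THRESHOLD) -> bool:
        return integrity_check(self.papp_mean, threshold)

    def classify(
        self, benchmarks: Mapping[str, float] | None = None
    ) -> tuple[str, dict[str, tuple[float, float]]]:
        return classify_permeability(self.papp_mean, benchmarks)

    def summary(self) -> pd.DataFrame:
        """One-row aggregate table: Papp, % permeation, tissue %, area, dose."""
        exp = self.experiment
        row = {
            "compound": exp.name,
            "n": exp.n_replicates,
            "area_cm2": exp.area_cm2,
            "dose_ug": exp.dose_ug,
            "Papp_cm_per_s": self.papp_mean,
            "Papp_sd": self.papp_sd,
            "permeation_percent": self.transport_mean,
            "permeation_sd": self.transport_sd,
            "tissue_percent": (
                float(self.tissue_percent.mean())
                if self.tissue_percent is not None
                else np.nan
            ),
        }
        return pd.DataFrame([row])

    def replicate_table(self) -> pd.DataFrame:
        rows = []
        for r, fit in enumerate(self.fits):
            rows.append(
                {
                    "replicate": r + 1,
                    "flux_ug_per_s": fit.flux_ug_per_s,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                    "Papp_cm_per_s": self.papp[r],
                    "permeation_percent": self.transport_percent[r],
                }
            )
        return pd.DataFrame(rows)
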