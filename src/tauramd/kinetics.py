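"""Harmonizing experimental kinetic constants and comparing with tau_RAMD.

Literature series measure k_off/k_on under different conditions and
techniques; to pool them, each series is normalized to its own wild-type
value and rescaled by the wild-type value of a chosen reference series,
then averaged per mutant. Missing rates are derived from K_d = k_off/k_on
(equivalently k_off = k_on * K_i for inhibition constants) with the SDs
combined by standard error propagation on a ratio/product:

    SD = value * sqrt((SD_1/v_1)^2 + (SD_2/v_2)^2)

The experimental residence time is tau_exp = 1/k_off. Computed and
experimental residence times are compared by an ordinary least-squares
straight-line fit in log10-log10 space (the scales span orders of
magnitude); R^2 is the squared Pearson correlation of the fitted
relation.

Tables are long-form: columns ``mutant, series_id, quantity, value, sd``
with the wild type carrying the reserved mutant id ``"WT"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidInputError

WT_ID = "WT"


class InvalidSeriesError(InvalidInputError):
    """A literature series is unusable (e.g. lacks a WT row)."""


class InvalidRecordError(InvalidInputError):
    """A kinetic record holds nonpositive rates or is incomplete."""


@dataclass
class Measurement:
    value: float
    sd: float = 0.0

    def __post_init__(self):
        if self.value <= 0:
            raise InvalidRecordError("rates and constants must be positive")
        if self.sd < 0:
            raise InvalidRecordError("SD must be nonnegative")


@dataclass
class KineticRecord:
    """Harmonized kinetic constants of one mutant."""

    mutant: str
    k_on: Measurement = None  # M^-1 s^-1
    k_off: Measurement = None  # s^-1
    k_d: Measurement = None  # M
    k_i: Measurement = None  # M

    @property
    def tau_exp(self) -> float:
        """Experimental residence time 1/k_off in seconds."""
        if self.k_off is None:
            raise InvalidRecordError(f"{self.mutant}: k_off unknown")
        return 1.0 / self.k_off.value


def _propagated(value, a: Measurement, b: Measurement) -> Measurement:
    sd = value * sqrt((a.sd / a.value) ** 2 + (b.sd / b.value) ** 2)
    return Measurement(value, sd)


def derive_rates(record: KineticRecord) -> KineticRecord:
    """Fill in the derivable quantities of a record.

    K_d = k_off / k_on when both rates are known; k_off = k_on * K_i when
    an inhibition constant was measured instead. SDs propagate through the
    ratio/product.
    """
    if record.k_off is None and record.k_on is not None \
            and record.k_i is not None:
        record.k_off = _propagated(
            record.k_on.value * record.k_i.value, record.k_on, record.k_i)
    if record.k_d is None and record.k_off is not None \
            and record.k_on is not None:
        record.k_d = _propagated(
            record.k_off.value / record.k_on.value, record.k_off,
            record.k_on)
    if record.k_off is None:
        raise InvalidRecordError(
            f"{record.mutant}: cannot derive k_off from the given quantities")
    return record


def normalize_series(table: pd.DataFrame, reference_series: str,
                     quantity: str = "k_off",
                     reference_wt_value: float = None) -> pd.DataFrame:
    """Pool one rate constant across literature series.

    ``table`` is long-form (mutant, series_id, quantity, value, sd). Each
    series' values are divided by its WT value and multiplied by the WT
    value of ``reference_series`` (or an explicit ``reference_wt_value``).
    Returns a frame with one row per mutant: the mean of the normalized
    values, their sample SD (0 for a single series) and the series count.
    """
    sub = table[table["quantity"] == quantity]
    if sub.empty:
        raise InvalidSeriesError(f"no rows with quantity {quantity!r}")
    series_ids = list(dict.fromkeys(sub["series_id"]))
    if reference_wt_value is None:
        if reference_series not in series_ids:
            raise InvalidSeriesError(
                f"reference series {reference_series!r} not in table")
        ref_rows = sub[(sub["series_id"] == reference_series)
                       & (sub["mutant"] == WT_ID)]
        if ref_rows.empty:
            raise InvalidSeriesError(
                f"reference series {reference_series!r} has no WT row")
        reference_wt_value = float(ref_rows["value"].iloc[0])

    normalized: dict = {}
    for sid in series_ids:
        rows = sub[sub["series_id"] == sid]
        wt = rows[rows["mutant"] == WT_ID]
        if wt.empty:
            raise InvalidSeriesError(f"series {sid!r} lacks a WT row")
        wt_value = float(wt["value"].iloc[0])
        if wt_value <= 0:
            raise InvalidSeriesError(f"series {sid!r} has nonpositive WT")
        for _, row in rows.iterrows():
            k_norm = row["value"] / wt_value * reference_wt_value
            normalized.setdefault(row["mutant"], []).append(k_norm)

    out = []
    for mutant, values in normalized.items():
        arr = np.asarray(values, dtype=float)
        out.append({
            "mutant": mutant,
            "quantity": quantity,
            "value": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n_series": int(arr.size),
        })
    return pd.DataFrame(out)


def normalize_koff(table: pd.DataFrame, reference_series: str,
                   reference_wt_value: float = None) -> pd.DataFrame:
    return normalize_series(table, reference_series, "k_off",
                            reference_wt_value)


def normalize_kon(table: pd.DataFrame, reference_series: str,
                  reference_wt_value: float = None) -> pd.DataFrame:
    return normalize_series(table, reference_series, "k_on",
                            reference_wt_value)


@dataclass
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    points: list  # (label, tau_exp, tau_ramd) used in the fit
    excluded: list = field(default_factory=list)  # (label, reason)
    log_space: bool = True


def loglog_fit(tau_ramd: dict, tau_exp: dict, exclusions: dict = None,
               log_space: bool = True) -> FitResult:
    """Straight-line fit of computed on experimental residence times.

    ``tau_ramd`` and ``tau_exp`` map mutant labels to positive times (any
    common unit per axis); ``exclusions`` maps labels to a reason for
    leaving them out of the fit (they are carried in the result). The fit
    is OLS of log10 tau_RAMD on log10 tau_exp by default.
    """
    exclusions = exclusions or {}
    labels = [m for m in tau_ramd if m in tau_exp]
    points, excluded = [], []
    for m in labels:
        if m in exclusions:
            excluded.append((m, exclusions[m]))
            continue
        x, y = tau_exp[m], tau_ramd[m]
        if x <= 0 or y <= 0:
            raise InvalidInputError(
                f"{m}: residence times must be positive, got ({x}, {y})")
        points.append((m, float(x), float(y)))
    if len(points) < 3:
        raise ConfigurationError("the fit needs at least 3 included points")
    x = np.asarray([p[1] for p in points])
    y = np.asarray([p[2] for p in points])
    if log_space:
        x, y = np.log10(x), np.log10(y)
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue ** 2)
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=r2, points=points, excluded=excluded,
                     log_space=log_space)
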