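"""Two-stage charcoal / filter air sampling reduction for ^131I.

Air is drawn through a Petryanov filter (aerosol fraction) and then two
identical activated-charcoal cassettes in series (gas fraction).  With equal
absorption yield per cassette the activities trapped on successive stages
form a geometric series, so the total activity that entered the cartridge is

    A_total = A_first / (1 - q),        q = A_second / A_first,

the sum of the infinite geometric series, and the two-cassette cartridge's
overall trapping efficiency is eps = 1 - q^2 (the escaping fraction is the
tail q^2 * A_total).  Division by the sampled air volume (flow x duration)
gives the concentration in Bq m^-3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np
import pandas as pd


class SamplingError(ValueError):
    """Raised for physically inconsistent cassette measurements."""


@dataclass(frozen=True)
class NuclideConstants:
    """Physical decay constants of the sampled nuclide.

    ``decay_constant`` is derived as ln 2 / ``half_life`` and must stay
    consistent with it.
    """

    half_life: float  # d
    decay_constant: float = 0.0  # 1/d

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")
        lam = math.log(2.0) / self.half_life
        if self.decay_constant == 0.0:
            object.__setattr__(self, "decay_constant", lam)
        elif abs(self.decay_constant * self.half_life - math.log(2.0)) > 1e-12 * math.log(2.0):
            raise ValueError("decay_constant inconsistent with half_life")


#: ^131I: 8.03 d physical half-life.
I131 = NuclideConstants(half_life=8.03)


@dataclass(frozen=True)
class CassettePair:
    """One day's two-cassette charcoal measurement (gas fraction)."""

    activity_first: float  # Bq trapped on the upstream cassette
    activity_second: float  # Bq trapped on the downstream cassette
    sigma_first: float = 0.0  # Bq, one-sigma counting uncertainty
    sigma_second: float = 0.0  # Bq
    flow_rate: float = 30.0  # m^3/h
    duration: float = 24.0  # h
    sample_end_time: datetime | None = None
    count_time: datetime | None = None

    def __post_init__(self) -> None:
        if self.activity_first < 0 or self.activity_second < 0:
            raise ValueError("activities must be >= 0")
        if self.sigma_first < 0 or self.sigma_second < 0:
            raise ValueError("sigmas must be >= 0")
        if self.flow_rate <= 0 or self.duration <= 0:
            raise ValueError("flow_rate and duration must be > 0")
        if (
            self.sample_end_time is not None
            and self.count_time is not None
            and self.count_time < self.sample_end_time
        ):
            raise ValueError("count_time must not precede sample_end_time")


@dataclass(frozen=True)
class FilterMeasurement:
    """One day's Petryanov-filter measurement (aerosol fraction)."""

    activity: float  # Bq
    sigma: float = 0.0  # Bq
    flow_rate: float = 30.0  # m^3/h
    duration: float = 24.0  # h

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError("activity must be >= 0")
        if self.flow_rate <= 0 or self.duration <= 0:
            raise ValueError("flow_rate and duration must be > 0")


@dataclass(frozen=True)
class ConcentrationRecord:
    """Reduced per-date air concentrations, gas and aerosol fractions."""

    location: str
    date: date | str
    gas_concentration: float  # Bq/m^3
    gas_sigma: float
    aerosol_concentration: float  # Bq/m^3
    aerosol_sigma: float
    below_detection: bool = False


@dataclass(frozen=True)
class CampaignSummary:
    """Arithmetic mean +/- sample standard deviation of daily values."""

    gas_mean: float
    gas_sd: float  # nan when a single record (flagged undefined)
    aerosol_mean: float
    aerosol_sd: float
    n_days: int


def breakthrough_ratio(pair: CassettePair) -> float:
    """Breakthrough ratio q = (second cassette)/(first cassette).

    q is the common ratio of the geometric trapping series.  A downstream
    cassette catching *more* than the upstream one cannot arise from simple
    breakthrough and is rejected as a sampling failure.
    """
    if pair.activity_first == 0:
        raise SamplingError("first cassette activity is zero: breakthrough ratio undefined")
    q = pair.activity_second / pair.activity_first
    if q > 1.0:
        raise SamplingError(
            f"second cassette ({pair.activity_second} Bq) exceeds first "
            f"({pair.activity_first} Bq): breakthrough > 1, sampling failure"
        )
    return q


def total_activity(activity_first: float, q: float) -> float:
    """Total activity entering the cartridge: A_first / (1 - q).

    Sum of the infinite geometric series A_first * (1 + q + q^2 + ...).
    Diverges for q >= 1 (the series does not converge; the cartridge no
    longer characterises the air).
    """
    if not 0.0 <= q < 1.0:
        raise SamplingError(f"q={q}: geometric series diverges unless 0 <= q < 1")
    return activity_first / (1.0 - q)


def trap_efficiency(q: float) -> float:
    """Overall two-cassette trapping efficiency eps = 1 - q^2."""
    if not 0.0 <= q <= 1.0:
        raise SamplingError(f"q={q} outside [0, 1]")
    return 1.0 - q * q


def concentration(activity: float, flow_rate: float, duration: float) -> float:
    """Air concentration Bq/m^3 = activity / (flow_rate x duration)."""
    volume = flow_rate * duration
    if volume <= 0:
        raise ValueError("sampled volume must be positive")
    return activity / volume


def decay_correct(activity: float, elapsed: float, constants: NuclideConstants = I131) -> float:
    """Back-correct a counted activity to the reference time.

    ``elapsed`` is the delay (days) between the reference time and the
    count; the correction multiplies by exp(lambda * elapsed).
    """
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    return activity * math.exp(constants.decay_constant * elapsed)


def propagate_total_uncertainty(pair: CassettePair) -> float:
    """One-sigma uncertainty of A_total by first-order propagation.

    A_total = A^2 / (A - B) with A, B the first/second cassette activities;
    dA_total/dA = A(A - 2B)/(A - B)^2 and dA_total/dB = A^2/(A - B)^2.
    """
    a, b = pair.activity_first, pair.activity_second
    q = breakthrough_ratio(pair)
    if q >= 1.0:
        raise SamplingError("uncertainty undefined for q >= 1")
    if b == 0.0 and pair.sigma_second == 0.0:
        return pair.sigma_first
    d = (a - b) ** 2
    da = a * (a - 2.0 * b) / d
    db = a * a / d
    return math.hypot(da * pair.sigma_first, db * pair.sigma_second)


def _mid_sampling_elapsed(pair: CassettePair) -> float:
    """Days from the mid-point of the sampling interval to the count."""
    if pair.sample_end_time is None or pair.count_time is None:
        return 0.0
    delay_d = (pair.count_time - pair.sample_end_time).total_seconds() / 86400.0
    return delay_d + pair.duration / 48.0  # half the sampling duration, in days


def reduce_campaign(
    pairs: list[CassettePair],
    filters: list[FilterMeasurement],
    dates: list[date | str] | None = None,
    location: str = "",
    decay: bool = False,
    constants: NuclideConstants = I131,
) -> list[ConcentrationRecord]:
    """Reduce paired daily cassette + filter measurements to concentrations.

    Gas concentration = breakthrough-corrected total activity / volume with
    first-order-propagated sigma; aerosol from the filter directly.  When
    ``decay`` is set, activities are back-corrected from counting time to
    the mid-point of the sampling interval.
    """
    if len(pairs) != len(filters):
        raise ValueError("pairs and filters must align one-to-one by date")
    if dates is None:
        dates = [str(i) for i in range(len(pairs))]
    if len(dates) != len(pairs):
        raise ValueError("date list does not match measurement list")

    records = []
    for d, pair, filt in zip(dates, pairs, filters):
        q = breakthrough_ratio(pair)
        a_tot = total_activity(pair.activity_first, q)
        sigma_tot = propagate_total_uncertainty(pair)
        if decay:
            f = math.exp(constants.decay_constant * _mid_sampling_elapsed(pair))
            a_tot, sigma_tot = a_tot * f, sigma_tot * f
        volume = pair.flow_rate * pair.duration
        fvol = filt.flow_rate * filt.duration
        records.append(
            ConcentrationRecord(
                location=location,
                date=d,
                gas_concentration=a_tot / volume,
                gas_sigma=sigma_tot / volume,
                aerosol_concentration=filt.activity / fvol,
                aerosol_sigma=filt.sigma / fvol,
            )
        )
    return records


def summarize_campaign(records: list[ConcentrationRecord]) -> CampaignSummary:
    """Campaign mean +/- sample SD of the daily concentrations.

    Mirrors the "Average" row of a monitoring table: arithmetic mean and
    sample standard deviation of the daily values (not propagated counting
    error).  With a single record the SD is undefined and returned as NaN.
    """
    if not records:
        raise ValueError("no records to summarize")
    gas = np.array([r.gas_concentration for r in records], dtype=float)
    aer = np.array([r.aerosol_concentration for r in records], dtype=float)
    if len(records) == 1:
        warnings.warn("single-record campaign: SD of the mean undefined", stacklevel=2)
        return CampaignSummary(gas[0], math.nan, aer[0], math.nan, 1)
    return CampaignSummary(
        gas_mean=float(gas.mean()),
        gas_sd=float(gas.std(ddof=1)),
        aerosol_mean=float(aer.mean()),
        aerosol_sd=float(aer.std(ddof=1)),
        n_days=len(records),
    )


# ---------------------------------------------------------------------------
# Delimited-table I/O

TABLE_COLUMNS = [
    "location",
    "date",
    "cassette1_bq",
    "cassette1_sigma",
    "cassette2_bq",
    "cassette2_sigma",
    "filter_bq",
    "filter_sigma",
    "flow_m3_h",
    "duration_h",
]


def read_measurement_table(path) -> pd.DataFrame:
    """Read the raw-measurement CSV (header row, columns ``TABLE_COLUMNS``)."""
    df = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return df


def reduce_table(df: pd.DataFrame, decay: bool = False) -> pd.DataFrame:
    """Reduce a raw-measurement table to a concentration table.

    Output columns mirror a published concentration table (location, date,
    gas_bq_m3, gas_sigma, aerosol_bq_m3, aerosol_sigma) plus one
    ``campaign-average`` summary row per location.
    """
    out = []
    for loc, sub in df.groupby("location", sort=False):
        pairs = [
            CassettePair(
                activity_first=r.cassette1_bq,
                activity_second=r.cassette2_bq,
                sigma_first=r.cassette1_sigma,
                sigma_second=r.cassette2_sigma,
                flow_rate=r.flow_m3_h,
                duration=r.duration_h,
            )
            for r in sub.itertuples()
        ]
        filts = [
            FilterMeasurement(
                activity=r.filter_bq,
                sigma=r.filter_sigma,
                flow_rate=r.flow_m3_h,
                duration=r.duration_h,
            )
            for r in sub.itertuples()
        ]
        records = reduce_campaign(pairs, filts, dates=list(sub["date"]), location=str(loc), decay=decay)
        for r in records:
            out.append(
                dict(
                    location=r.location,
                    date=r.date,
                    gas_bq_m3=r.gas_concentration,
                    gas_sigma=r.gas_sigma,
                    aerosol_bq_m3=r.aerosol_concentration,
                    aerosol_sigma=r.aerosol_sigma,
                )
            )
        s = summarize_campaign(records)
        out.append(
            dict(
                location=str(loc),
                date="campaign-average",
                gas_bq_m3=s.gas_mean,
                gas_sigma=s.gas_sd,
                aerosol_bq_m3=s.aerosol_mean,
                aerosol_sigma=s.aerosol_sd,
            )
        )
    return pd.DataFrame(out)
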