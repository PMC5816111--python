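"""Respiratory-tract regional deposition of inhaled ^131I.

Maps an inhaled activity onto initial deposits in the HRTM regions:
ET1 (anterior nose), ET2 (posterior nasal passages / pharynx / larynx),
BB (bronchial, fast+sequestered and slow sub-compartments), bb
(bronchiolar), and AI (alveolar-interstitial).

Two forms are supported:

* ``aerosol_5um`` — particle-bound iodine at 5 µm AMAD, sitting worker;
  fractions are sex-specific and sum to < 1 (the rest is exhaled).
* ``gas`` — elemental iodine vapour: 100% deposition, 10% ET1 / 40% ET2 /
  50% BB, sex-independent.

Fractions are data, not code: the shipped parameter file
(``data/deposition_fractions.csv``) can be replaced by the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

REGIONS = ("ET1", "ET2", "BB_fast_seq", "BB_slow", "bb_fast_seq", "bb_slow", "AI")
FORMS = ("aerosol_5um", "gas")


def _default_table_path():
    return resources.files("iodair.data") / "deposition_fractions.csv"


@dataclass(frozen=True)
class DepositionTable:
    """Regional deposition fractions keyed by (sex, form)."""

    entries: dict  # (sex, form) -> {region: fraction}

    @classmethod
    def from_csv(cls, path=None) -> "DepositionTable":
        path = _default_table_path() if path is None else Path(path)
        df = pd.read_csv(path)
        entries: dict = {}
        for row in df.itertuples():
            if row.region not in REGIONS:
                raise ValueError(f"unknown region {row.region!r}")
            if not 0.0 <= row.fraction <= 1.0:
                raise ValueError(f"fraction out of [0,1]: {row}")
            entries.setdefault((row.sex, row.form), {})[row.region] = float(row.fraction)
        for key, fracs in entries.items():
            total = sum(fracs.values())
            if total > 1.0 + 1e-9:
                raise ValueError(f"deposition fractions for {key} sum to {total} > 1")
        return cls(entries=entries)

    @classmethod
    def default(cls) -> "DepositionTable":
        return cls.from_csv()

    def fractions(self, sex: str, form: str) -> dict:
        try:
            return self.entries[(sex, form)]
        except KeyError:
            raise KeyError(f"no deposition entry for sex={sex!r}, form={form!r}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(region=region, sex=sex, form=form, fraction=frac)
            for (sex, form), fracs in self.entries.items()
            for region, frac in fracs.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegionalDeposit:
    """Initial activity deposited per HRTM region, plus the exhaled part."""

    deposits: dict  # region -> Bq
    exhaled: float  # Bq

    @property
    def total_deposited(self) -> float:
        return sum(self.deposits.values())

    def __add__(self, other: "RegionalDeposit") -> "RegionalDeposit":
        regions = set(self.deposits) | set(other.deposits)
        return RegionalDeposit(
            deposits={r: self.deposits.get(r, 0.0) + other.deposits.get(r, 0.0) for r in regions},
            exhaled=self.exhaled + other.exhaled,
        )

    def scaled(self, factor: float) -> "RegionalDeposit":
        return RegionalDeposit(
            deposits={r: a * factor for r, a in self.deposits.items()},
            exhaled=self.exhaled * factor,
        )


def regional_deposition(
    inhaled: float, sex: str, form: str, table: DepositionTable | None = None
) -> RegionalDeposit:
    """Split an inhaled activity into regional deposits and an exhaled rest.

    Conservation holds exactly: sum(deposits) + exhaled == inhaled.
    """
    if inhaled < 0:
        raise ValueError("inhaled activity must be >= 0")
    table = DepositionTable.default() if table is None else table
    fracs = table.fractions(sex, form)
    deposits = {region: inhaled * fracs.get(region, 0.0) for region in REGIONS}
    return RegionalDeposit(deposits=deposits, exhaled=inhaled - sum(deposits.values()))


def total_deposited_fraction(sex: str, form: str, table: DepositionTable | None = None) -> float:
    """Summed regional deposition fraction for a (sex, form) pair."""
    table = DepositionTable.default() if table is None else table
    return sum(table.fractions(sex, form).values())
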