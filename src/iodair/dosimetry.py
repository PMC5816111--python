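"""Equivalent and effective doses from committed time-integrated activities.

The dose bridge is the standard MIRD/ICRP scheme: for each target tissue T,

    H_T = sum_S  U_S  x  S_w(T <- S, sex)          [Sv per intake]
    E   = sum_T  w_T  x  H_T                       [Sv per intake]

with U_S the committed time-integrated activity of source region S (Bq d),
S_w the radiation-weighted dose per unit time-integrated activity
(Sv / Bq d) and w_T the ICRP 103 tissue weighting factors.  Annual doses
are per-intake committed doses times the number of intakes per year.

The default S-coefficient table is *derived in-package* from ^131I mean
decay energies, reference organ masses and a simple photon absorbed-
fraction model (see :func:`derive_default_s_table`); user-supplied tables
are drop-in replacements.  A calibration mode scales the whole default
table by one factor so that the male-gas effective dose coefficient
matches a reference value implied by an independent SEECAL-based
calculation; calibration is always explicit, never silent.

Note on "per-sex effective dose": ICRP 103 defines E as sex-averaged; the
per-sex w_T-weighted quantities reported here follow the workplace-survey
convention of quoting males and females separately, and the sex-averaged
value is also available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from iodair.biokinetics import TimeIntegratedActivity, build_iodine_model, integrate_committed
from iodair.deposition import DepositionTable, regional_deposition
from iodair.scenario import ExposureScenario, annual_intake, single_intake

# ^131I mean energies per decay (MeV): all electrons (beta + conversion +
# Auger) and all photons (gamma + X-rays).
E_ELECTRON_MEV = 0.1917
E_PHOTON_MEV = 0.3817

#: J deposited per (MeV/decay) per Bq d  =  86400 s/d x 1.602e-13 J/MeV
_K = 86400.0 * 1.602176634e-13

#: reference adult organ/content masses (kg)
ORGAN_MASSES = {
    "male": dict(
        body=73.0,
        thyroid=0.020,
        lungs=1.2,
        et_tissue=0.050,
        stomach_contents=0.25,
        si_contents=0.35,
        colon_contents=0.30,
        bladder_contents=0.20,
    ),
    "female": dict(
        body=60.0,
        thyroid=0.017,
        lungs=0.95,
        et_tissue=0.040,
        stomach_contents=0.23,
        si_contents=0.28,
        colon_contents=0.28,
        bladder_contents=0.20,
    ),
}

#: whole-body absorbed fraction for the ~364 keV photon field
AF_PHOTON_BODY = {"male": 0.34, "female": 0.33}
#: photon absorbed fraction in a 20-g organ, scaled as (m/0.020)^0.3
_AF_PHOTON_20G = 0.0306

SOURCES = (
    "thyroid",
    "blood",
    "other",
    "stomach_contents",
    "si_contents",
    "colon_contents",
    "bladder_contents",
    "lungs",
    "ET",
    "excreta",
)
TARGETS = (
    "thyroid",
    "stomach_wall",
    "colon_wall",
    "lung",
    "bladder_wall",
    "si_wall",
    "extrathoracic",
    "whole_body",
)

#: named tissue -> dose target; tissues absent here receive the
#: whole-body (uniform-field) dose
_TISSUE_TO_TARGET = {
    "thyroid": "thyroid",
    "stomach": "stomach_wall",
    "colon": "colon_wall",
    "lung": "lung",
    "bladder": "bladder_wall",
}
#: ICRP 103 remainder: mean of 13 tissues; two of them (extrathoracic
#: airways, small-intestine wall) have specific dose targets here, the
#: other 11 sit in the uniform field.
_N_REMAINDER = 13

#: Reference effective dose coefficient used by the calibration mode:
#: annual male-technician gas effective dose of 1.3e-3 Sv from an
#: independent SEECAL/SAAM-II calculation, divided by the corresponding
#: annual intake 490 Bq/m3 x 0.54 m3/h x 6 h x 50 = 79380 Bq.
CALIBRATION_EFFECTIVE_COEFF = 1.3e-3 / 79380.0  # Sv/Bq, male, gas


class DoseConfigurationError(KeyError):
    pass


def _af_photon(mass_kg: float, sex: str) -> float:
    return min(_AF_PHOTON_20G * (mass_kg / 0.020) ** 0.3, AF_PHOTON_BODY[sex])


@dataclass(frozen=True)
class SCoefficientTable:
    """S_w(target <- source, sex) in Sv per Bq d."""

    entries: dict  # (sex, target, source) -> Sv/(Bq d)

    def s(self, sex: str, target: str, source: str) -> float:
        try:
            return self.entries[(sex, target, source)]
        except KeyError:
            raise DoseConfigurationError(
                f"no S coefficient for target={target!r} <- source={source!r} (sex={sex!r})"
            ) from None

    def scaled(self, factor: float) -> "SCoefficientTable":
        return SCoefficientTable({k: v * factor for k, v in self.entries.items()})

    @classmethod
    def default(cls) -> "SCoefficientTable":
        return derive_default_s_table()

    @classmethod
    def from_csv(cls, path) -> "SCoefficientTable":
        df = pd.read_csv(path)
        entries = {}
        for row in df.itertuples():
            if row.s_sv_per_bq_d < 0:
                raise ValueError("S coefficients must be >= 0")
            entries[(row.sex, row.target, row.source)] = float(row.s_sv_per_bq_d)
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(sex=sex, target=target, source=source, s_sv_per_bq_d=v)
            for (sex, target, source), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


def derive_default_s_table() -> SCoefficientTable:
    """Derive the default S-coefficient table from first principles.

    Rules, per source region S and target T:

    * self-irradiation of a compact organ (thyroid, lungs): electrons fully
      absorbed, photons with the small-organ absorbed fraction
      0.0306 (m/20 g)^0.3;
    * surface deposit (ET): half the electron energy into tissue;
    * walled organs: electron dose to the wall = half the equilibrium dose
      in the contents (ICRP 30 convention), plus the whole-body photon field;
    * distributed sources (blood iodide, extrathyroidal organic iodine):
      uniform whole-body field, electrons locally absorbed plus photons at
      the whole-body absorbed fraction;
    * photon cross-fire between distinct regions: body-averaged photon dose
      (no proximity enhancement — conservative for E, negligible next to
      thyroid self-dose for this nuclide);
    * excreta: no dose.
    """
    entries: dict = {}
    for sex in ("male", "female"):
        m = ORGAN_MASSES[sex]
        af_wb = AF_PHOTON_BODY[sex]
        cross = _K * E_PHOTON_MEV * af_wb / m["body"]  # photon-only, body-averaged
        uniform = _K * (E_ELECTRON_MEV + E_PHOTON_MEV * af_wb) / m["body"]

        def organ_self(mass: float, electron_fraction: float = 1.0) -> float:
            return _K * (
                E_ELECTRON_MEV * electron_fraction + E_PHOTON_MEV * _af_photon(mass, sex)
            ) / mass

        def wall_from_contents(mass_contents: float) -> float:
            return _K * 0.5 * E_ELECTRON_MEV / mass_contents + cross

        specific = {
            ("thyroid", "thyroid"): organ_self(m["thyroid"]),
            ("lung", "lungs"): organ_self(m["lungs"]),
            ("extrathoracic", "ET"): organ_self(m["et_tissue"], electron_fraction=0.5),
            ("stomach_wall", "stomach_contents"): wall_from_contents(m["stomach_contents"]),
            ("si_wall", "si_contents"): wall_from_contents(m["si_contents"]),
            ("colon_wall", "colon_contents"): wall_from_contents(m["colon_contents"]),
            ("bladder_wall", "bladder_contents"): wall_from_contents(m["bladder_contents"]),
        }
        for target in TARGETS:
            for source in SOURCES:
                if source == "excreta":
                    v = 0.0
                elif source in ("blood", "other"):
                    v = uniform
                else:
                    v = specific.get((target, source), cross)
                entries[(sex, target, source)] = v
    return SCoefficientTable(entries)


@dataclass(frozen=True)
class TissueWeights:
    weights: dict  # tissue -> w_T

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tissue weights must sum to 1, got {total}")

    @classmethod
    def default(cls) -> "TissueWeights":
        return cls.from_csv(resources.files("iodair.data") / "tissue_weights.csv")

    @classmethod
    def from_csv(cls, path) -> "TissueWeights":
        df = pd.read_csv(path)
        return cls(weights={row.tissue: float(row.w_t) for row in df.itertuples()})


def equivalent_dose(
    u: TimeIntegratedActivity, s: SCoefficientTable, sex: str, tissue: str
) -> float:
    """Committed equivalent dose to one tissue for one intake (Sv).

    ``tissue`` may be a dose target, a named w_T tissue, or ``remainder``
    (arithmetic mean of the 13 remainder tissues).
    """
    def target_dose(target: str) -> float:
        return sum(u_s * s.s(sex, target, source) for source, u_s in u.by_source.items())

    if tissue == "remainder":
        return (
            target_dose("extrathoracic")
            + target_dose("si_wall")
            + (_N_REMAINDER - 2) * target_dose("whole_body")
        ) / _N_REMAINDER
    target = _TISSUE_TO_TARGET.get(tissue, tissue if tissue in TARGETS else "whole_body")
    return target_dose(target)


def tissue_doses(
    u: TimeIntegratedActivity, s: SCoefficientTable, sex: str, w: TissueWeights
) -> dict:
    """Committed equivalent dose per w_T tissue for one intake (Sv)."""
    return {tissue: equivalent_dose(u, s, sex, tissue) for tissue in w.weights}


def effective_dose(h: dict, w: TissueWeights) -> float:
    """E = sum_T w_T H_T over the tissues of ``w``."""
    missing = set(w.weights) - set(h)
    if missing:
        raise DoseConfigurationError(f"missing tissue doses for {sorted(missing)}")
    return sum(w.weights[t] * h[t] for t in w.weights)


@dataclass(frozen=True)
class FractionDoses:
    """Annual doses for one airborne fraction (gas or aerosol)."""

    annual_intake: float  # Bq
    tissue_equivalent: dict  # tissue -> Sv/yr
    effective: float  # Sv/yr


@dataclass(frozen=True)
class DoseReport:
    profession: str
    sex: str
    calibrated: bool
    fractions: dict  # "gas"/"aerosol" -> FractionDoses

    @property
    def total_effective(self) -> float:
        return sum(f.effective for f in self.fractions.values())


_FORM_OF_FRACTION = {"gas": "gas", "aerosol": "aerosol_5um"}


def committed_doses_per_intake(
    sex: str,
    form: str,
    s_table: SCoefficientTable,
    weights: TissueWeights,
    intake: float = 1.0,
    deposition_table: DepositionTable | None = None,
) -> tuple[dict, float]:
    """(tissue equivalent doses, effective dose) committed by one intake."""
    model = build_iodine_model(sex, form)
    deposit = regional_deposition(intake, sex, form, table=deposition_table)
    u = integrate_committed(model, deposit)
    h = tissue_doses(u, s_table, sex, weights)
    return h, effective_dose(h, weights)


def calibration_factor(s_table: SCoefficientTable | None = None) -> float:
    """Scale factor aligning the male-gas effective coefficient with the
    calibration reference (``CALIBRATION_EFFECTIVE_COEFF``)."""
    s_table = SCoefficientTable.default() if s_table is None else s_table
    w = TissueWeights.default()
    _, e = committed_doses_per_intake("male", "gas", s_table, w)
    return CALIBRATION_EFFECTIVE_COEFF / e


def calibrated_s_table(s_table: SCoefficientTable | None = None) -> SCoefficientTable:
    s_table = SCoefficientTable.default() if s_table is None else s_table
    return s_table.scaled(calibration_factor(s_table))


def annual_dose(
    scenario: ExposureScenario,
    s_table: SCoefficientTable | None = None,
    weights: TissueWeights | None = None,
    calibrated: bool = False,
    deposition_table: DepositionTable | None = None,
) -> DoseReport:
    """Annual equivalent/effective doses for one scenario, both fractions.

    Gas and aerosol are reported separately (the aerosol fraction is small
    under typical hot-room conditions but is always printed).
    """
    s_table = SCoefficientTable.default() if s_table is None else s_table
    if calibrated:
        s_table = calibrated_s_table(s_table)
    weights = TissueWeights.default() if weights is None else weights
    sex = scenario.subject.sex
    fractions = {}
    for fraction, form in _FORM_OF_FRACTION.items():
        per_intake = single_intake(scenario, fraction)
        h1, e1 = committed_doses_per_intake(
            sex, form, s_table, weights, intake=per_intake, deposition_table=deposition_table
        )
        n = scenario.intakes_per_year
        fractions[fraction] = FractionDoses(
            annual_intake=annual_intake(scenario, fraction),
            tissue_equivalent={t: v * n for t, v in h1.items()},
            effective=e1 * n,
        )
    return DoseReport(
        profession=scenario.profession, sex=sex, calibrated=calibrated, fractions=fractions
    )


def sex_averaged_effective(reports: list[DoseReport], fraction: str) -> float:
    """ICRP-style sex-averaged annual effective dose for one fraction."""
    return sum(r.fractions[fraction].effective for r in reports) / len(reports)


def dose_coefficient(
    sex: str,
    form: str,
    s_table: SCoefficientTable | None = None,
    calibrated: bool = False,
) -> dict:
    """Committed dose per unit inhaled activity (Sv/Bq).

    Returns ``{"effective": ..., "thyroid": ...}``; enables the simplified
    coefficient x intake workflow in place of full modelling.
    """
    s_table = SCoefficientTable.default() if s_table is None else s_table
    if calibrated:
        s_table = calibrated_s_table(s_table)
    w = TissueWeights.default()
    h, e = committed_doses_per_intake(sex, form, s_table, w, intake=1.0)
    return {"effective": e, "thyroid": h["thyroid"]}


def career_ratio(annual_thyroid: float, years: float, reference: float) -> float:
    """Career thyroid dose (annual x years) relative to a reference dose."""
    if reference <= 0:
        raise ValueError("reference dose must be > 0")
    return annual_thyroid * years / reference


def format_report(report: DoseReport) -> str:
    """Human-readable annual dose table, two significant figures."""
    lines = [
        f"Annual doses — {report.profession}, {report.sex}"
        + (" (calibrated S-table)" if report.calibrated else ""),
    ]
    for fraction, fd in report.fractions.items():
        lines.append(f"  {fraction} fraction (annual intake {fd.annual_intake:.3g} Bq):")
        lines.append(f"    thyroid equivalent: {fd.tissue_equivalent['thyroid']:.2g} Sv")
        lines.append(f"    effective:          {fd.effective:.2g} Sv")
    return "\n".join(lines)
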