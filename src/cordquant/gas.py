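"""Oxygen-dose arithmetic for normobaric and hyperbaric exposure arms.

An exposure arm is an inspired oxygen fraction (FiO2) breathed at an ambient
pressure in atmospheres absolute (ATA).  From those two numbers the module
derives the inspired and alveolar oxygen partial pressures and the physically
dissolved plasma O2 content, using the alveolar gas equation with standard
physiological constants:

    PIO2 = FiO2 * (Pb - PH2O)           Pb = pressure_ata * 760 mmHg
    PAO2 = PIO2 - PaCO2 / RQ            PH2O = 47 mmHg at body temperature
    dissolved O2 = alpha * PaO2         alpha = 0.003 mL O2 / dL / mmHg

A zero alveolar-arterial gradient is assumed throughout, so PAO2 stands in
for PaO2.  ``isooxic_fraction`` inverts the dry-gas product FiO2 * ATA to
find the oxygen fraction that keeps inspired O2 at the room-air level while
the ambient pressure rises — the "pressure control" arm of a hyperbaric
study (10.5% O2 at 2 ATA matches 21% at 1 ATA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

ATM_MMHG = 760.0
"""One atmosphere absolute, in mmHg."""

WATER_VAPOR_MMHG = 47.0
"""Saturated water-vapor pressure at 37 degrees C, mmHg."""

DEFAULT_PACO2_MMHG = 40.0
DEFAULT_RQ = 0.8
DEFAULT_ALPHA_ML_DL_MMHG = 0.003


def inspired_po2(fio2: float, pressure_ata: float) -> float:
    """Inspired (tracheal) PO2 in mmHg after water-vapor saturation.

    Parameters
    ----------
    fio2 : float
        Fraction of inspired oxygen, in (0, 1].
    pressure_ata : float
        Ambient pressure in atmospheres absolute (> 0).
    """
    if not 0.0 < fio2 <= 1.0:
        raise ValueError(f"fio2 must be in (0, 1], got {fio2}")
    if pressure_ata <= 0.0:
        raise ValueError(f"pressure_ata must be > 0, got {pressure_ata}")
    return fio2 * (pressure_ata * ATM_MMHG - WATER_VAPOR_MMHG)


def alveolar_po2(
    fio2: float,
    pressure_ata: float,
    paco2: float = DEFAULT_PACO2_MMHG,
    rq: float = DEFAULT_RQ,
) -> float:
    """Alveolar PO2 (mmHg) via the alveolar gas equation.

    With the default PaCO2 = 40 mmHg and RQ = 0.8 this yields ~100 mmHg on
    room air, 663 mmHg on 100% O2 at 1 ATA and 2183 mmHg at 3 ATA.
    """
    if paco2 < 0.0:
        raise ValueError(f"paco2 must be >= 0, got {paco2}")
    if rq <= 0.0:
        raise ValueError(f"rq must be > 0, got {rq}")
    return inspired_po2(fio2, pressure_ata) - paco2 / rq


def dissolved_o2(pao2_mmhg: float, alpha: float = DEFAULT_ALPHA_ML_DL_MMHG) -> float:
    """Physically dissolved plasma O2 content, mL O2 per dL plasma.

    Henry's-law linearity: ``alpha`` (mL/dL/mmHg) times arterial PO2.
    Hemoglobin-bound O2 is deliberately excluded.
    """
    if pao2_mmhg < 0.0:
        raise ValueError(f"pao2_mmhg must be >= 0, got {pao2_mmhg}")
    if alpha < 0.0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    return alpha * pao2_mmhg


def isooxic_fraction(
    pressure_ata: float,
    reference_fio2: float = 0.21,
    reference_ata: float = 1.0,
) -> float:
    """FiO2 at ``pressure_ata`` matching the reference inspired dry-gas O2.

    Solves f * pressure_ata = reference_fio2 * reference_ata, the dry-gas
    partial-pressure match: at 2 ATA the normoxic control fraction is
    exactly 0.105 (10.5% O2).  Matching water-vapor-corrected (wet) inspired
    pressures instead gives slightly less O2 (10.17% at 2 ATA, since the
    fixed 47 mmHg vapor bite shrinks relatively as pressure rises); that
    variant is available via :func:`isooxic_fraction_wet`.
    """
    if pressure_ata <= 0.0:
        raise ValueError(f"pressure_ata must be > 0, got {pressure_ata}")
    f = reference_fio2 * reference_ata / pressure_ata
    if f > 1.0:
        raise ValueError(
            f"isooxic fraction {f:.3f} exceeds 1 at {pressure_ata} ATA"
        )
    return f


def isooxic_fraction_wet(
    pressure_ata: float,
    reference_fio2: float = 0.21,
    reference_ata: float = 1.0,
) -> float:
    """FiO2 matching the water-vapor-corrected inspired PO2 of the reference."""
    target = inspired_po2(reference_fio2, reference_ata)
    denom = pressure_ata * ATM_MMHG - WATER_VAPOR_MMHG
    if denom <= 0.0:
        raise ValueError("ambient pressure below water-vapor pressure")
    f = target / denom
    if f > 1.0:
        raise ValueError(
            f"isooxic fraction {f:.3f} exceeds 1 at {pressure_ata} ATA"
        )
    return f


@dataclass(frozen=True)
class GasCondition:
    """One exposure arm and its derived oxygen pressures.

    Attributes
    ----------
    fio2 : float
        Inspired oxygen fraction in (0, 1].
    pressure_ata : float
        Ambient pressure, atmospheres absolute.
    label : str
        Free-text arm name (e.g. ``"HBO 3 ATA"``).
    """

    fio2: float
    pressure_ata: float
    label: str = ""
    paco2: float = DEFAULT_PACO2_MMHG
    rq: float = DEFAULT_RQ
    alpha: float = DEFAULT_ALPHA_ML_DL_MMHG
    inspired_po2_mmhg: float = field(init=False)
    alveolar_po2_mmhg: float = field(init=False)
    dissolved_o2_ml_dl: float = field(init=False)

    def __post_init__(self) -> None:
        pio2 = inspired_po2(self.fio2, self.pressure_ata)
        pao2 = alveolar_po2(self.fio2, self.pressure_ata, self.paco2, self.rq)
        object.__setattr__(self, "inspired_po2_mmhg", pio2)
        object.__setattr__(self, "alveolar_po2_mmhg", pao2)
        object.__setattr__(
            self, "dissolved_o2_ml_dl", dissolved_o2(max(pao2, 0.0), self.alpha)
        )


def study_arms() -> list[GasCondition]:
    """The six exposure arms of a normobaric/hyperbaric O2-therapy design."""
    return [
        GasCondition(0.21, 1.0, label="normoxia 1 ATA"),
        GasCondition(isooxic_fraction(2.0), 2.0, label="pressure control 2 ATA"),
        GasCondition(1.0, 1.0, label="100% O2 1 ATA"),
        GasCondition(1.0, 2.0, label="100% O2 2 ATA"),
        GasCondition(1.0, 3.0, label="100% O2 3 ATA"),
    ]
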