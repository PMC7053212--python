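"""Organ absorbed-dose coefficients and doses (MIRD schema, self-dose).

The MIRD formalism gives the absorbed dose to an organ as

    D = A_tilde x Delta x phi / m

with ``A_tilde`` the time-integrated activity, ``Delta`` the emitted energy
per decay, ``phi`` the absorbed fraction and ``m`` the target mass.  Working
per gram of tissue (TIAC in MBq.h/g per MBq injected) the mass cancels and
the dose coefficient is

    d [Gy/MBq] = TIAC x 3600 [s/h] x 1e6 [decays/(MBq.s)]
                 x Delta [J/decay] x 1000 [g/kg] x phi.

The Auger/conversion electrons have sub-cellular range, so their organ-level
absorbed fraction is unity; the photon channel uses an organ-specific
self-absorbed fraction (Monte Carlo, see ``photon_transport``) and is
reported separately from the electron channel because the two carry very
different microscopic dose patterns.  Photon dose is self-dose only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .biokinetics import TiacCoefficient
from .physics import EmissionSpectrum, KEV_TO_J

__all__ = [
    "OrganModel",
    "DoseCoefficient",
    "DoseReport",
    "electron_dose_coefficient",
    "photon_dose_coefficient",
    "dose_at_activity",
    "build_dose_report",
]

# MBq.h/g -> decays/s factors folded with J/keV and g/kg; multiply by keV/decay
# to get Gy/MBq per unit TIAC.
_GY_PER_MBQ_H_PER_G_PER_KEV = 3600.0 * 1.0e6 * KEV_TO_J * 1000.0


@dataclass(frozen=True)
class OrganModel:
    """Whole-organ model: name, mass, photon self-absorbed fraction.

    The default kidney mass follows the MIRD Pamphlet 19 kidney scaled to
    the mouse (298 mg).
    """

    name: str
    mass_g: float = 0.298
    photon_self_af: float | None = None

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("organ mass must be positive")
        if self.photon_self_af is not None and not 0.0 < self.photon_self_af < 1.0:
            raise ValueError("photon absorbed fraction must lie in (0, 1)")


@dataclass(frozen=True)
class DoseCoefficient:
    """Absorbed dose per unit injected activity, split by emission channel."""

    organ: str
    electron_gy_per_mbq: float
    photon_gy_per_mbq: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.electron_gy_per_mbq < 0 or self.photon_gy_per_mbq < 0:
            raise ValueError("dose coefficients must be non-negative")

    @property
    def total_gy_per_mbq(self) -> float:
        return self.electron_gy_per_mbq + self.photon_gy_per_mbq


def electron_dose_coefficient(
    tiac: TiacCoefficient, spectrum: EmissionSpectrum
) -> float:
    """Electron-channel dose coefficient in Gy/MBq (absorbed fraction 1).

    ``TIAC = 1 MBq.s/g per MBq`` (i.e. 1/3600 MBq.h/g) with the 19.2 keV
    electron energy gives 3.076e-6 Gy/MBq, the unit-conversion anchor.
    """
    return (
        tiac.value
        * spectrum.electron_energy_per_decay
        * _GY_PER_MBQ_H_PER_G_PER_KEV
    )


def photon_dose_coefficient(
    tiac: TiacCoefficient,
    spectrum: EmissionSpectrum,
    organ: OrganModel,
) -> float:
    """Photon-channel (self-dose) coefficient in Gy/MBq.

    Scales the electron-channel formula by the photon/electron per-decay
    energy ratio and the organ's photon self-absorbed fraction.
    """
    if organ.photon_self_af is None:
        raise ValueError(
            f"{organ.name}: photon self-absorbed fraction not set; supply a "
            "value or estimate one with photon_transport"
        )
    ratio = spectrum.photon_energy_per_decay / spectrum.electron_energy_per_decay
    return electron_dose_coefficient(tiac, spectrum) * ratio * organ.photon_self_af


def dose_at_activity(coeff_gy_per_mbq: float, injected_mbq: float) -> float:
    """Absorbed dose in Gy for an injected activity in MBq."""
    if injected_mbq < 0:
        raise ValueError("injected activity must be non-negative")
    return coeff_gy_per_mbq * injected_mbq


@dataclass
class DoseReport:
    """Per-organ, per-channel doses at one injected activity."""

    injected_mbq: float
    coefficients: dict[str, DoseCoefficient]
    doses_gy: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "injected_mbq": self.injected_mbq,
            "coefficients": {k: asdict(v) for k, v in self.coefficients.items()},
            "doses_gy": self.doses_gy,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "DoseReport":
        raw = json.loads(text)
        coeffs = {
            k: DoseCoefficient(**v) for k, v in raw["coefficients"].items()
        }
        return cls(
            injected_mbq=raw["injected_mbq"],
            coefficients=coeffs,
            doses_gy=raw["doses_gy"],
        )


def build_dose_report(
    coefficients: list[DoseCoefficient], injected_mbq: float
) -> DoseReport:
    """Assemble a serializable per-organ dose report at one activity."""
    if not coefficients:
        raise ValueError("need at least one dose coefficient")
    names = [c.organ for c in coefficients]
    if len(set(names)) != len(names):
        raise ValueError("duplicate organ entries")
    if injected_mbq < 0:
        raise ValueError("injected activity must be non-negative")
    doses = {
        c.organ: {
            "electron": dose_at_activity(c.electron_gy_per_mbq, injected_mbq),
            "photon": dose_at_activity(c.photon_gy_per_mbq, injected_mbq),
            "total": dose_at_activity(c.total_gy_per_mbq, injected_mbq),
        }
        for c in coefficients
    }
    return DoseReport(
        injected_mbq=injected_mbq,
        coefficients={c.organ: c for c in coefficients},
        doses_gy=doses,
    )
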