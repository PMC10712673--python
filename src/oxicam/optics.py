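"""Hemoglobin optics: absorption table and the closed-form SpO2 inversion.

SpO2 is defined as the oxyhemoglobin fraction of total hemoglobin,

    SpO2 = c_HbO2 / (c_HbO2 + c_Hb) * 100 .

Under the Lambert-Beer model, cardiac pulsation modulates the optical path
length through the subcutaneous arteries, so the pulsatile absorbance change
at wavelength ``lam`` is proportional to

    dA(lam) = { eps_HbO2(lam) c_HbO2 + eps_Hb(lam) c_Hb } * dl .

The path-length term ``dl`` cancels in the two-wavelength ratio
``r = dA(lam1) / dA(lam2)``, which can therefore be inverted for SpO2 without
any per-subject calibration:

    SpO2 = 100 * [eps_Hb(1) - eps_Hb(2) r]
               / [eps_Hb(1) - eps_HbO2(1) + (eps_HbO2(2) - eps_Hb(2)) r] .

This module deliberately never clips the inversion output to [0, 100]; raw
invertibility is preserved and clipping is a reporting decision made by the
estimation pipeline.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

__all__ = [
    "Band",
    "WavelengthBand",
    "AbsorptionTable",
    "AbsorbanceRatio",
    "default_table",
    "forward_ratio",
    "spo2_from_ratio",
]


class Band(str, Enum):
    """Labels of the three illumination bands."""

    G = "G"
    R = "R"
    NIR = "NIR"


@dataclass(frozen=True)
class WavelengthBand:
    """A single illumination band identified by label and center wavelength."""

    label: Band
    center_nm: float

    def __post_init__(self) -> None:
        if self.center_nm <= 0:
            raise ValueError(f"center_nm must be positive, got {self.center_nm}")


#: Default band set: green / red / near-infrared LED centers (nm).
DEFAULT_BANDS: dict[Band, WavelengthBand] = {
    Band.G: WavelengthBand(Band.G, 524.0),
    Band.R: WavelengthBand(Band.R, 630.0),
    Band.NIR: WavelengthBand(Band.NIR, 850.0),
}


@dataclass(frozen=True)
class AbsorbanceRatio:
    """Dimensionless ratio of pulsatile absorbance changes dA(lam1)/dA(lam2)."""

    value: float
    band_pair: tuple[Band, Band] = (Band.R, Band.NIR)


class AbsorptionTable:
    """Molar absorption coefficients of HbO2 and Hb per band.

    Parameters
    ----------
    coefficients
        Mapping from band label to ``(eps_hbo2, eps_hb)`` in L mol^-1 cm^-1.
    centers_nm
        Optional mapping from band label to center wavelength.

    Notes
    -----
    All coefficients must be strictly positive.  For SpO2 inversion with the
    (R, NIR) pair the table must have the qualitative shape of the hemoglobin
    spectra: deoxyhemoglobin dominates at red and oxyhemoglobin at NIR; this
    guarantees a nonzero denominator in the inversion for physical ratios.
    """

    def __init__(
        self,
        coefficients: Mapping[Band | str, tuple[float, float]],
        centers_nm: Mapping[Band | str, float] | None = None,
    ) -> None:
        self._eps: dict[Band, tuple[float, float]] = {}
        for key, (e_o2, e_hb) in coefficients.items():
            band = Band(key)
            if e_o2 <= 0 or e_hb <= 0:
                raise ValueError(
                    f"absorption coefficients must be strictly positive, "
                    f"got ({e_o2}, {e_hb}) for band {band.value}"
                )
            self._eps[band] = (float(e_o2), float(e_hb))
        self.centers_nm = {
            Band(k): float(v) for k, v in (centers_nm or {}).items()
        }

    @property
    def bands(self) -> tuple[Band, ...]:
        return tuple(self._eps)

    def eps_hbo2(self, band: Band | str) -> float:
        return self._eps[Band(band)][0]

    def eps_hb(self, band: Band | str) -> float:
        return self._eps[Band(band)][1]

    def validate_pair(self, band_pair: tuple[Band | str, Band | str]) -> None:
        for b in band_pair:
            if Band(b) not in self._eps:
                raise KeyError(f"band {b!r} not in absorption table")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        rows = ", ".join(
            f"{b.value}: ({o:g}, {h:g})" for b, (o, h) in self._eps.items()
        )
        return f"AbsorptionTable({rows})"


def load_table(path) -> AbsorptionTable:
    """Read an absorption table from delimited text.

    Expected columns (tab- or whitespace-separated): band label, center
    wavelength in nm, eps_hbo2, eps_hb.  Lines starting with ``#`` are
    comments.
    """
    coeffs: dict[str, tuple[float, float]] = {}
    centers: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns "
                    f"(band, center_nm, eps_hbo2, eps_hb), got {len(parts)}"
                )
            label, center, e_o2, e_hb = parts
            coeffs[label] = (float(e_o2), float(e_hb))
            centers[label] = float(center)
    if not coeffs:
        raise ValueError(f"{path}: no coefficient rows found")
    return AbsorptionTable(coeffs, centers)


def default_table() -> AbsorptionTable:
    """The packaged hemoglobin absorption table at the 524/630/850 nm bands."""
    ref = importlib.resources.files("oxicam.data") / "absorption_table.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_table(path)


def forward_ratio(
    spo2: float,
    table: AbsorptionTable,
    band_pair: tuple[Band | str, Band | str] = (Band.R, Band.NIR),
) -> AbsorbanceRatio:
    """Absorbance-change ratio predicted by the Lambert-Beer model at a given SpO2.

    With saturation fraction ``s = spo2/100`` the hemoglobin mix contributes
    ``eps_HbO2 s + eps_Hb (1 - s)`` per band (total concentration and the
    pulsatile path length cancel in the ratio).
    """
    if not 0.0 <= spo2 <= 100.0:
        raise ValueError(f"spo2 must be in [0, 100], got {spo2}")
    table.validate_pair(band_pair)
    b1, b2 = Band(band_pair[0]), Band(band_pair[1])
    s = spo2 / 100.0
    num = table.eps_hbo2(b1) * s + table.eps_hb(b1) * (1.0 - s)
    den = table.eps_hbo2(b2) * s + table.eps_hb(b2) * (1.0 - s)
    return AbsorbanceRatio(num / den, (b1, b2))


def spo2_from_ratio(
    ratio: AbsorbanceRatio | float,
    table: AbsorptionTable,
    band_pair: tuple[Band | str, Band | str] | None = None,
    denom_rtol: float = 1e-12,
) -> float:
    """Invert an absorbance-change ratio to SpO2 in percent.

    Parameters
    ----------
    ratio
        An :class:`AbsorbanceRatio`, or a bare positive float (then
        ``band_pair`` must be given or defaults to (R, NIR)).
    table
        Absorption coefficients covering both bands.
    denom_rtol
        The inversion denominator must exceed this tolerance relative to the
        numerator scale; below it a ``ZeroDivisionError`` is raised instead of
        returning an unbounded value.

    Returns
    -------
    float
        SpO2 in percent.  The result is *not* clipped to [0, 100].
    """
    if isinstance(ratio, AbsorbanceRatio):
        r = ratio.value
        pair = band_pair or ratio.band_pair
    else:
        r = float(ratio)
        pair = band_pair or (Band.R, Band.NIR)
    if not r > 0:
        raise ValueError(f"absorbance ratio must be positive, got {r}")
    table.validate_pair(pair)
    b1, b2 = Band(pair[0]), Band(pair[1])
    e_hb1, e_hb2 = table.eps_hb(b1), table.eps_hb(b2)
    e_o1, e_o2 = table.eps_hbo2(b1), table.eps_hbo2(b2)
    num = e_hb1 - e_hb2 * r
    den = (e_hb1 - e_o1) + (e_o2 - e_hb2) * r
    scale = max(abs(e_hb1), abs(e_hb2 * r))
    if abs(den) < denom_rtol * scale:
        raise ZeroDivisionError(
            f"SpO2 inversion denominator {den:g} below tolerance "
            f"({denom_rtol:g} relative to numerator scale {scale:g})"
        )
    return 100.0 * num / den
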