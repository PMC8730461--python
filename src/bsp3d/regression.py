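"""Mass/stature linear regression estimator and literature reference tables.

Each segment parameter is modelled as ``B0 + B1·W + B2·H`` with W the body
mass in kg and H the stature in cm.  The default male segment-mass
coefficients are the classic photogrammetric cadaver-population triples
(Zatsiorsky–Seluyanov); they were developed on young adult Caucasian males
(mass 73±9.1 kg, height 1.74±0.06 m), so inputs far outside that envelope
trigger a warning.

Default coefficient coverage:

* male segment masses — full Zatsiorsky–Seluyanov triples;
* female segment masses — a documented proportional model (de Leva's
  adjusted female mass fractions: ``B0 = 0, B1 = fraction, B2 = 0``), a
  pragmatic stand-in where the sex-specific triples are not available;
* moments of inertia — not shipped: requesting them raises
  :class:`CoefficientsUnavailableError` unless a user coefficient table
  provides the triples.

Segment lengths and proximal-COM percentages have no regression form; the
estimator exposes population mean values instead
(:func:`reference_anthro`), with explicit not-available errors where the
source tables have no entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .segmentation import BASE_LABELS

logger = logging.getLogger(__name__)

PARAMETERS = ("mass", "I_ap", "I_ml", "I_long")


class RegressionError(KeyError):
    """Unknown sex/segment/parameter."""


class CoefficientsUnavailableError(RegressionError):
    """A coefficient triple or reference value is not provided by the
    shipped tables (never silently defaulted)."""


#: (B0, B1 per kg body mass, B2 per cm stature) — male segment masses, kg
MALE_MASS_COEFFICIENTS: dict[str, tuple[float, float, float]] = {
    "head": (1.296, 0.0171, 0.0143),
    "torso": (8.2144, 0.1862, -0.0584),
    "abdomen": (7.181, 0.2234, -0.0663),
    "pelvis": (-7.498, 0.0976, 0.04896),
    "thigh": (-2.649, 0.1463, 0.0137),
    "shank": (-1.592, 0.0362, 0.0121),
    "foot": (-0.829, 0.0077, 0.0073),
    "arm": (0.250, 0.03012, -0.0027),
    "forearm": (0.3185, 0.01445, -0.00114),
    "hand": (-0.1165, 0.0036, 0.00175),
}

#: female segment masses as fractions of body mass (proportional model,
#: de Leva's adjusted female fractions): B0 = 0, B1 = fraction, B2 = 0
FEMALE_MASS_FRACTIONS: dict[str, float] = {
    "head": 0.0668,
    "torso": 0.1545,
    "abdomen": 0.1465,
    "pelvis": 0.1247,
    "thigh": 0.1478,
    "shank": 0.0481,
    "foot": 0.0129,
    "arm": 0.0255,
    "forearm": 0.0138,
    "hand": 0.0056,
}


def _default_table() -> dict[tuple[str, str, str], tuple[float, float, float]]:
    table: dict[tuple[str, str, str], tuple[float, float, float]] = {}
    for segment, triple in MALE_MASS_COEFFICIENTS.items():
        table[("male", segment, "mass")] = triple
    for segment, frac in FEMALE_MASS_FRACTIONS.items():
        table[("female", segment, "mass")] = (0.0, frac, 0.0)
    return table


@dataclass
class RegressionCoefficients:
    """Per (sex, segment, parameter) linear-model triples."""

    table: dict[tuple[str, str, str], tuple[float, float, float]]

    def __post_init__(self) -> None:
        for sex in ("male", "female"):
            for segment in BASE_LABELS:
                if (sex, segment, "mass") not in self.table:
                    raise RegressionError(f"missing mass triple for {sex} {segment}")
        flagged = [
            (sex, segment, param)
            for sex in ("male", "female")
            for segment in BASE_LABELS
            for param in PARAMETERS[1:]
            if (sex, segment, param) not in self.table
        ]
        if flagged:
            logger.info(
                "%d inertia coefficient triples unavailable in this table", len(flagged)
            )

    @classmethod
    def defaults(cls) -> "RegressionCoefficients":
        return cls(_default_table())

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegressionCoefficients":
        """Load ``sex,segment,parameter,B0,B1,B2`` rows, layered over the
        shipped defaults."""
        df = pd.read_csv(path)
        required = {"sex", "segment", "parameter", "B0", "B1", "B2"}
        if not required <= set(df.columns):
            raise RegressionError(f"coefficient CSV needs columns {sorted(required)}")
        table = _default_table()
        for row in df.itertuples():
            if row.parameter not in PARAMETERS:
                raise RegressionError(f"unknown parameter {row.parameter!r}")
            table[(str(row.sex), str(row.segment), str(row.parameter))] = (
                float(row.B0),
                float(row.B1),
                float(row.B2),
            )
        return cls(table)

    def triple(self, sex: str, segment: str, parameter: str) -> tuple[float, float, float]:
        if sex not in ("male", "female"):
            raise RegressionError(f"unknown sex {sex!r}")
        if segment not in BASE_LABELS:
            raise RegressionError(f"unknown segment {segment!r}")
        if parameter not in PARAMETERS:
            raise RegressionError(f"unknown parameter {parameter!r}")
        key = (sex, segment, parameter)
        if key not in self.table:
            raise CoefficientsUnavailableError(
                f"no {parameter} coefficient triple for {sex} {segment} in this table"
            )
        return self.table[key]


def regress_bsp(
    sex: str,
    body_mass: float,
    stature: float,
    coefficients: RegressionCoefficients | None = None,
    parameters: tuple[str, ...] = ("mass",),
) -> dict[str, dict[str, float]]:
    """Evaluate ``B0 + B1·W + B2·H`` for every segment.

    Parameters
    ----------
    sex : {"male", "female"}
    body_mass : float
        W in kg.
    stature : float
        H in cm (note: participant tables often print metres).
    parameters : tuple of str
        Which parameters to evaluate; requesting a parameter whose triple is
        not in the table raises :class:`CoefficientsUnavailableError`.
    """
    coefficients = coefficients or RegressionCoefficients.defaults()
    if not (30.0 < body_mass < 150.0) or not (130.0 < stature < 210.0):
        warnings.warn(
            f"inputs (W={body_mass} kg, H={stature} cm) are outside the model "
            "population envelope; extrapolated estimates may be unreliable",
            stacklevel=2,
        )
    out: dict[str, dict[str, float]] = {}
    for segment in BASE_LABELS:
        out[segment] = {}
        for parameter in parameters:
            b0, b1, b2 = coefficients.triple(sex, segment, parameter)
            out[segment][parameter] = b0 + b1 * body_mass + b2 * stature
    return out


# ---------------------------------------------------------------------------
# reference anthropometry (population mean length / pCOM tables)
# ---------------------------------------------------------------------------

_NA = None

#: population mean longitudinal lengths (cm) and pCOM (%) per sex/segment;
#: ``None`` marks entries the source tables leave blank.
REFERENCE_LENGTH_CM: dict[str, dict[str, float | None]] = {
    "male": {
        "head": 24.3, "torso": 24.2, "abdomen": 21.6, "pelvis": 25.2,
        "thigh": 42.2, "shank": 44.0, "foot": 25.8, "arm": 28.2,
        "forearm": 26.9, "hand": 18.8,
    },
    "female": {
        "head": 24.6, "torso": 22.8, "abdomen": 20.5, "pelvis": _NA,
        "thigh": 36.9, "shank": 43.9, "foot": 22.8, "arm": 27.5,
        "forearm": 26.4, "hand": 17.0,
    },
}

REFERENCE_PCOM_PCT: dict[str, dict[str, float | None]] = {
    "male": {
        "head": 50.0, "torso": 50.7, "abdomen": 45.0, "pelvis": 35.4,
        "thigh": 41.0, "shank": 44.0, "foot": 44.2, "arm": 42.3,
        "forearm": 42.7, "hand": 36.9,
    },
    "female": {
        "head": 48.4, "torso": 50.5, "abdomen": 45.1, "pelvis": 34.8,
        "thigh": 46.1, "shank": 40.3, "foot": 40.1, "arm": 44.0,
        "forearm": 42.6, "hand": 35.0,
    },
}


def reference_anthro(sex: str, segment: str) -> tuple[float, float]:
    """Population mean (length cm, pCOM %) for a sex/segment.

    Raises :class:`CoefficientsUnavailableError` for entries the source
    tables leave blank (never substitutes a default).
    """
    if sex not in REFERENCE_LENGTH_CM:
        raise RegressionError(f"unknown sex {sex!r}")
    if segment not in BASE_LABELS:
        raise RegressionError(f"unknown segment {segment!r}")
    length = REFERENCE_LENGTH_CM[sex][segment]
    pcom = REFERENCE_PCOM_PCT[sex][segment]
    if length is None or pcom is None:
        raise CoefficientsUnavailableError(
            f"no reference length/pCOM available for {sex} {segment}"
        )
    return float(length), float(pcom)
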