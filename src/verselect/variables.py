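"""Clinical variable registry and extended-variable naming.

The analysis tracks 19 continuous measurements collected at each health
examination.  Every base variable is expanded into four longitudinal
statistics over a subject's two predictor exams:

* ``C`` -- closest value (second exam),
* ``M`` -- mean of the two exams,
* ``S`` -- sample standard deviation of the two exams,
* ``D`` -- difference (second minus first).

Extended variables are named ``"<code>(<stat>)"``, e.g. ``"BUN(S)"``, and
that naming round-trips through :func:`extended_name` / :func:`parse_extended`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

STATISTICS = ("C", "M", "S", "D")


@dataclass(frozen=True)
class ClinicalVariable:
    """A base measurement: short code, full name, unit and a typical
    location/scale for a middle-aged screening population (used as the
    synthetic generator's default baseline)."""

    code: str
    name: str
    unit: str
    mean: float
    sd: float


#: The 19 screening measurements, in canonical (V1..V19) order.
VARIABLES: tuple[ClinicalVariable, ...] = (
    ClinicalVariable("BF", "Body Fat", "%", 28.0, 6.0),
    ClinicalVariable("BMI", "Body Mass Index", "kg/m^2", 26.5, 3.5),
    ClinicalVariable("BUN", "Blood Urea Nitrogen", "mg/dL", 16.0, 4.5),
    ClinicalVariable("DBP", "Diastolic Blood Pressure", "mmHg", 82.0, 10.0),
    ClinicalVariable("FPG", "Fasting Plasma Glucose", "mg/dL", 108.0, 25.0),
    ClinicalVariable("Hb", "Hemoglobin", "g/dL", 14.2, 1.5),
    ClinicalVariable("HC", "Hip Circumference", "cm", 98.0, 6.0),
    ClinicalVariable("HDL", "High-Density Lipoprotein Cholesterol", "mg/dL", 44.0, 10.0),
    ClinicalVariable("IOP", "Intraocular Pressure", "mmHg", 15.0, 3.0),
    ClinicalVariable("LDL", "Low-Density Lipoprotein Cholesterol", "mg/dL", 128.0, 32.0),
    ClinicalVariable("MCV", "Mean Cell Volume", "fl", 89.0, 5.0),
    ClinicalVariable("RBC", "Red Blood Cells", "10^6/uL", 4.8, 0.45),
    ClinicalVariable("r-GT", "Gamma Glutamyl Transpeptidase", "U/L", 38.0, 30.0),
    ClinicalVariable("SBP", "Systolic Blood Pressure", "mmHg", 130.0, 15.0),
    ClinicalVariable("SGOT", "Serum Glutamic Oxaloacetic Transaminase", "U/L", 26.0, 12.0),
    ClinicalVariable("SGPT", "Serum Glutamic Pyruvic Transaminase", "U/L", 32.0, 20.0),
    ClinicalVariable("TG", "Triglyceride", "mg/dL", 175.0, 80.0),
    ClinicalVariable("UA", "Uric Acid", "mg/dL", 6.3, 1.4),
    ClinicalVariable("WC", "Waist Circumference", "cm", 90.0, 9.0),
)

VARIABLE_CODES: tuple[str, ...] = tuple(v.code for v in VARIABLES)
N_VARIABLES = len(VARIABLES)
N_EXTENDED = N_VARIABLES * len(STATISTICS)  # 76 for the default panel

_BY_CODE = {v.code: v for v in VARIABLES}


def get_variable(code: str) -> ClinicalVariable:
    try:
        return _BY_CODE[code]
    except KeyError:
        raise KeyError(
            f"unknown clinical variable {code!r}; expected one of {VARIABLE_CODES}"
        ) from None


def extended_name(code: str, statistic: str) -> str:
    """Compose an extended-variable column name, e.g. ``('BUN','S') -> 'BUN(S)'``."""
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}, got {statistic!r}")
    return f"{code}({statistic})"


def parse_extended(name: str) -> tuple[str, str]:
    """Inverse of :func:`extended_name`; raises ``ValueError`` on malformed names."""
    if not name.endswith(")") or "(" not in name:
        raise ValueError(f"malformed extended-variable name {name!r}")
    code, _, stat = name[:-1].rpartition("(")
    if stat not in STATISTICS:
        raise ValueError(f"malformed extended-variable name {name!r}")
    return code, stat


def iter_extended(codes: tuple[str, ...] = VARIABLE_CODES) -> Iterator[str]:
    """All extended names, grouped per base variable in C, M, S, D order."""
    for code in codes:
        for stat in STATISTICS:
            yield extended_name(code, stat)


EXTENDED_NAMES: tuple[str, ...] = tuple(iter_extended())
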