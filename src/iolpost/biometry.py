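"""Domain types, units and validation for post-refractive IOL biometry.

Units are fixed throughout the package: millimetres for lengths, diopters
for powers and refractions.  There is no automatic unit detection — only
validation with actionable error messages, because silent unit coercion is
the dominant failure mode in IOL software.

The anterior chamber depth (ACD) follows the optical-biometer convention:
corneal epithelium to lens front surface, the quantity consumed by the
Haigis effective-lens-position model.  Constants files must state which
convention their a-constants were optimized for.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

# validity ranges (inclusive) for construction-time checks
AXIAL_LENGTH_RANGE = (15.0, 40.0)   # mm
ACD_RANGE = (1.5, 6.0)              # mm
K_RANGE = (25.0, 60.0)              # D
IOL_POWER_RANGE = (-10.0, 40.0)     # D
TARGET_SE_LIMIT = 10.0              # |D|
POSTOP_SE_LIMIT = 15.0              # |D|

COHORT_COLUMNS = [
    "eye_id",
    "axial_length_mm",
    "acd_mm",
    "k_tcrp_4mm_d",
    "k_trp_4mm_d",
    "implanted_power_d",
    "target_se_d",
    "postop_sphere_d",
    "postop_cylinder_d",
]


def _check_range(name: str, value: float, lo: float, hi: float, unit: str) -> None:
    if not (lo <= value <= hi):
        hint = ""
        if name == "axial_length" and 0 < value < 0.05:
            hint = (
                " (value looks like metres — this package expects millimetres;"
                " check the input units)"
            )
        raise ValidationError(
            f"{name}={value!r} outside valid range [{lo}, {hi}] {unit}{hint}"
        )


@dataclass(frozen=True)
class EyeBiometry:
    """One eye's preoperative optical biometry.

    Parameters
    ----------
    axial_length : float
        Axial length in mm.
    acd : float
        Anterior chamber depth in mm (epithelium to lens front, the Haigis
        ELP convention).
    k_tcrp_4mm : float or None
        Scheimpflug total corneal refractive power, 4.0 mm zone, in D.
    k_trp_4mm : float or None
        Scheimpflug total refractive power, 4.0 mm zone, in D.
    eye_id : str
        Opaque identifier.
    """

    axial_length: float
    acd: float
    k_tcrp_4mm: float | None = None
    k_trp_4mm: float | None = None
    eye_id: str = ""

    def __post_init__(self) -> None:
        _check_range("axial_length", self.axial_length, *AXIAL_LENGTH_RANGE, "mm")
        _check_range("acd", self.acd, *ACD_RANGE, "mm")
        if self.k_tcrp_4mm is None and self.k_trp_4mm is None:
            raise ValidationError(
                "at least one of k_tcrp_4mm / k_trp_4mm must be present"
            )
        for name, k in (("k_tcrp_4mm", self.k_tcrp_4mm), ("k_trp_4mm", self.k_trp_4mm)):
            if k is not None:
                _check_range(name, k, *K_RANGE, "D")

    def k_value(self, source: str) -> float:
        """Return the K of the requested map (``'tcrp4'`` or ``'trp4'``)."""
        k = {"tcrp4": self.k_tcrp_4mm, "trp4": self.k_trp_4mm}.get(source)
        if source not in ("tcrp4", "trp4"):
            raise ValueError(f"unknown K source {source!r}; expected 'tcrp4' or 'trp4'")
        if k is None:
            raise ValidationError(f"eye {self.eye_id!r} has no {source} K value")
        return k


@dataclass(frozen=True)
class IOLConstants:
    """Haigis a-constant triple plus the optical constants of the model.

    The a-constants are user-supplied configuration (e.g. community-optimized
    ULIB values for a specific lens model); they are never treated as ground
    truth by this package.  ``n_aqueous`` is the refractive index used for
    aqueous and vitreous in the thin-lens vergence model; ``vertex_distance``
    is the spectacle-to-cornea distance in mm used to move refractions
    between planes.
    """

    a0: float
    a1: float
    a2: float
    n_aqueous: float = 1.336
    vertex_distance: float = 12.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.n_aqueous > 1:
            raise ValidationError(f"n_aqueous={self.n_aqueous} must exceed 1")
        if not (0 <= self.vertex_distance <= 20):
            raise ValidationError(
                f"vertex_distance={self.vertex_distance} mm outside [0, 20]"
            )


@dataclass(frozen=True)
class Refraction:
    """Sphere/cylinder refraction in D.

    The cylinder sign convention (plus- vs minus-cylinder) is deliberately
    not interpreted: only the spherical equivalent is consumed downstream,
    and SE is invariant under cross-cylinder transposition.
    """

    sphere: float
    cylinder: float = 0.0

    @property
    def spherical_equivalent(self) -> float:
        return self.sphere + self.cylinder / 2.0

    def transposed(self) -> "Refraction":
        """Cross-cylinder transposition (sphere+cyl, −cyl); same SE."""
        return Refraction(self.sphere + self.cylinder, -self.cylinder)


@dataclass(frozen=True)
class SurgeryOutcome:
    """Implanted IOL power, surgical target and postoperative refraction."""

    implanted_power: float
    target_refraction: float
    postop_refraction: Refraction

    def __post_init__(self) -> None:
        _check_range("implanted_power", self.implanted_power, *IOL_POWER_RANGE, "D")
        if abs(self.target_refraction) > TARGET_SE_LIMIT:
            raise ValidationError(
                f"target_refraction={self.target_refraction} D outside "
                f"±{TARGET_SE_LIMIT}"
            )
        se = self.postop_refraction.spherical_equivalent
        if abs(se) > POSTOP_SE_LIMIT:
            raise ValidationError(
                f"postoperative SE={se} D outside ±{POSTOP_SE_LIMIT}"
            )


@dataclass
class RowRejection:
    """Why one CSV row was rejected during loading."""

    row: int            # 0-based data-row index
    message: str


@dataclass
class CohortLoadResult:
    """Validated records plus a report of rejected rows."""

    records: list[tuple[EyeBiometry, SurgeryOutcome]]
    rejected: list[RowRejection] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def load_cohort(path: str | Path) -> CohortLoadResult:
    """Load and validate a cohort CSV (one eye per row).

    Required columns: ``eye_id, axial_length_mm, acd_mm, k_tcrp_4mm_d,
    k_trp_4mm_d, implanted_power_d, target_se_d, postop_sphere_d,
    postop_cylinder_d``.  Rows failing validation are collected in
    ``rejected`` with their 0-based row index and the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s) {missing}; "
            f"expected schema {COHORT_COLUMNS}"
        )
    result = CohortLoadResult(records=[])
    for i, row in df.iterrows():
        try:
            bio = EyeBiometry(
                axial_length=float(row["axial_length_mm"]),
                acd=float(row["acd_mm"]),
                k_tcrp_4mm=_opt(row["k_tcrp_4mm_d"]),
                k_trp_4mm=_opt(row["k_trp_4mm_d"]),
                eye_id=str(row["eye_id"]),
            )
            outcome = SurgeryOutcome(
                implanted_power=float(row["implanted_power_d"]),
                target_refraction=float(row["target_se_d"]),
                postop_refraction=Refraction(
                    float(row["postop_sphere_d"]), float(row["postop_cylinder_d"])
                ),
            )
        except (ValidationError, ValueError) as exc:
            result.rejected.append(RowRejection(row=int(i), message=f"row {i}: {exc}"))
            continue
        result.records.append((bio, outcome))
    return result


def write_cohort(
    records: Iterable[tuple[EyeBiometry, SurgeryOutcome]], path: str | Path
) -> None:
    """Write records back to the cohort CSV schema (round-trips load_cohort)."""
    rows = []
    for bio, outcome in records:
        rows.append(
            {
                "eye_id": bio.eye_id,
                "axial_length_mm": bio.axial_length,
                "acd_mm": bio.acd,
                "k_tcrp_4mm_d": bio.k_tcrp_4mm,
                "k_trp_4mm_d": bio.k_trp_4mm,
                "implanted_power_d": outcome.implanted_power,
                "target_se_d": outcome.target_refraction,
                "postop_sphere_d": outcome.postop_refraction.sphere,
                "postop_cylinder_d": outcome.postop_refraction.cylinder,
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def load_constants(path: str | Path) -> tuple[IOLConstants, str]:
    """Read an IOL-constants config (JSON or TOML by extension).

    Keys: ``a0, a1, a2`` (required), ``n_aqueous``, ``vertex_distance_mm``,
    ``label``, ``k_mode`` (keratometric handling, ``direct`` or ``reindex``;
    default ``direct``).  Returns ``(constants, k_mode)``.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    try:
        constants = IOLConstants(
            a0=float(data["a0"]),
            a1=float(data["a1"]),
            a2=float(data["a2"]),
            n_aqueous=float(data.get("n_aqueous", 1.336)),
            vertex_distance=float(data.get("vertex_distance_mm", 12.0)),
            label=str(data.get("label", "")),
        )
    except KeyError as exc:
        raise SchemaError(f"{path.name}: missing constants key {exc}") from exc
    k_mode = str(data.get("k_mode", "direct"))
    if k_mode not in ("direct", "reindex"):
        raise SchemaError(f"{path.name}: k_mode must be 'direct' or 'reindex'")
    return constants, k_mode


def records_to_frame(
    records: Sequence[tuple[EyeBiometry, SurgeryOutcome]]
) -> pd.DataFrame:
    """Flatten records into a DataFrame (column-per-field, one eye per row)."""
    rows = []
    for bio, outcome in records:
        rows.append(
            {
                "eye_id": bio.eye_id,
                "axial_length_mm": bio.axial_length,
                "acd_mm": bio.acd,
                "k_tcrp_4mm_d": bio.k_tcrp_4mm,
                "k_trp_4mm_d": bio.k_trp_4mm,
                "implanted_power_d": outcome.implanted_power,
                "target_se_d": outcome.target_refraction,
                "postop_se_d": outcome.postop_refraction.spherical_equivalent,
            }
        )
    return pd.DataFrame(rows)
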