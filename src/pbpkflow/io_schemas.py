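"""Parsing and validation of the three user-supplied input files.

The batch pipeline takes at most three files from the user:

1. a mandatory *compound file* (CSV or XLSX) listing the compounds to
   simulate with their identifiers and optional per-compound trial options;
2. an optional *experimental file* (XLSX) with measured fraction unbound
   (FU), blood-to-plasma ratio (BP) and hepatic intrinsic clearance (CLINT);
3. an optional *additional physicochemical file* (XLSX) supplementing the
   automatically curated data.

Header matching is case-insensitive and order-independent; unrecognised
columns are ignored.  Blank cells mean "missing"; an explicit 0 is a value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "DoseUnits",
    "CompoundType",
    "CompoundRecord",
    "ExperimentalRow",
    "AdditionalRow",
    "parse_compound_file",
    "parse_experimental_file",
    "parse_additional_file",
    "write_compound_file",
    "write_experimental_file",
    "write_additional_file",
]


class SchemaError(ValueError):
    """A mandatory header is absent or misspelled."""


class ValidationError(ValueError):
    """The file has the right headers but invalid content (e.g. duplicate codes)."""


class DoseUnits(str, enum.Enum):
    MG = "mg"
    MG_PER_KG = "mg/kg"
    MG_PER_M2 = "mg.m-2"


class CompoundType(str, enum.Enum):
    """Declared ionisation character of a compound (as supplied by a data source)."""

    ACID = "acid"
    BASE = "base"
    NEUTRAL = "neutral"
    AMPHOLYTE = "ampholyte"


@dataclass
class CompoundRecord:
    """One row of the mandatory compound file.

    ``code`` is the unique batch-local identifier; ``name`` falls back to the
    code when the compound name is blank.  A record with an empty ``inchikey``
    cannot be matched against the snapshot databases and is flagged as not
    simulatable.
    """

    code: str
    name: str = ""
    inchikey: str = ""
    smiles: str = ""
    vss_method: Optional[int] = None  # 1, 2 or 3
    dose: Optional[float] = None  # > 0
    dose_units: Optional[DoseUnits] = None

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("compound code must be non-empty")
        if not self.name:
            self.name = self.code

    @property
    def simulatable(self) -> bool:
        return bool(self.inchikey)


@dataclass
class ExperimentalRow:
    """One row of the optional experimental-PK file (any subset may be missing)."""

    code: str
    fu: Optional[float] = None  # fraction in (0, 1]
    bp: Optional[float] = None  # blood:plasma ratio > 0
    clint: Optional[float] = None  # µL/min/10^6 cells, >= 0


@dataclass
class AdditionalRow:
    """One row of the optional additional-physchem file."""

    code: str
    logp: Optional[float] = None
    pka_acid: Optional[float] = None
    pka_base: Optional[float] = None
    hbd: Optional[float] = None
    psa: Optional[float] = None
    mw: Optional[float] = None
    type: Optional[CompoundType] = None


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        df = pd.read_excel(path, dtype=object)
    else:
        df = pd.read_csv(path, dtype=object, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _header_map(df: pd.DataFrame) -> dict[str, str]:
    """lower-cased header -> actual column name (first occurrence wins)."""
    out: dict[str, str] = {}
    for col in df.columns:
        key = col.lower()
        if key not in out:
            out[key] = col
    return out


def _cell_str(value: object) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    if pd.isna(value):
        return ""
    return str(value).strip()


def _cell_float(
    value: object, *, column: str, code: str, warnings: list[str]
) -> Optional[float]:
    """Coerce a cell to float; uncoercible non-blank text warns and yields missing."""
    text = _cell_str(value)
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        warnings.append(
            f"row {code!r}: value {text!r} in column {column!r} is not numeric; treated as missing"
        )
        return None


# ---------------------------------------------------------------------------
# compound file
# ---------------------------------------------------------------------------

_COMPOUND_MANDATORY = ("code", "compound", "inchikey", "smiles")
_COMPOUND_OPTIONAL = ("vssmethod", "dose", "doseunits")

_DOSE_UNIT_ALIASES = {
    "mg": DoseUnits.MG,
    "mg/kg": DoseUnits.MG_PER_KG,
    "mg.m-2": DoseUnits.MG_PER_M2,
    "mg.m^-2": DoseUnits.MG_PER_M2,
    "mg/m2": DoseUnits.MG_PER_M2,
}


def parse_compound_file(path: str | Path) -> tuple[list[CompoundRecord], list[str]]:
    """Parse the mandatory compound file (CSV or XLSX).

    Returns the parsed records and a list of human-readable warnings.  Raises
    :class:`SchemaError` when any of the four mandatory headers (Code,
    Compound, InChIKey, SMILES) is absent, and :class:`ValidationError` on
    duplicate codes.
    """
    df = _read_table(path)
    headers = _header_map(df)
    missing = [h for h in _COMPOUND_MANDATORY if h not in headers]
    if missing:
        raise SchemaError(
            "compound file is missing mandatory header(s): "
            + ", ".join(sorted(missing))
        )

    warnings: list[str] = []
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        code = _cell_str(row[headers["code"]])
        if not code:
            warnings.append("row with empty Code skipped")
            continue
        if code in seen:
            raise ValidationError(f"duplicate compound code {code!r}")
        seen.add(code)

        vss_method: Optional[int] = None
        if "vssmethod" in headers:
            raw = _cell_float(
                row[headers["vssmethod"]], column="VssMethod", code=code,
                warnings=warnings,
            )
            if raw is not None:
                if int(raw) not in (1, 2, 3) or raw != int(raw):
                    raise ValidationError(
                        f"row {code!r}: VssMethod must be 1, 2 or 3 (got {raw})"
                    )
                vss_method = int(raw)

        dose: Optional[float] = None
        if "dose" in headers:
            dose = _cell_float(
                row[headers["dose"]], column="Dose", code=code, warnings=warnings
            )
            if dose is not None and dose <= 0:
                raise ValidationError(f"row {code!r}: Dose must be > 0 (got {dose})")

        dose_units: Optional[DoseUnits] = None
        if "doseunits" in headers:
            text = _cell_str(row[headers["doseunits"]]).lower()
            if text:
                if text not in _DOSE_UNIT_ALIASES:
                    raise ValidationError(
                        f"row {code!r}: DoseUnits must be one of mg, mg/kg, mg.m-2 (got {text!r})"
                    )
                dose_units = _DOSE_UNIT_ALIASES[text]

        record = CompoundRecord(
            code=code,
            name=_cell_str(row[headers["compound"]]),
            inchikey=_cell_str(row[headers["inchikey"]]),
            smiles=_cell_str(row[headers["smiles"]]),
            vss_method=vss_method,
            dose=dose,
            dose_units=dose_units,
        )
        if not record.simulatable:
            warnings.append(
                f"compound {code!r} has no InChIKey and will not be simulated"
            )
        records.append(record)
    return records, warnings


# ---------------------------------------------------------------------------
# experimental file
# ---------------------------------------------------------------------------

_EXPERIMENTAL_MANDATORY = ("code", "fu", "bp", "clint")


def parse_experimental_file(
    path: str | Path, known_codes: Optional[set[str]] = None
) -> tuple[list[ExperimentalRow], list[str]]:
    """Parse the optional experimental-PK file (XLSX with Code/FU/BP/CLINT).

    Rows whose code is not in ``known_codes`` (when given) are reported in the
    warnings and dropped.  A missing mandatory header raises
    :class:`SchemaError` — the workflow cannot incorporate the user-provided
    experimental data in that case.
    """
    df = _read_table(path)
    headers = _header_map(df)
    missing = [h for h in _EXPERIMENTAL_MANDATORY if h not in headers]
    if missing:
        raise SchemaError(
            "cannot incorporate the user-provided experimental data: missing "
            "mandatory header(s): " + ", ".join(h.upper() for h in sorted(missing))
        )

    warnings: list[str] = []
    rows: list[ExperimentalRow] = []
    for _, raw in df.iterrows():
        code = _cell_str(raw[headers["code"]])
        if not code:
            warnings.append("experimental row with empty Code skipped")
            continue
        if known_codes is not None and code not in known_codes:
            warnings.append(
                f"experimental row {code!r} does not match any compound code; dropped"
            )
            continue
        rows.append(
            ExperimentalRow(
                code=code,
                fu=_cell_float(raw[headers["fu"]], column="FU", code=code, warnings=warnings),
                bp=_cell_float(raw[headers["bp"]], column="BP", code=code, warnings=warnings),
                clint=_cell_float(
                    raw[headers["clint"]], column="CLINT", code=code, warnings=warnings
                ),
            )
        )
    return rows, warnings


# ---------------------------------------------------------------------------
# additional physchem file
# ---------------------------------------------------------------------------

_ADDITIONAL_NUMERIC = {
    "logp": "logp",
    "pka(acid)": "pka_acid",
    "pka(base)": "pka_base",
    "hbd": "hbd",
    "psa": "psa",
    "mw": "mw",
}


def parse_additional_file(path: str | Path) -> tuple[list[AdditionalRow], list[str]]:
    """Parse the optional additional-physchem file (XLSX; only Code mandatory)."""
    df = _read_table(path)
    headers = _header_map(df)
    if "code" not in headers:
        raise SchemaError("additional data file is missing the mandatory header: Code")

    warnings: list[str] = []
    rows: list[AdditionalRow] = []
    for _, raw in df.iterrows():
        code = _cell_str(raw[headers["code"]])
        if not code:
            warnings.append("additional-data row with empty Code skipped")
            continue
        kwargs: dict[str, object] = {}
        for header, attr in _ADDITIONAL_NUMERIC.items():
            if header in headers:
                kwargs[attr] = _cell_float(
                    raw[headers[header]], column=header, code=code, warnings=warnings
                )
        ctype: Optional[CompoundType] = None
        if "type" in headers:
            text = _cell_str(raw[headers["type"]]).lower()
            if text:
                try:
                    ctype = CompoundType(text)
                except ValueError:
                    warnings.append(
                        f"row {code!r}: TYPE {text!r} not one of acid/base/neutral/"
                        "ampholyte; treated as missing"
                    )
        rows.append(AdditionalRow(code=code, type=ctype, **kwargs))  # type: ignore[arg-type]
    return rows, warnings


# ---------------------------------------------------------------------------
# writers (round-trip support; also used by the fixture generator)
# ---------------------------------------------------------------------------


def write_compound_file(records: list[CompoundRecord], path: str | Path) -> None:
    data = {
        "Code": [r.code for r in records],
        "Compound": [r.name for r in records],
        "InChIKey": [r.inchikey for r in records],
        "SMILES": [r.smiles for r in records],
    }
    if any(r.vss_method is not None for r in records):
        data["VssMethod"] = [r.vss_method for r in records]
    if any(r.dose is not None for r in records):
        data["Dose"] = [r.dose for r in records]
    if any(r.dose_units is not None for r in records):
        data["DoseUnits"] = [
            r.dose_units.value if r.dose_units else None for r in records
        ]
    _write_table(pd.DataFrame(data), path)


def write_experimental_file(rows: list[ExperimentalRow], path: str | Path) -> None:
    _write_table(
        pd.DataFrame(
            {
                "Code": [r.code for r in rows],
                "FU": [r.fu for r in rows],
                "BP": [r.bp for r in rows],
                "CLINT": [r.clint for r in rows],
            }
        ),
        path,
    )


def write_additional_file(rows: list[AdditionalRow], path: str | Path) -> None:
    _write_table(
        pd.DataFrame(
            {
                "Code": [r.code for r in rows],
                "logP": [r.logp for r in rows],
                "pka(acid)": [r.pka_acid for r in rows],
                "pka(base)": [r.pka_base for r in rows],
                "HBD": [r.hbd for r in rows],
                "PSA": [r.psa for r in rows],
                "MW": [r.mw for r in rows],
                "TYPE": [r.type.value if r.type else None for r in rows],
            }
        ),
        path,
    )


def _write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
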