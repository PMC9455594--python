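"""Automated curation of physicochemical and experimental PK data.

Data sources are local SQLite *snapshots* with five tables mirroring the
coverage of the live resources they emulate:

========== =========================================================
table      parameters supplied
========== =========================================================
chembl     MW, LogP, pKa list, type, PSA, HBD, LogD7.4, SMILES
susdat     MW, LogP, CAS, DTXSID, SMILES
obach      fu, CLsys (CAS-keyed)
wambaugh   fu, CLint (CAS/DTXSID-keyed)
chem_phys  fu, CLint, BP — possibly several replicate rows per compound
========== =========================================================

Curation order is fixed: the ChEMBL-like table is queried first by InChIKey;
only compounds absent from it are looked up in the SusDat-like table.  The
experimental tables are then queried by CAS/DTXSID (resolved through SusDat),
replicates within ``chem_phys`` are arithmetic-averaged, and a user-chosen
operation (arithmetic mean, geometric mean, median, minimum, maximum) reduces
the cross-database fu and CLint values to one number each.  User-supplied
files can override or supplement each stage; every non-missing field carries
a provenance tag naming the source that won.
"""

from __future__ import annotations

import sqlite3
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_schemas import AdditionalRow, CompoundRecord, CompoundType, ExperimentalRow

__all__ = [
    "CuratedParameters",
    "SnapshotDB",
    "ConfigError",
    "AGGREGATION_OPERATIONS",
    "aggregate",
    "collect_physchem",
    "merge_additional",
    "collect_experimental",
    "merge_user_experimental",
    "curated_table_frame",
    "export_curated_table",
]


class ConfigError(ValueError):
    """Invalid run configuration (unknown operation, negative threshold, ...)."""


@dataclass
class CuratedParameters:
    """Merged physicochemical + experimental values for one compound.

    ``provenance`` maps field name -> source tag: one of ``chembl``,
    ``susdat``, ``additional``, ``obach``, ``wambaugh``, ``chem_phys``,
    ``user``, ``assumed`` or ``predicted``.  ``fu_values``/``clint_values``
    keep the per-database values before cross-database reduction (only
    retained when the operation is ``None``).
    """

    code: str
    name: str = ""
    inchikey: str = ""
    smiles: str = ""
    mw: Optional[float] = None
    logp: Optional[float] = None
    pka_values: list[float] = field(default_factory=list)
    type: Optional[CompoundType] = None
    psa: Optional[float] = None
    hbd: Optional[float] = None
    logd74_extracted: Optional[float] = None
    cas: Optional[str] = None
    dtxsid: Optional[str] = None
    fu: Optional[float] = None
    fu_sd: Optional[float] = None
    clint: Optional[float] = None
    clint_sd: Optional[float] = None
    bp: Optional[float] = None
    clsys: Optional[float] = None  # extracted but never consumed downstream
    fu_values: Optional[dict[str, float]] = None
    clint_values: Optional[dict[str, float]] = None
    vss_method: Optional[int] = None
    dose: Optional[float] = None
    dose_units: Optional[str] = None
    provenance: dict[str, str] = field(default_factory=dict)

    def set(self, fieldname: str, value, source: str) -> None:
        setattr(self, fieldname, value)
        self.provenance[fieldname] = source

    def has(self, fieldname: str) -> bool:
        value = getattr(self, fieldname)
        if fieldname == "pka_values":
            return bool(value)
        return value is not None

    @property
    def has_any_physchem(self) -> bool:
        return any(
            self.has(f) for f in ("mw", "logp", "psa", "hbd", "pka_values", "type")
        )


# ---------------------------------------------------------------------------
# snapshot access
# ---------------------------------------------------------------------------

SNAPSHOT_SCHEMA = {
    "chembl": (
        "inchikey TEXT PRIMARY KEY, mw REAL, logp REAL, pka TEXT, type TEXT, "
        "psa REAL, hbd INTEGER, logd REAL, smiles TEXT"
    ),
    "susdat": (
        "inchikey TEXT PRIMARY KEY, mw REAL, logp REAL, cas TEXT, dtxsid TEXT, "
        "smiles TEXT"
    ),
    "obach": "cas TEXT, fu REAL, clsys REAL",
    "wambaugh": "cas TEXT, dtxsid TEXT, fu REAL, clint REAL",
    "chem_phys": "cas TEXT, dtxsid TEXT, fu REAL, clint REAL, bp REAL",
}


class SnapshotDB:
    """Read access to a five-table SQLite snapshot.

    Loader hook: any SQLite file with the :data:`SNAPSHOT_SCHEMA` tables works,
    so locally-built dumps of the real resources can be dropped in.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(f"snapshot database not found: {self.path}")
        self._conn = sqlite3.connect(f"file:{self.path}?mode=ro", uri=True)
        self._conn.row_factory = sqlite3.Row

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "SnapshotDB":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @staticmethod
    def create(path: str | Path) -> sqlite3.Connection:
        """Create an empty snapshot with the expected schema (writable handle)."""
        conn = sqlite3.connect(path)
        for table, cols in SNAPSHOT_SCHEMA.items():
            conn.execute(f"CREATE TABLE IF NOT EXISTS {table} ({cols})")
        conn.commit()
        return conn

    # -- physchem tables ----------------------------------------------------

    def chembl_lookup(self, inchikey: str) -> Optional[sqlite3.Row]:
        cur = self._conn.execute(
            "SELECT * FROM chembl WHERE inchikey = ?", (inchikey,)
        )
        return cur.fetchone()

    def susdat_lookup(self, inchikey: str) -> Optional[sqlite3.Row]:
        cur = self._conn.execute(
            "SELECT * FROM susdat WHERE inchikey = ?", (inchikey,)
        )
        return cur.fetchone()

    # -- experimental tables ------------------------------------------------

    def _rows_by_ids(
        self, table: str, cas: Optional[str], dtxsid: Optional[str], has_dtxsid: bool
    ) -> list[sqlite3.Row]:
        # DTXSID preferred when the table carries it; CAS only as fallback.
        if has_dtxsid and dtxsid:
            rows = self._conn.execute(
                f"SELECT * FROM {table} WHERE dtxsid = ?", (dtxsid,)
            ).fetchall()
            if rows:
                return rows
        if cas:
            return self._conn.execute(
                f"SELECT * FROM {table} WHERE cas = ?", (cas,)
            ).fetchall()
        return []

    def obach_rows(self, cas: Optional[str], dtxsid: Optional[str]) -> list[sqlite3.Row]:
        return self._rows_by_ids("obach", cas, dtxsid, has_dtxsid=False)

    def wambaugh_rows(self, cas, dtxsid) -> list[sqlite3.Row]:
        return self._rows_by_ids("wambaugh", cas, dtxsid, has_dtxsid=True)

    def chem_phys_rows(self, cas, dtxsid) -> list[sqlite3.Row]:
        return self._rows_by_ids("chem_phys", cas, dtxsid, has_dtxsid=True)


def encode_pka_list(values: Iterable[float]) -> str:
    return ";".join(repr(float(v)) for v in values)


def decode_pka_list(text: Optional[str]) -> list[float]:
    if not text:
        return []
    return [float(tok) for tok in str(text).split(";") if tok.strip()]


# ---------------------------------------------------------------------------
# stage 1: physchem collection (ChEMBL before SusDat, fixed hierarchy)
# ---------------------------------------------------------------------------


def collect_physchem(
    compounds: Sequence[CompoundRecord],
    snapshot: SnapshotDB,
    missing_info: bool = False,
) -> tuple[dict[str, CuratedParameters], list[str], list[str]]:
    """Query the ChEMBL-like then SusDat-like snapshot for every compound.

    Returns ``(table, not_found, lacking)``: the curated table keyed by code
    (one row per input compound — never dropped), the codes found in neither
    source, and — only when ``missing_info`` is set — the codes with some
    physicochemical information missing (PSA, pKa, HBD, type, MW or LogP).
    """
    table: dict[str, CuratedParameters] = {}
    not_found: list[str] = []
    lacking: list[str] = []
    for record in compounds:
        row = CuratedParameters(
            code=record.code,
            name=record.name,
            inchikey=record.inchikey,
            smiles=record.smiles,
            vss_method=record.vss_method,
            dose=record.dose,
            dose_units=record.dose_units.value if record.dose_units else None,
        )
        table[record.code] = row
        if not record.inchikey:
            not_found.append(record.code)
            continue

        hit = snapshot.chembl_lookup(record.inchikey)
        if hit is not None:
            for col, fieldname in (
                ("mw", "mw"),
                ("logp", "logp"),
                ("psa", "psa"),
                ("hbd", "hbd"),
                ("logd", "logd74_extracted"),
            ):
                if hit[col] is not None:
                    row.set(fieldname, float(hit[col]), "chembl")
            if hit["pka"]:
                row.set("pka_values", decode_pka_list(hit["pka"]), "chembl")
            if hit["type"]:
                row.set("type", CompoundType(str(hit["type"]).lower()), "chembl")
            if hit["smiles"] and not row.smiles:
                row.smiles = str(hit["smiles"])
        else:
            sus = snapshot.susdat_lookup(record.inchikey)
            if sus is None:
                not_found.append(record.code)
                continue
            for col, fieldname in (("mw", "mw"), ("logp", "logp")):
                if sus[col] is not None:
                    row.set(fieldname, float(sus[col]), "susdat")
            if sus["cas"]:
                row.set("cas", str(sus["cas"]), "susdat")
            if sus["dtxsid"]:
                row.set("dtxsid", str(sus["dtxsid"]), "susdat")
            if sus["smiles"] and not row.smiles:
                row.smiles = str(sus["smiles"])

        if missing_info and any(
            not row.has(f) for f in ("mw", "logp", "psa", "hbd", "pka_values", "type")
        ):
            lacking.append(record.code)

    return table, not_found, (lacking if missing_info else [])


def resolve_cas_dtxsid(
    table: dict[str, CuratedParameters], snapshot: SnapshotDB
) -> None:
    """Fill CAS/DTXSID from the SusDat-like snapshot for compounds lacking them."""
    for row in table.values():
        if not row.inchikey or (row.cas and row.dtxsid):
            continue
        sus = snapshot.susdat_lookup(row.inchikey)
        if sus is None:
            continue
        if sus["cas"] and not row.cas:
            row.set("cas", str(sus["cas"]), "susdat")
        if sus["dtxsid"] and not row.dtxsid:
            row.set("dtxsid", str(sus["dtxsid"]), "susdat")


# ---------------------------------------------------------------------------
# stage 2: user-supplied additional physchem data
# ---------------------------------------------------------------------------

_ADDITIONAL_FIELDS = ("logp", "hbd", "psa", "mw", "type")


def merge_additional(
    table: dict[str, CuratedParameters],
    additional_rows: Sequence[AdditionalRow],
    override_existing_data: bool = False,
) -> list[str]:
    """Fold the additional-physchem file into the curated table.

    With ``override_existing_data`` the user file wins on overlap; otherwise
    the automatically curated value is retained.  Either way, additional
    values fill gaps.  Returns warnings (codes absent from the table).
    """
    warnings: list[str] = []
    for add in additional_rows:
        row = table.get(add.code)
        if row is None:
            warnings.append(
                f"additional-data code {add.code!r} not in compound file; skipped"
            )
            continue
        for fieldname in _ADDITIONAL_FIELDS:
            value = getattr(add, fieldname)
            if value is None:
                continue
            if override_existing_data or not row.has(fieldname):
                row.set(fieldname, value, "additional")
        pkas = [v for v in (add.pka_acid, add.pka_base) if v is not None]
        if pkas and (override_existing_data or not row.has("pka_values")):
            row.set("pka_values", sorted(pkas), "additional")
    return warnings


# ---------------------------------------------------------------------------
# stage 3: httk-style experimental collection
# ---------------------------------------------------------------------------


def _geometric_mean(values: Sequence[float]) -> float:
    if any(v <= 0 for v in values):
        # geometric mean undefined at 0/negatives; arithmetic fallback
        return float(np.mean(values))
    return float(np.exp(np.mean(np.log(values))))


AGGREGATION_OPERATIONS: dict[str, Callable[[Sequence[float]], float]] = {
    "arithmetic mean": lambda v: float(np.mean(v)),
    "geometric mean": _geometric_mean,
    "median": lambda v: float(np.median(v)),
    "minimum": lambda v: float(np.min(v)),
    "maximum": lambda v: float(np.max(v)),
}


def aggregate(values: Sequence[float], operation: str) -> float:
    try:
        fn = AGGREGATION_OPERATIONS[operation]
    except KeyError:
        raise ConfigError(
            f"unknown aggregation operation {operation!r}; expected one of "
            + ", ".join(sorted(AGGREGATION_OPERATIONS)) + ", or None"
        ) from None
    return fn(values)


def collect_experimental(
    table: dict[str, CuratedParameters],
    snapshot: SnapshotDB,
    db_flags: Optional[dict[str, bool]] = None,
    fu_operation: Optional[str] = "arithmetic mean",
    clint_operation: Optional[str] = "arithmetic mean",
) -> list[str]:
    """Collect fu/CLint/BP from the three httk-like tables and reduce them.

    ``db_flags`` selects the tables ({'obach','wambaugh','chem_phys'} -> bool;
    all true by default).  Replicate rows inside ``chem_phys`` are first
    arithmetic-averaged per compound; the ``fu_operation``/``clint_operation``
    then reduce the per-database values to one number.  Standard deviations
    are recorded across >=2 cross-database values.  Passing ``None`` for an
    operation keeps all values (the table is then not simulation-ready).
    BP is taken from ``chem_phys`` only, with no cross-database operation.
    """
    flags = {"obach": True, "wambaugh": True, "chem_phys": True}
    if db_flags:
        unknown = set(db_flags) - set(flags)
        if unknown:
            raise ConfigError(f"unknown database flag(s): {sorted(unknown)}")
        flags.update(db_flags)
    if not any(flags.values()):
        raise ConfigError("at least one experimental database must be selected")
    for op in (fu_operation, clint_operation):
        if op is not None and op not in AGGREGATION_OPERATIONS:
            raise ConfigError(
                f"unknown aggregation operation {op!r}; expected one of "
                + ", ".join(sorted(AGGREGATION_OPERATIONS)) + ", or None"
            )

    warnings: list[str] = []
    resolve_cas_dtxsid(table, snapshot)

    for row in table.values():
        fu_by_db: dict[str, float] = {}
        clint_by_db: dict[str, float] = {}

        if flags["obach"]:
            hits = snapshot.obach_rows(row.cas, row.dtxsid)
            fus = [r["fu"] for r in hits if r["fu"] is not None]
            clsys = [r["clsys"] for r in hits if r["clsys"] is not None]
            if fus:
                fu_by_db["obach"] = float(np.mean(fus))
            if clsys:
                row.set("clsys", float(np.mean(clsys)), "obach")
        if flags["wambaugh"]:
            hits = snapshot.wambaugh_rows(row.cas, row.dtxsid)
            fus = [r["fu"] for r in hits if r["fu"] is not None]
            clints = [r["clint"] for r in hits if r["clint"] is not None]
            if fus:
                fu_by_db["wambaugh"] = float(np.mean(fus))
            if clints:
                clint_by_db["wambaugh"] = float(np.mean(clints))
        if flags["chem_phys"]:
            hits = snapshot.chem_phys_rows(row.cas, row.dtxsid)
            fus = [r["fu"] for r in hits if r["fu"] is not None]
            clints = [r["clint"] for r in hits if r["clint"] is not None]
            bps = [r["bp"] for r in hits if r["bp"] is not None]
            # replicate values from this single source are arithmetic-averaged
            if fus:
                fu_by_db["chem_phys"] = float(np.mean(fus))
            if clints:
                clint_by_db["chem_phys"] = float(np.mean(clints))
            if bps:
                row.set("bp", float(np.mean(bps)), "chem_phys")

        for values, operation, fieldname, sd_field, keep_field in (
            (fu_by_db, fu_operation, "fu", "fu_sd", "fu_values"),
            (clint_by_db, clint_operation, "clint", "clint_sd", "clint_values"),
        ):
            if not values:
                continue
            if operation is None:
                setattr(row, keep_field, dict(values))
                warnings.append(
                    f"{row.code}: {fieldname} operation is None; all values retained, "
                    "table not simulation-ready"
                )
                continue
            if operation == "geometric mean" and any(v <= 0 for v in values.values()):
                warnings.append(
                    f"{row.code}: geometric mean of {fieldname} undefined for "
                    "non-positive values; arithmetic mean used"
                )
            source = "+".join(sorted(values)) if len(values) > 1 else next(iter(values))
            row.set(fieldname, aggregate(list(values.values()), operation), source)
            if len(values) >= 2:
                row.set(sd_field, float(statistics.stdev(values.values())), source)
    return warnings


def table_simulation_ready(table: dict[str, CuratedParameters]) -> bool:
    """False when any compound still carries unreduced fu/CLint value lists."""
    return not any(
        row.fu_values is not None or row.clint_values is not None
        for row in table.values()
    )


# ---------------------------------------------------------------------------
# stage 4: user-supplied measured experimental values
# ---------------------------------------------------------------------------


def merge_user_experimental(
    table: dict[str, CuratedParameters],
    experimental_rows: Sequence[ExperimentalRow],
    mean_flag: bool = False,
    thresholds: Optional[dict[str, float]] = None,
) -> list[str]:
    """Fold the user experimental file into the table.

    Values at or below the per-parameter threshold (default 0) are discarded
    before merging.  When both a user and an httk-derived value survive,
    ``mean_flag`` false keeps the user value; true takes their arithmetic
    mean.  A user value always fills a gap.
    """
    th = {"fu": 0.0, "clint": 0.0, "bp": 0.0}
    if thresholds:
        unknown = set(thresholds) - set(th)
        if unknown:
            raise ConfigError(f"unknown threshold parameter(s): {sorted(unknown)}")
        for key, value in thresholds.items():
            if value < 0:
                raise ConfigError(f"threshold for {key} must be >= 0 (got {value})")
            th[key] = float(value)

    warnings: list[str] = []
    for exp in experimental_rows:
        row = table.get(exp.code)
        if row is None:
            warnings.append(
                f"experimental code {exp.code!r} not in compound file; skipped"
            )
            continue
        for fieldname in ("fu", "bp", "clint"):
            user_value = getattr(exp, fieldname)
            if user_value is None:
                continue
            if user_value <= th[fieldname]:
                warnings.append(
                    f"{exp.code}: user {fieldname}={user_value} at or below "
                    f"threshold {th[fieldname]}; discarded"
                )
                continue
            existing = getattr(row, fieldname)
            if existing is None or not mean_flag:
                row.set(fieldname, float(user_value), "user")
            else:
                row.set(
                    fieldname,
                    float((existing + user_value) / 2.0),
                    f"user+{row.provenance.get(fieldname, 'httk')}",
                )
    return warnings


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_EXPORT_FIELDS = (
    "code", "name", "inchikey", "smiles", "mw", "logp", "type", "psa", "hbd",
    "logd74_extracted", "cas", "dtxsid", "fu", "fu_sd", "clint", "clint_sd",
    "bp", "clsys", "vss_method", "dose", "dose_units",
)


def curated_table_frame(table: dict[str, CuratedParameters]) -> pd.DataFrame:
    """Flatten the curated table to a DataFrame (one row per compound)."""
    rows = []
    for row in table.values():
        rec: dict[str, object] = {f: getattr(row, f) for f in _EXPORT_FIELDS}
        rec["type"] = row.type.value if row.type else None
        rec["pka_values"] = encode_pka_list(row.pka_values) if row.pka_values else None
        rec["provenance"] = ";".join(
            f"{k}={v}" for k, v in sorted(row.provenance.items())
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def export_curated_table(
    table: dict[str, CuratedParameters], path: str | Path
) -> None:
    """Write the curated table to CSV or XLSX depending on the suffix."""
    df = curated_table_frame(table)
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
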