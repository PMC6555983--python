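"""Domain model for administrative-claims analysis of mRCC targeted therapy.

This module owns the vocabulary every other stage speaks: normalized
ICD-9/ICD-10-CM diagnosis codes, prefix-based code sets, the study drug
catalog (agent -> drug class, administration route, and imputed coverage
for IV agents), adverse-event definitions, and the reader/writer for the
four delimited claims tables (enrollment spans, medical claims, pharmacy
fills, IV administrations).

Codes are stored without decimal points and uppercased, so the ``C64.xx``
style wildcard in eligibility definitions becomes the plain prefix
``C64``.  Dates are ISO-8601 in files and ``datetime64`` in memory;
rule engines convert to integer day offsets.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ClaimsModelError(ValueError):
    """Base class for domain-validation failures."""


class CatalogError(ClaimsModelError):
    """Unknown agent or inconsistent catalog entry."""


class SchemaError(ClaimsModelError):
    """A claims table does not conform to the documented schema."""


class DrugClass(str, enum.Enum):
    TK_VEGF = "TK_VEGF"
    MTOR = "MTOR"
    IL2 = "IL2"


class Route(str, enum.Enum):
    ORAL = "ORAL"
    IV = "IV"


#: Label used for the bevacizumab + interferon-alfa combination regimen.
COMBINATION_AGENT = "bevacizumab+ifn_alfa"
BEVACIZUMAB = "bevacizumab"
IFN_ALFA = "ifn_alfa"


def normalize_code(raw_code: str) -> str:
    """Normalize a diagnosis/procedure code: strip, uppercase, drop the dot.

    ``"189.0" -> "1890"``, ``"c64.1" -> "C641"``.
    """
    if raw_code is None:
        raise ClaimsModelError("code must be non-empty")
    code = str(raw_code).strip().upper().replace(".", "")
    if not code:
        raise ClaimsModelError("code must be non-empty")
    return code


@dataclass(frozen=True)
class CodeSet:
    """A named set of normalized code prefixes (ICD-9 and ICD-10 dialects)."""

    name: str
    prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.prefixes:
            raise ClaimsModelError(f"code set {self.name!r} has no prefixes")
        object.__setattr__(
            self, "prefixes", tuple(normalize_code(p) for p in self.prefixes)
        )

    def __contains__(self, code: str) -> bool:
        return match_code(code, self)


def match_code(code: str, code_set: CodeSet) -> bool:
    """True iff ``code`` starts with any prefix of ``code_set``.

    Prefix semantics realize the ``.xx`` wildcard of code-list
    definitions (e.g. prefix ``C64`` matches ``C641``).
    """
    return any(code.startswith(p) for p in code_set.prefixes)


@dataclass(frozen=True)
class DrugCatalogEntry:
    agent: str
    drug_class: DrugClass
    route: Route
    cycle_length_days: int | None = None
    #: Agents that can only appear as a combination partner (IFN-alfa)
    #: never anchor an index date on their own.
    combination_partner_only: bool = False

    def __post_init__(self) -> None:
        if self.route is Route.ORAL and self.cycle_length_days is not None:
            raise CatalogError(f"{self.agent}: oral agents carry no cycle length")
        if self.route is Route.IV:
            if self.cycle_length_days is None or self.cycle_length_days < 1:
                raise CatalogError(f"{self.agent}: IV agents need cycle_length_days >= 1")


class DrugCatalog:
    """The study drug catalog: 8 first-line mRCC agents plus IFN-alfa.

    TK/VEGF inhibitors: sunitinib, sorafenib, pazopanib, axitinib (oral)
    and bevacizumab +/- IFN-alfa (IV).  mTOR inhibitors: everolimus (oral)
    and temsirolimus (IV).  IL-2 (aldesleukin) is its own class, IV.
    IV coverage per administration is imputed from the labeled cycle
    length, which is configurable.
    """

    def __init__(self, entries: Iterable[DrugCatalogEntry]):
        self._entries: dict[str, DrugCatalogEntry] = {}
        for e in entries:
            if e.agent in self._entries:
                raise CatalogError(f"duplicate catalog entry {e.agent!r}")
            self._entries[e.agent] = e

    def __contains__(self, agent: str) -> bool:
        return agent in self._entries or agent == COMBINATION_AGENT

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def agents(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def entry(self, agent: str) -> DrugCatalogEntry:
        if agent == COMBINATION_AGENT:
            # Combination regimen inherits bevacizumab's class and route.
            base = self._entries[BEVACIZUMAB]
            return dataclasses.replace(base, agent=COMBINATION_AGENT)
        try:
            return self._entries[agent]
        except KeyError:
            raise CatalogError(f"unknown agent {agent!r}") from None

    def classify_agent(self, agent: str) -> tuple[DrugClass, Route]:
        e = self.entry(agent)
        return e.drug_class, e.route

    def indexable_agents(self) -> tuple[str, ...]:
        return tuple(a for a, e in self._entries.items() if not e.combination_partner_only)

    def coverage_days(self, agent: str, days_supply: float | None) -> int:
        """Coverage contributed by one claim: days supply (oral) or cycle (IV)."""
        e = self.entry(agent)
        if e.route is Route.ORAL:
            if days_supply is None or not np.isfinite(days_supply) or days_supply <= 0:
                raise ClaimsModelError(
                    f"oral claim for {agent!r} requires days_supply > 0, got {days_supply!r}"
                )
            return int(days_supply)
        return int(e.cycle_length_days)


def default_catalog(cycle_lengths: Mapping[str, int] | None = None) -> DrugCatalog:
    """Catalog of the 8 study agents + IFN-alfa with default IV cycle lengths.

    Default cycles follow US label dosing intervals: bevacizumab every
    14 days, temsirolimus weekly, aldesleukin (IL-2) 14-day courses;
    IFN-alfa is carried with bevacizumab's cadence.  All are overridable.
    """
    cyc = {"bevacizumab": 14, "temsirolimus": 7, "aldesleukin": 14, "ifn_alfa": 14}
    if cycle_lengths:
        cyc.update(cycle_lengths)
    return DrugCatalog(
        [
            DrugCatalogEntry("sunitinib", DrugClass.TK_VEGF, Route.ORAL),
            DrugCatalogEntry("sorafenib", DrugClass.TK_VEGF, Route.ORAL),
            DrugCatalogEntry("pazopanib", DrugClass.TK_VEGF, Route.ORAL),
            DrugCatalogEntry("axitinib", DrugClass.TK_VEGF, Route.ORAL),
            DrugCatalogEntry("everolimus", DrugClass.MTOR, Route.ORAL),
            DrugCatalogEntry("bevacizumab", DrugClass.TK_VEGF, Route.IV, cyc["bevacizumab"]),
            DrugCatalogEntry("temsirolimus", DrugClass.MTOR, Route.IV, cyc["temsirolimus"]),
            DrugCatalogEntry("aldesleukin", DrugClass.IL2, Route.IV, cyc["aldesleukin"]),
            DrugCatalogEntry(
                IFN_ALFA, DrugClass.TK_VEGF, Route.IV, cyc["ifn_alfa"],
                combination_partner_only=True,
            ),
        ]
    )


@dataclass(frozen=True)
class AEDefinition:
    """A named adverse event, its diagnosis code set, and chronicity.

    ``chronic`` selects the 365-day pre-index washout (vs 30 days for
    acute events) when deciding whether a post-index claim is incident.
    """

    ae_name: str
    code_set: CodeSet
    chronic: bool = False

    @property
    def washout_days(self) -> int:
        return 365 if self.chronic else 30


# ---------------------------------------------------------------------------
# Claims bundle I/O
# ---------------------------------------------------------------------------

ENROLLMENT_COLUMNS = [
    "patient_id", "start_date", "end_date", "birth_year", "sex",
    "region", "employment", "plan_type", "insurance_type",
]
PHARMACY_COLUMNS = ["patient_id", "fill_date", "agent", "days_supply"]
ADMIN_COLUMNS = ["patient_id", "service_date", "agent"]
MEDICAL_REQUIRED = ["patient_id", "service_date"]

TABLE_FILES = {
    "enrollment": "enrollment.csv",
    "medical": "medical.csv",
    "pharmacy": "pharmacy.csv",
    "administration": "administration.csv",
}


@dataclass
class RowIssue:
    table: str
    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}:{self.line}: {self.message}"


@dataclass
class ClaimsBundle:
    """Normalized in-memory claims bundle.

    enrollment: one row per (merged) continuous-coverage span with
        demographics; medical: long format, one row per code with the
        originating claim id; drug: unified pharmacy + administration
        exposures (``days_supply`` is NaN for IV administrations).
    """

    enrollment: pd.DataFrame
    medical: pd.DataFrame
    drug: pd.DataFrame
    issues: list[RowIssue] = field(default_factory=list)

    def patients(self) -> pd.Index:
        return pd.Index(
            sorted(
                set(self.enrollment["patient_id"])
                | set(self.medical["patient_id"])
                | set(self.drug["patient_id"])
            ),
            name="patient_id",
        )


def normalize_enrollment_spans(enrollment: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or adjacent spans per patient.

    Two spans merge when the later one starts no more than one day after
    the earlier ends, i.e. coverage is gapless in whole days.
    Demographics are taken from the first span of each merged run.
    """
    if enrollment.empty:
        return enrollment.copy()
    df = enrollment.sort_values(["patient_id", "start_date"]).reset_index(drop=True)
    multi = df["patient_id"].duplicated(keep=False)
    singles = df[~multi]
    out_rows = []
    for _, grp in df[multi].groupby("patient_id", sort=False):
        cur = grp.iloc[0].copy()
        for _, row in grp.iloc[1:].iterrows():
            if row["start_date"] <= cur["end_date"] + pd.Timedelta(days=1):
                cur["end_date"] = max(cur["end_date"], row["end_date"])
            else:
                out_rows.append(cur)
                cur = row.copy()
        out_rows.append(cur)
    merged = pd.DataFrame(out_rows, columns=df.columns) if out_rows else df.iloc[0:0]
    out = (
        pd.concat([singles, merged], ignore_index=True)
        .sort_values(["patient_id", "start_date"])
        .reset_index(drop=True)
    )
    bad = out["start_date"] > out["end_date"]
    if bad.any():
        raise SchemaError("enrollment span with start_date > end_date")
    return out


def _parse_dates(
    df: pd.DataFrame, col: str, table: str, strict: bool, issues: list[RowIssue]
) -> pd.DataFrame:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[col].notna() | df[col].isna()
    if bad.any():
        for idx in df.index[bad]:
            msg = f"unparseable {col} {df.loc[idx, col]!r}"
            if strict:
                raise SchemaError(f"{table}:{idx + 2}: {msg}")
            issues.append(RowIssue(table, int(idx) + 2, msg))
        df = df[~bad].copy()
        parsed = parsed[~bad]
    df[col] = parsed
    return df


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def read_claims_bundle(
    path: str | Path,
    catalog: DrugCatalog | None = None,
    *,
    delimiter: str = ",",
    strict: bool = True,
    extra_agents: Iterable[str] | None = None,
) -> ClaimsBundle:
    """Read the four claims tables from ``path`` into a normalized bundle.

    In strict mode any malformed row raises :class:`SchemaError` with its
    line number; otherwise bad rows are dropped and reported in
    ``bundle.issues``.  Unknown agents are always an error because a silent
    drop would bias every downstream exposure rule; ``extra_agents`` lists
    permitted non-study agents (e.g. the TCC-indicated drugs used by the
    exclusion criterion).
    """
    catalog = catalog or default_catalog()
    allowed_extra = set(extra_agents or ())
    path = Path(path)
    issues: list[RowIssue] = []

    def _read(name: str) -> pd.DataFrame:
        f = path / TABLE_FILES[name]
        if not f.exists():
            raise SchemaError(f"missing claims table {f}")
        return pd.read_csv(f, sep=delimiter, dtype=str, keep_default_na=True)

    enr = _read("enrollment")
    _require_columns(enr, ["patient_id", "start_date", "end_date"], "enrollment")
    enr = _parse_dates(enr, "start_date", "enrollment", strict, issues)
    enr = _parse_dates(enr, "end_date", "enrollment", strict, issues)
    for col in ENROLLMENT_COLUMNS:
        if col not in enr.columns:
            enr[col] = pd.NA
    enr["birth_year"] = pd.to_numeric(enr["birth_year"], errors="coerce").astype("Int64")
    enr = normalize_enrollment_spans(enr[ENROLLMENT_COLUMNS])

    med = _read("medical")
    _require_columns(med, MEDICAL_REQUIRED, "medical")
    med = _parse_dates(med, "service_date", "medical", strict, issues)
    dx_cols = sorted(c for c in med.columns if c.startswith("dx"))
    proc_cols = sorted(c for c in med.columns if c.startswith("proc"))
    if not dx_cols and not proc_cols:
        raise SchemaError("medical: needs at least one dx* or proc* column")
    med = med.reset_index(drop=True)
    med["claim_id"] = med.index
    long_parts = []
    for kind, cols in (("dx", dx_cols), ("proc", proc_cols)):
        for c in cols:
            part = med[["patient_id", "service_date", "claim_id", c]].dropna(subset=[c])
            if part.empty:
                continue
            part = part.rename(columns={c: "code"})
            part["code"] = part["code"].map(normalize_code)
            part["kind"] = kind
            long_parts.append(part)
    if long_parts:
        medical = pd.concat(long_parts, ignore_index=True)
    else:
        medical = pd.DataFrame(
            columns=["patient_id", "service_date", "claim_id", "code", "kind"]
        )
    medical = medical.rename(columns={"service_date": "date"})
    medical = medical.sort_values(["patient_id", "date", "claim_id"]).reset_index(drop=True)

    rx = _read("pharmacy")
    _require_columns(rx, PHARMACY_COLUMNS, "pharmacy")
    rx = _parse_dates(rx, "fill_date", "pharmacy", strict, issues)
    rx["days_supply"] = pd.to_numeric(rx["days_supply"], errors="coerce")
    bad_ds = rx["days_supply"].isna() | (rx["days_supply"] <= 0)
    if bad_ds.any():
        for idx in rx.index[bad_ds]:
            msg = f"invalid days_supply {rx.loc[idx, 'days_supply']!r}"
            if strict:
                raise SchemaError(f"pharmacy:{idx + 2}: {msg}")
            issues.append(RowIssue("pharmacy", int(idx) + 2, msg))
        rx = rx[~bad_ds]
    rx = rx.rename(columns={"fill_date": "date"})
    rx["source"] = "pharmacy"

    adm = _read("administration")
    _require_columns(adm, ADMIN_COLUMNS, "administration")
    adm = _parse_dates(adm, "service_date", "administration", strict, issues)
    adm = adm.rename(columns={"service_date": "date"})
    adm["days_supply"] = np.nan
    adm["source"] = "administration"

    drug = pd.concat(
        [rx[["patient_id", "date", "agent", "days_supply", "source"]],
         adm[["patient_id", "date", "agent", "days_supply", "source"]]],
        ignore_index=True,
    )
    unknown = sorted(set(drug["agent"].dropna()) - set(catalog.agents) - allowed_extra)
    if unknown:
        raise CatalogError(f"unknown agent(s) in drug claims: {unknown}")
    drug = drug.sort_values(["patient_id", "date"]).reset_index(drop=True)

    return ClaimsBundle(enrollment=enr, medical=medical, drug=drug, issues=issues)


def write_claims_bundle(
    bundle: ClaimsBundle, path: str | Path, *, delimiter: str = ","
) -> None:
    """Serialize a bundle back to the four delimited tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    enr = bundle.enrollment.copy()
    for c in ("start_date", "end_date"):
        enr[c] = enr[c].dt.strftime("%Y-%m-%d")
    enr.to_csv(path / TABLE_FILES["enrollment"], sep=delimiter, index=False)

    med = bundle.medical.copy()
    if med.empty:
        wide = pd.DataFrame(columns=["patient_id", "service_date", "dx1"])
    else:
        med["rank"] = med.groupby(["claim_id", "kind"]).cumcount() + 1
        med["col"] = med["kind"].map({"dx": "dx", "proc": "proc"}) + med["rank"].astype(str)
        wide = med.pivot_table(
            index=["claim_id", "patient_id", "date"],
            columns="col", values="code", aggfunc="first",
        ).reset_index()
        wide = wide.rename(columns={"date": "service_date"})
        wide["service_date"] = wide["service_date"].dt.strftime("%Y-%m-%d")
        wide = wide.drop(columns=["claim_id"])
        front = ["patient_id", "service_date"]
        code_cols = sorted(c for c in wide.columns if c not in front)
        wide = wide[front + code_cols]
    wide.to_csv(path / TABLE_FILES["medical"], sep=delimiter, index=False)

    drug = bundle.drug.copy()
    drug["date"] = drug["date"].dt.strftime("%Y-%m-%d")
    rx = drug[drug["source"] == "pharmacy"].copy()
    rx = rx.rename(columns={"date": "fill_date"})
    rx["days_supply"] = rx["days_supply"].astype(int)
    rx[PHARMACY_COLUMNS].to_csv(path / TABLE_FILES["pharmacy"], sep=delimiter, index=False)
    adm = drug[drug["source"] == "administration"].rename(columns={"date": "service_date"})
    adm[ADMIN_COLUMNS].to_csv(path / TABLE_FILES["administration"], sep=delimiter, index=False)
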