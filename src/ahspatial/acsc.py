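"""Ambulatory-care-sensitive condition (ACSC) classification.

An ACSC is a diagnosis for which hospitalisation is considered avoidable
through timely and effective outpatient (primary) care.  This module ships
the catalogue of acute and chronic ACSCs with their ICD-10 code patterns,
classifies individual discharge diagnoses against it, and aggregates
discharge records to district-year counts and shares of avoidable
hospitalisations (AH) on all general hospitalisations.

Code-pattern semantics
----------------------
Patterns come in three flavours:

* a 3-character category like ``"J45"`` matches the category itself and
  every subcode (``J45.0``, ``J45.9``, ...);
* a dotted subcode like ``"I24.0"`` matches exactly that subcode and any
  deeper extension of it;
* a range like ``"E10.0-10.8"`` expands over the single-decimal subcodes
  ``.0`` ... ``.8`` inclusive (so ``E10.9`` does *not* match).

Codes are normalised to upper case with a dot inserted after the
3-character category when missing (``"J450"`` -> ``"J45.0"``).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "AcscEntry",
    "DischargeRecord",
    "load_acsc_table",
    "classify_code",
    "normalize_code",
    "aggregate",
    "read_discharges",
    "write_acsc_table",
]

logger = logging.getLogger(__name__)

Classification = Literal["acute", "chronic"]

#: Built-in ACSC catalogue: condition, acute/chronic, ICD-10 patterns.
_BUILTIN_ROWS: tuple[tuple[str, str, str], ...] = (
    ("Angina", "acute", "I20; I24.0; I24.8; I24.9"),
    ("Asthma", "chronic", "J45; J46"),
    ("Cardiovascular diseases", "chronic", "I13.0; I25; I48"),
    (
        "Cellulitis",
        "acute",
        "I89.1; L01; L02; L03; L04; L08.0; L08.8; L08.9; L88; L98.0; L98.3",
    ),
    ("Congestive heart failure", "chronic", "I11.0; I50; J81"),
    ("Convulsions and epilepsy", "chronic", "G40; G41; R56"),
    ("COPD", "chronic", "J20; J41; J42; J43; J44; J47"),
    ("Dehydration and gastroenteritis", "acute", "E86; K52.2; K52.8; K52.9"),
    (
        "Diabetes",
        "chronic",
        "E10.0-10.8; E11.0-11.8; E12; E13.0-13.8; E14.0-14.8; E16.2",
    ),
    ("Diseases of the blood", "chronic", "D51; D52"),
    ("Ear, nose, throat infections", "acute", "H66; H67; J02; J03; J04; J06; J31.2"),
    ("Gangrene", "acute", "R02"),
    ("Hypertension", "chronic", "I10; I11.9"),
    (
        "Influenza and pneumonia",
        "acute",
        "J10; J11; J13; J14; J15.3; J15.4; J15.7; J15.9; J16.8; J18.1; J18.8",
    ),
    ("Iron deficiency anaemia", "chronic", "D50.1; D50.8; D50.9"),
    ("Nutritional deficiencies", "chronic", "E40; E41; E42; E43; E55.0; E64.3"),
    ("Pelvic inflammatory disease", "acute", "N70; N73; N74"),
    (
        "Perforated/bleeding ulcer",
        "acute",
        "K20; K21; K25.0-25.2; K25.4-25.6; K26.0-26.2; K26.4-26.6; "
        "K27.0-27.2; K27.4-27.6; K28.0-28.2; K28.4-28.6",
    ),
    (
        "Urinary tract infection",
        "acute",
        "N10; N11; N12; N13.6; N15.9; N30.0; N30.8; N30.9; N39.0",
    ),
)

_CODE_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")
_RANGE_RE = re.compile(r"^([A-Z]\d{2})\.(\d+)[-–](?:[A-Z]?\d{2})?\.(\d+)$")


class AcscParseError(ValueError):
    """A malformed ICD-10 pattern or catalogue file."""


@dataclass(frozen=True)
class AcscEntry:
    """One condition of the ACSC catalogue.

    Attributes
    ----------
    condition : str
        Human-readable condition name, e.g. ``"Asthma"``.
    classification : {"acute", "chronic"}
    code_patterns : tuple of str
        Raw ICD-10 patterns as listed in the catalogue.
    resolved_prefixes : tuple of str
        Patterns with ranges expanded; each element is matched as a prefix.
    """

    condition: str
    classification: Classification
    code_patterns: tuple[str, ...]
    resolved_prefixes: tuple[str, ...] = field(default=(), compare=False)


@dataclass(frozen=True)
class DischargeRecord:
    """One district-year-diagnosis count line from a discharge file."""

    district_id: str
    year: int
    icd10: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative discharge count for {self.district_id}")


def normalize_code(code: str) -> str:
    """Normalise an ICD-10 code: upper-case, no whitespace, dotted form.

    Returns the normalised code, or raises :class:`AcscParseError` if the
    result is not a plausible ICD-10 code.
    """
    c = str(code).strip().upper().replace(" ", "")
    if len(c) > 3 and "." not in c:
        c = c[:3] + "." + c[3:]
    if not _CODE_RE.match(c):
        raise AcscParseError(f"not a valid ICD-10 code: {code!r}")
    return c


def expand_pattern(pattern: str) -> list[str]:
    """Expand one catalogue pattern into its list of matchable prefixes.

    ``"J45"`` -> ``["J45"]``; ``"I24.0"`` -> ``["I24.0"]``;
    ``"E10.0-10.8"`` -> ``["E10.0", ..., "E10.8"]``.
    """
    p = pattern.strip().upper().replace(" ", "")
    m = _RANGE_RE.match(p)
    if m:
        base, lo, hi = m.group(1), m.group(2), m.group(3)
        if len(lo) != 1 or len(hi) != 1:
            raise AcscParseError(f"only single-decimal ranges supported: {pattern!r}")
        lo_i, hi_i = int(lo), int(hi)
        if lo_i > hi_i:
            raise AcscParseError(f"descending range: {pattern!r}")
        return [f"{base}.{d}" for d in range(lo_i, hi_i + 1)]
    if _CODE_RE.match(p):
        return [p]
    raise AcscParseError(f"malformed ICD-10 pattern: {pattern!r}")


def _prefixes_overlap(a: str, b: str) -> bool:
    # two prefixes collide iff one extends the other at a subcode boundary
    if a == b:
        return True
    lo, hi = (a, b) if len(a) < len(b) else (b, a)
    if not hi.startswith(lo):
        return False
    return len(lo) == 3 and hi[3] == "." or len(lo) > 3


def load_acsc_table(source: str | Path | None = None) -> list[AcscEntry]:
    """Load the ACSC catalogue.

    Parameters
    ----------
    source : path or None
        CSV with columns ``condition, classification, patterns`` (patterns
        separated by ``;``).  ``None`` loads the built-in catalogue.

    Returns
    -------
    list of AcscEntry
        With ranges pre-expanded.  Raises :class:`AcscParseError` on any
        malformed pattern, an empty file, or acute/chronic overlap.
    """
    if source is None:
        rows = [(c, k, p) for c, k, p in _BUILTIN_ROWS]
    else:
        df = pd.read_csv(source, dtype=str)
        required = {"condition", "classification", "patterns"}
        if df.empty or not required.issubset(df.columns):
            raise AcscParseError(
                f"ACSC table {source} must be non-empty with columns {sorted(required)}"
            )
        rows = [
            (r["condition"], r["classification"].strip().lower(), r["patterns"])
            for _, r in df.iterrows()
        ]

    entries: list[AcscEntry] = []
    for condition, classification, patterns in rows:
        if classification not in ("acute", "chronic"):
            raise AcscParseError(
                f"classification for {condition!r} must be acute/chronic, "
                f"got {classification!r}"
            )
        pats = tuple(p.strip() for p in str(patterns).split(";") if p.strip())
        if not pats:
            raise AcscParseError(f"no patterns for condition {condition!r}")
        resolved: list[str] = []
        for p in pats:
            resolved.extend(expand_pattern(p))
        entries.append(
            AcscEntry(condition, classification, pats, tuple(resolved))  # type: ignore[arg-type]
        )

    _check_disjoint(entries)
    return entries


def _check_disjoint(entries: Sequence[AcscEntry]) -> None:
    """Acute and chronic prefix sets must not overlap at the resolved level."""
    acute = [(p, e.condition) for e in entries if e.classification == "acute" for p in e.resolved_prefixes]
    chronic = [(p, e.condition) for e in entries if e.classification == "chronic" for p in e.resolved_prefixes]
    for pa, ca in acute:
        for pc, cc in chronic:
            if _prefixes_overlap(pa, pc):
                raise AcscParseError(
                    f"acute/chronic overlap: {pa!r} ({ca}) vs {pc!r} ({cc})"
                )


def classify_code(
    icd10: str, table: Sequence[AcscEntry]
) -> tuple[Literal["acute", "chronic", "none"], str | None]:
    """Classify one ICD-10 code against the ACSC catalogue.

    Returns ``(classification, condition)`` where classification is
    ``"acute"``, ``"chronic"`` or ``"none"``.  An unparseable code logs a
    warning and returns ``("none", None)`` rather than raising.
    """
    try:
        code = normalize_code(icd10)
    except AcscParseError:
        logger.warning("unparseable ICD-10 code %r classified as none", icd10)
        return "none", None
    for entry in table:
        for prefix in entry.resolved_prefixes:
            if code == prefix:
                return entry.classification, entry.condition
            if code.startswith(prefix):
                # category prefix only matches at the subcode boundary
                if len(prefix) == 3 and code[3] != ".":
                    continue
                return entry.classification, entry.condition
    return "none", None


def read_discharges(path: str | Path) -> list[DischargeRecord]:
    """Read a discharge CSV (district_id, year, icd10, count)."""
    df = pd.read_csv(path, dtype={"district_id": str, "icd10": str})
    return [
        DischargeRecord(r.district_id, int(r.year), str(r.icd10), int(r.count))
        for r in df.itertuples()
    ]


def aggregate(
    records: Iterable[DischargeRecord],
    general_counts: pd.DataFrame,
    table: Sequence[AcscEntry] | None = None,
) -> pd.DataFrame:
    """Aggregate discharge records to district-year AH counts and shares.

    Parameters
    ----------
    records : iterable of DischargeRecord
    general_counts : DataFrame
        Columns ``district_id, year, general_hosp`` giving the denominator
        (all general hospitalisations) for every district-year cell.
    table : ACSC catalogue, built-in when None.

    Returns
    -------
    DataFrame
        Balanced over the district x year grid of ``general_counts``, with
        columns ``district_id, year, ah_total, ah_acute, ah_chronic,
        general_hosp, share_total, share_acute, share_chronic``.  Cells with
        no ACSC records are zero-filled.  The share is the avoidable
        fraction of all general hospitalisations.
    """
    if table is None:
        table = load_acsc_table()

    gc = general_counts.copy()
    gc["district_id"] = gc["district_id"].astype(str)
    gc["year"] = gc["year"].astype(int)
    if (gc["general_hosp"] <= 0).any():
        raise ValueError("general_hosp must be positive for every district-year")
    if gc.duplicated(["district_id", "year"]).any():
        raise ValueError("duplicate district-year rows in general_counts")
    gc = gc.sort_values(["district_id", "year"]).reset_index(drop=True)

    counts: dict[tuple[str, int], dict[str, int]] = {
        (r.district_id, r.year): {"acute": 0, "chronic": 0} for r in gc.itertuples()
    }
    cache: dict[str, str] = {}
    for rec in records:
        key = (str(rec.district_id), int(rec.year))
        if key not in counts:
            raise KeyError(
                f"district-year {key} in discharge records has no general count"
            )
        cls = cache.get(rec.icd10)
        if cls is None:
            cls = classify_code(rec.icd10, table)[0]
            cache[rec.icd10] = cls
        if cls != "none":
            counts[key][cls] += rec.count

    out = gc.copy()
    out["ah_acute"] = [counts[(r.district_id, r.year)]["acute"] for r in gc.itertuples()]
    out["ah_chronic"] = [counts[(r.district_id, r.year)]["chronic"] for r in gc.itertuples()]
    out["ah_total"] = out["ah_acute"] + out["ah_chronic"]
    bad = out["ah_total"] > out["general_hosp"]
    if bad.any():
        rows = out.loc[bad, ["district_id", "year"]].to_records(index=False).tolist()
        raise ValueError(f"ACSC count exceeds general hospitalisations at {rows}")
    for part in ("total", "acute", "chronic"):
        out[f"share_{part}"] = out[f"ah_{part}"] / out["general_hosp"]
    cols = [
        "district_id", "year", "ah_total", "ah_acute", "ah_chronic",
        "general_hosp", "share_total", "share_acute", "share_chronic",
    ]
    return out[cols]


def write_acsc_table(entries: Sequence[AcscEntry], path: str | Path) -> None:
    """Write a catalogue to the CSV interchange format."""
    df = pd.DataFrame(
        {
            "condition": [e.condition for e in entries],
            "classification": [e.classification for e in entries],
            "patterns": ["; ".join(e.code_patterns) for e in entries],
        }
    )
    df.to_csv(path, index=False)
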