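"""Dated knowledge-base snapshots and day-over-day deltas.

A snapshot is the state, on one calendar day, of the three knowledge
channels that drive reinterpretation of stored exome data:

* gene-disease entries (with inheritance mode, OMIM-registration status and
  an HPO profile for the disease),
* variant-level assertions (five-tier classifications from curated sources),
* population allele frequencies.

``diff_snapshots`` computes what changed between two days; the resulting
:class:`KBDelta` is what the daily reanalysis loop reacts to.  Frequency
changes are only considered material when they cross a criterion boundary
(PM2/BS1/BA1), so immaterial daily churn in the fourth decimal place does
not re-trigger review of every variant.
"""
from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .config import DateOrderingError, SchemaError, RunConfig

_OMIM_RE = re.compile(r"^\d{6}$")

#: Published symbol variants mapped to one canonical symbol for keying;
#: display strings keep whatever spelling the source printed.
GENE_ALIASES = {"HUEW1": "HUWE1"}


def normalize_gene(symbol: str) -> str:
    s = symbol.strip()
    return GENE_ALIASES.get(s, s)


class Inheritance(str, Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"
    AD_AR = "AD_AR"

    @classmethod
    def parse(cls, text: str) -> "Inheritance":
        t = text.strip().upper().replace("/", "_")
        if t in ("XD", "XR", "X_LINKED", "XLD", "XLR"):
            t = "XL"
        try:
            return cls(t)
        except ValueError:
            raise SchemaError(f"unknown inheritance mode: {text!r}") from None

    @property
    def dominant_like(self) -> bool:
        """One het/hemi allele can cause disease (AD, XL, or AD/AR)."""
        return self in (Inheritance.AD, Inheritance.XL, Inheritance.AD_AR)

    @property
    def recessive_like(self) -> bool:
        return self in (Inheritance.AR, Inheritance.AD_AR)


class Registration(str, Enum):
    OMIM_REGISTERED = "omim_registered"
    LITERATURE_CANDIDATE = "literature_candidate"


def is_omim_id(disease_id: str) -> bool:
    """True for a six-digit OMIM phenotype number."""
    return bool(_OMIM_RE.match(disease_id.strip()))


def _parse_date(value: str | dt.date, context: str = "") -> dt.date:
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        raise SchemaError(f"bad ISO date {value!r} {context}".strip()) from None


@dataclass(frozen=True)
class GeneDiseaseEntry:
    """One gene-disease relationship as curated on a given date."""

    gene_symbol: str
    disease_id: str
    disease_name: str
    inheritance: Inheritance
    registration: Registration
    hpo_profile: frozenset[str]
    entry_date: dt.date
    lof_mechanism: bool = True
    missense_constrained: bool = False

    def __post_init__(self) -> None:
        if not self.hpo_profile:
            raise SchemaError(
                f"entry ({self.gene_symbol}, {self.disease_id}): empty hpo_profile"
            )
        omim = is_omim_id(self.disease_id)
        registered = self.registration is Registration.OMIM_REGISTERED
        if omim != registered:
            raise SchemaError(
                f"entry ({self.gene_symbol}, {self.disease_id}): registration "
                f"{self.registration.value!r} inconsistent with disease id"
            )

    @property
    def digenic(self) -> bool:
        # Digenic conditions (flagged in the curated disease name) manifest
        # with a single het allele per locus, so triage treats them under the
        # dominant-style rule even when the formal mode is recessive.
        return "digenic" in self.disease_name.lower()

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_symbol, self.disease_id)


class AssertedClass(str, Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


@dataclass(frozen=True)
class VariantAssertion:
    """A curated five-tier classification for one variant key."""

    variant_key: str
    asserted_class: AssertedClass
    source: str = ""
    protein_residue: str | None = None
    assertion_date: dt.date = dt.date(1970, 1, 1)

    def __post_init__(self) -> None:
        if any(c.isspace() for c in self.variant_key):
            raise SchemaError(f"variant_key contains whitespace: {self.variant_key!r}")


@dataclass
class Snapshot:
    """Knowledge-base state on one calendar day."""

    snapshot_date: dt.date
    entries: dict[tuple[str, str], GeneDiseaseEntry] = field(default_factory=dict)
    assertions: dict[str, VariantAssertion] = field(default_factory=dict)
    frequencies: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "Snapshot":
        for key, af in self.frequencies.items():
            if not (0.0 <= af <= 1.0):
                raise SchemaError(f"frequency for {key}: {af} outside [0, 1]")
        for entry in self.entries.values():
            if entry.entry_date > self.snapshot_date:
                raise SchemaError(
                    f"entry ({entry.gene_symbol}, {entry.disease_id}) dated "
                    f"{entry.entry_date} after snapshot date {self.snapshot_date}"
                )
        return self

    def entries_for_gene(self, gene_symbol: str) -> list[GeneDiseaseEntry]:
        wanted = normalize_gene(gene_symbol)
        return [
            e for e in self.entries.values()
            if normalize_gene(e.gene_symbol) == wanted
        ]

    @classmethod
    def build(
        cls,
        snapshot_date: dt.date,
        entries: Iterable[GeneDiseaseEntry] = (),
        assertions: Iterable[VariantAssertion] = (),
        frequencies: Mapping[str, float] | None = None,
    ) -> "Snapshot":
        snap = cls(snapshot_date=snapshot_date)
        for e in entries:
            if e.key in snap.entries:
                raise SchemaError(f"duplicate entry for {e.key}")
            snap.entries[e.key] = e
        for a in assertions:
            snap.assertions[a.variant_key] = a
        snap.frequencies.update(frequencies or {})
        return snap.validate()


@dataclass
class KBDelta:
    """What changed between two snapshots.

    ``changed_frequencies`` maps variant_key to (old, new); ``old`` is None
    for a frequency seen for the first time.
    """

    old_date: dt.date
    new_date: dt.date
    added_entries: list[GeneDiseaseEntry] = field(default_factory=list)
    changed_or_added_assertions: list[VariantAssertion] = field(default_factory=list)
    changed_frequencies: dict[str, tuple[float | None, float]] = field(
        default_factory=dict
    )

    @property
    def affected_genes(self) -> set[str]:
        genes = {e.gene_symbol for e in self.added_entries}
        genes.update(a.variant_key.split("|", 1)[0] for a in self.changed_or_added_assertions)
        genes.update(k.split("|", 1)[0] for k in self.changed_frequencies)
        return genes

    @property
    def empty(self) -> bool:
        return not (
            self.added_entries
            or self.changed_or_added_assertions
            or self.changed_frequencies
        )


def _crosses_boundary(
    old: float | None, new: float, boundaries: Iterable[float]
) -> bool:
    if old is None:
        return True
    if old == new:
        return False
    return any((old <= b) != (new <= b) for b in boundaries)


def diff_snapshots(
    old: Snapshot,
    new: Snapshot,
    config: RunConfig | None = None,
    material_only: bool = True,
) -> KBDelta:
    """Everything present or changed in ``new`` relative to ``old``.

    Entry identity is keyed on (gene, disease_id), assertions on variant_key;
    any field change counts as changed.  With ``material_only`` (the default)
    a frequency change is only reported when it crosses one of the criterion
    boundaries from ``config``.
    """
    if old.snapshot_date > new.snapshot_date:
        raise DateOrderingError(
            f"old snapshot {old.snapshot_date} dated after new {new.snapshot_date}"
        )
    boundaries = (config or RunConfig()).frequency_boundaries
    delta = KBDelta(old_date=old.snapshot_date, new_date=new.snapshot_date)
    for key, entry in new.entries.items():
        prev = old.entries.get(key)
        if prev is None or (prev is not entry and prev != entry):
            delta.added_entries.append(entry)
    for key, assertion in new.assertions.items():
        prev = old.assertions.get(key)
        if prev is None or (prev is not assertion and prev != assertion):
            delta.changed_or_added_assertions.append(assertion)
    for key, af in new.frequencies.items():
        prev = old.frequencies.get(key)
        if prev == af:
            continue
        if not material_only or _crosses_boundary(prev, af, boundaries):
            delta.changed_frequencies[key] = (prev, af)
    return delta


# ---------------------------------------------------------------------------
# Loading: JSON document or sectioned TSV
# ---------------------------------------------------------------------------


def _entry_from_record(rec: Mapping[str, object], where: str) -> GeneDiseaseEntry:
    try:
        profile = rec["hpo_profile"]
        if isinstance(profile, str):
            terms = frozenset(t for t in profile.split(";") if t)
        else:
            terms = frozenset(profile)  # type: ignore[arg-type]
        return GeneDiseaseEntry(
            gene_symbol=str(rec["gene_symbol"]).strip(),
            disease_id=str(rec["disease_id"]).strip(),
            disease_name=str(rec.get("disease_name", "")).strip(),
            inheritance=Inheritance.parse(str(rec["inheritance"])),
            registration=Registration(str(rec["registration"]).strip()),
            hpo_profile=terms,
            entry_date=_parse_date(rec["entry_date"], where),  # type: ignore[arg-type]
            lof_mechanism=_parse_flag(rec.get("lof_mechanism", True)),
            missense_constrained=_parse_flag(rec.get("missense_constrained", False)),
        )
    except KeyError as exc:
        raise SchemaError(f"{where}: missing field {exc.args[0]!r}") from None
    except ValueError as exc:
        raise SchemaError(f"{where}: {exc}") from None


def _assertion_from_record(rec: Mapping[str, object], where: str) -> VariantAssertion:
    try:
        return VariantAssertion(
            variant_key="".join(str(rec["variant_key"]).split()),
            asserted_class=AssertedClass(str(rec["asserted_class"]).strip()),
            source=str(rec.get("source", "")).strip(),
            protein_residue=(str(rec["protein_residue"]).strip() or None)
            if rec.get("protein_residue")
            else None,
            assertion_date=_parse_date(rec.get("assertion_date", "1970-01-01"), where),  # type: ignore[arg-type]
        )
    except KeyError as exc:
        raise SchemaError(f"{where}: missing field {exc.args[0]!r}") from None
    except ValueError as exc:
        raise SchemaError(f"{where}: {exc}") from None


def _parse_flag(value: object) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "yes")


def _frequency_from_record(rec: Mapping[str, object], where: str) -> tuple[str, float]:
    try:
        key = "".join(str(rec["variant_key"]).split())
        af = float(rec["af"])  # type: ignore[arg-type]
    except (KeyError, ValueError, TypeError):
        raise SchemaError(f"{where}: bad frequency record {dict(rec)!r}") from None
    if not (0.0 <= af <= 1.0):
        raise SchemaError(f"{where}: frequency {af} outside [0, 1]")
    return key, af


def load_snapshot(path: str | Path, expected_date: dt.date | None = None) -> Snapshot:
    """Load a snapshot from a JSON document or the sectioned TSV dialect.

    Raises :class:`SchemaError` naming the offending line/field for malformed
    records, and :class:`DateOrderingError` when ``expected_date`` is given
    and does not match the file.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        snap = _load_snapshot_json(text, str(path))
    else:
        snap = _load_snapshot_tsv(text, str(path))
    if expected_date is not None and snap.snapshot_date != expected_date:
        raise DateOrderingError(
            f"{path}: snapshot dated {snap.snapshot_date}, expected {expected_date}"
        )
    return snap


def _load_snapshot_json(text: str, where: str) -> Snapshot:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{where}: invalid JSON ({exc})") from None
    if "date" not in doc:
        raise SchemaError(f"{where}: missing 'date'")
    snap = Snapshot(snapshot_date=_parse_date(doc["date"], where))
    for i, rec in enumerate(doc.get("entries", [])):
        entry = _entry_from_record(rec, f"{where}: entries[{i}]")
        if entry.key in snap.entries:
            raise SchemaError(f"{where}: entries[{i}]: duplicate entry {entry.key}")
        snap.entries[entry.key] = entry
    for i, rec in enumerate(doc.get("assertions", [])):
        a = _assertion_from_record(rec, f"{where}: assertions[{i}]")
        snap.assertions[a.variant_key] = a
    for key, af in (doc.get("frequencies") or {}).items():
        k, v = _frequency_from_record(
            {"variant_key": key, "af": af}, f"{where}: frequencies[{key}]"
        )
        snap.frequencies[k] = v
    return snap.validate()


def _load_snapshot_tsv(text: str, where: str) -> Snapshot:
    """Sectioned TSV: '##date<TAB>YYYY-MM-DD', then per-record-type sections
    introduced by a '#'-prefixed header line naming the columns; data rows
    start with the record type (entry / assertion / frequency)."""
    snap_date: dt.date | None = None
    header: list[str] | None = None
    snap = Snapshot(snapshot_date=dt.date(1970, 1, 1))
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        loc = f"{where}:{lineno}"
        if line.startswith("##date"):
            snap_date = _parse_date(line.split("\t")[1], loc)
            continue
        if line.startswith("#"):
            header = line.lstrip("#").split("\t")
            continue
        if header is None:
            raise SchemaError(f"{loc}: data row before any section header")
        fields = line.split("\t")
        rec = dict(zip(header, fields))
        kind = fields[0]
        if kind != header[0]:
            raise SchemaError(
                f"{loc}: record type {kind!r} does not match section {header[0]!r}"
            )
        if kind == "entry":
            entry = _entry_from_record(rec, loc)
            if entry.key in snap.entries:
                raise SchemaError(f"{loc}: duplicate entry {entry.key}")
            snap.entries[entry.key] = entry
        elif kind == "assertion":
            a = _assertion_from_record(rec, loc)
            snap.assertions[a.variant_key] = a
        elif kind == "frequency":
            k, v = _frequency_from_record(rec, loc)
            snap.frequencies[k] = v
        else:
            raise SchemaError(f"{loc}: unknown record type {kind!r}")
    if snap_date is None:
        raise SchemaError(f"{where}: missing '##date' line")
    snap.snapshot_date = snap_date
    return snap.validate()


def write_snapshot_json(snap: Snapshot, path: str | Path) -> None:
    doc = {
        "date": snap.snapshot_date.isoformat(),
        "entries": [
            {
                "gene_symbol": e.gene_symbol,
                "disease_id": e.disease_id,
                "disease_name": e.disease_name,
                "inheritance": e.inheritance.value,
                "registration": e.registration.value,
                "hpo_profile": sorted(e.hpo_profile),
                "entry_date": e.entry_date.isoformat(),
                "lof_mechanism": e.lof_mechanism,
                "missense_constrained": e.missense_constrained,
            }
            for e in snap.entries.values()
        ],
        "assertions": [
            {
                "variant_key": a.variant_key,
                "asserted_class": a.asserted_class.value,
                "source": a.source,
                "protein_residue": a.protein_residue,
                "assertion_date": a.assertion_date.isoformat(),
            }
            for a in snap.assertions.values()
        ],
        "frequencies": dict(sorted(snap.frequencies.items())),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
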