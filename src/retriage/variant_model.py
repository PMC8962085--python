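"""Patient variants, HGVS c. parsing, consequence categories, compound hets.

The parser covers the HGVS coding-DNA subset that clinical exome reports
actually print: substitutions, deletions, duplications, insertions and
deletion-insertions, with optional intronic offsets on either breakpoint
(``c.1608-2A>G``, ``c.4582-2_4582-1del``).  Whitespace inside descriptions
is tolerated because published tables routinely typeset ``c.316G > A``.
Repeats, mosaic alleles and genome-coordinate normalization are out of
scope; anything unparseable is retained with consequence ``other``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .config import HgvsParseError
from .knowledge_base import GENE_ALIASES, Inheritance, normalize_gene  # noqa: F401
# (gene aliasing lives with the knowledge base; re-exported here because the
# variant key is where it takes effect)


def variant_key(gene_symbol: str, transcript: str, hgvs_c: str) -> str:
    """``GENE|TRANSCRIPT|c.DESC`` with whitespace removed, case preserved."""
    return "|".join(
        (
            normalize_gene(gene_symbol),
            "".join(transcript.split()),
            "".join(hgvs_c.split()),
        )
    )


class Zygosity(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"

    @classmethod
    def parse(cls, text: str) -> "Zygosity":
        t = text.strip().lower()
        table = {
            "het": cls.HETEROZYGOUS,
            "heterozygous": cls.HETEROZYGOUS,
            "hom": cls.HOMOZYGOUS,
            "homozygous": cls.HOMOZYGOUS,
            "hemi": cls.HEMIZYGOUS,
            "hemizygous": cls.HEMIZYGOUS,
        }
        if t not in table:
            raise ValueError(f"unknown zygosity {text!r}")
        return table[t]


class AlleleOrigin(str, Enum):
    ASSUMED_DE_NOVO = "assumed_de_novo"
    TRANS_CONFIRMED = "trans_confirmed"
    INHERITED_AFFECTED_PARENT = "inherited_affected_parent"
    INHERITED_UNAFFECTED_PARENT = "inherited_unaffected_parent"
    MATERNAL_MOSAIC = "maternal_mosaic"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "AlleleOrigin":
        t = text.strip().lower().replace(" ", "_")
        table = {
            "assumed_de_novo": cls.ASSUMED_DE_NOVO,
            "de_novo": cls.ASSUMED_DE_NOVO,
            "trans_phase": cls.TRANS_CONFIRMED,
            "trans": cls.TRANS_CONFIRMED,
            "trans_confirmed": cls.TRANS_CONFIRMED,
            "inherited_affected_parent": cls.INHERITED_AFFECTED_PARENT,
            "inherited_unaffected_parent": cls.INHERITED_UNAFFECTED_PARENT,
            "maternal_mosaic": cls.MATERNAL_MOSAIC,
            "unknown": cls.UNKNOWN,
        }
        if t not in table:
            raise ValueError(f"unknown allele origin {text!r}")
        return table[t]


class EditKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"


class ConsequenceCategory(str, Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    SYNONYMOUS = "synonymous"
    SUBSTITUTION_UNRESOLVED = "substitution_unresolved"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    CANONICAL_SPLICE = "canonical_splice"
    SPLICE_REGION = "splice_region"
    OTHER = "other"


@dataclass(frozen=True)
class HgvsDescription:
    """Structured form of one HGVS c. description."""

    start: int
    end: int
    edit_kind: EditKind
    edit_length: int | None
    start_offset: int | None = None
    end_offset: int | None = None
    deleted_length: int | None = None
    inserted_length: int | None = None

    @property
    def intron_offsets(self) -> tuple[int, ...]:
        return tuple(o for o in (self.start_offset, self.end_offset) if o is not None)

    @property
    def net_length_change(self) -> int | None:
        """Signed change in coding length; None when undeterminable."""
        if self.edit_kind is EditKind.SUBSTITUTION:
            return 0
        if self.edit_kind is EditKind.DELETION:
            return None if self.edit_length is None else -self.edit_length
        if self.edit_kind in (EditKind.DUPLICATION, EditKind.INSERTION):
            return self.edit_length
        # delins: inserted minus deleted
        if self.inserted_length is None or self.deleted_length is None:
            return None
        return self.inserted_length - self.deleted_length

    def render(self) -> str:
        """Re-render a normalized (whitespace-free) description."""
        def pos(p: int, off: int | None) -> str:
            return f"{p}{off:+d}" if off else str(p)

        span = pos(self.start, self.start_offset)
        if (self.end, self.end_offset) != (self.start, self.start_offset):
            span += f"_{pos(self.end, self.end_offset)}"
        suffix = {
            EditKind.DELETION: "del",
            EditKind.DUPLICATION: "dup",
            EditKind.INSERTION: "ins",
            EditKind.DELINS: "delins",
            EditKind.SUBSTITUTION: "",
        }[self.edit_kind]
        return f"c.{span}{suffix}"


_POS = r"(?P<{0}>\d+)(?P<{0}_off>[+-]\d+)?"
_SPAN = _POS.format("start") + r"(?:_" + _POS.format("end") + r")?"
_SUB_RE = re.compile(r"^c\." + _SPAN + r"(?P<ref>[ACGTN])>(?P<alt>[ACGTN])$")
_DELINS_RE = re.compile(
    r"^c\." + _SPAN + r"del(?P<dseq>[ACGTN]*)ins(?P<iseq>[ACGTN]+)$"
)
_DEL_RE = re.compile(r"^c\." + _SPAN + r"del(?P<seq>[ACGTN]*)$")
_DUP_RE = re.compile(r"^c\." + _SPAN + r"dup(?P<seq>[ACGTN]*)$")
_INS_RE = re.compile(r"^c\." + _SPAN + r"ins(?P<seq>[ACGTN]*)$")


def _span_fields(m: re.Match) -> tuple[int, int, int | None, int | None]:
    start = int(m.group("start"))
    start_off = int(m.group("start_off")) if m.group("start_off") else None
    if m.group("end") is not None:
        end = int(m.group("end"))
        end_off = int(m.group("end_off")) if m.group("end_off") else None
    else:
        end, end_off = start, start_off
    if start_off == 0 or end_off == 0:
        raise HgvsParseError("intron offset 0 is invalid")
    return start, end, start_off, end_off


def _span_length(
    start: int, end: int, start_off: int | None, end_off: int | None
) -> int | None:
    """Number of nucleotides in the span, when computable without knowing
    intron lengths."""
    if start_off is None and end_off is None:
        return end - start + 1
    if start == end and start_off is not None and end_off is not None:
        return end_off - start_off + 1
    return None


def parse_hgvs_c(text: str) -> HgvsDescription:
    """Parse an HGVS c. description (whitespace tolerated).

    Raises :class:`HgvsParseError` for anything outside the supported
    grammar; callers that must never fail keep the variant with consequence
    ``other`` instead.
    """
    compact = "".join(text.split()).replace(" ", "")
    if not compact.startswith("c."):
        raise HgvsParseError(f"not a coding description: {text!r}")

    m = _SUB_RE.match(compact)
    if m:
        start, end, so, eo = _span_fields(m)
        return HgvsDescription(start, end, EditKind.SUBSTITUTION, 1, so, eo)
    m = _DELINS_RE.match(compact)
    if m:
        start, end, so, eo = _span_fields(m)
        dseq, iseq = m.group("dseq"), m.group("iseq")
        deleted = len(dseq) if dseq else _span_length(start, end, so, eo)
        net = None if deleted is None else len(iseq) - deleted
        return HgvsDescription(
            start, end, EditKind.DELINS,
            abs(net) if net is not None else None,
            so, eo, deleted_length=deleted, inserted_length=len(iseq),
        )
    for regex, kind in ((_DEL_RE, EditKind.DELETION), (_DUP_RE, EditKind.DUPLICATION)):
        m = regex.match(compact)
        if m:
            start, end, so, eo = _span_fields(m)
            seq = m.group("seq")
            length = len(seq) if seq else _span_length(start, end, so, eo)
            if length is not None and length < 1:
                raise HgvsParseError(f"empty span in {text!r}")
            return HgvsDescription(start, end, kind, length, so, eo)
    m = _INS_RE.match(compact)
    if m:
        start, end, so, eo = _span_fields(m)
        seq = m.group("seq")
        return HgvsDescription(
            start, end, EditKind.INSERTION, len(seq) if seq else None, so, eo
        )
    raise HgvsParseError(f"unsupported HGVS description: {text!r}")


def classify_consequence(
    h: HgvsDescription | None, hgvs_p: str | None = None
) -> ConsequenceCategory:
    """Structural consequence of a parsed description.

    Canonical splice takes precedence (any breakpoint at intron offset
    +/-1 or +/-2); other intronic breakpoints are splice_region.  Exonic
    length-changing edits are frameshift or inframe by net length mod 3.
    Substitutions resolve to missense / stop-gain / synonymous only when a
    protein-level annotation is supplied.  Total: degenerate input -> other.
    """
    if h is None:
        return ConsequenceCategory.OTHER
    offsets = h.intron_offsets
    if any(abs(o) <= 2 for o in offsets):
        return ConsequenceCategory.CANONICAL_SPLICE
    if offsets:
        return ConsequenceCategory.SPLICE_REGION
    if h.edit_kind is EditKind.SUBSTITUTION:
        return _substitution_consequence(hgvs_p)
    net = h.net_length_change
    if net is None:
        return ConsequenceCategory.OTHER
    if net % 3 != 0:
        return ConsequenceCategory.FRAMESHIFT
    return ConsequenceCategory.INFRAME_INDEL


def _substitution_consequence(hgvs_p: str | None) -> ConsequenceCategory:
    if not hgvs_p:
        return ConsequenceCategory.SUBSTITUTION_UNRESOLVED
    p = "".join(hgvs_p.split())
    if p.endswith("=") or p.endswith("%3D"):
        return ConsequenceCategory.SYNONYMOUS
    if p.endswith("Ter") or p.endswith("*") or p.endswith("X"):
        return ConsequenceCategory.STOP_GAIN
    return ConsequenceCategory.MISSENSE


@dataclass
class Variant:
    """One observed allele in one patient."""

    patient_id: str
    gene_symbol: str
    transcript: str
    hgvs_c: str
    zygosity: Zygosity
    allele_origin: AlleleOrigin = AlleleOrigin.UNKNOWN
    hgvs_p: str | None = None
    parsed: HgvsDescription | None = field(default=None, repr=False)
    parse_failed: bool = False

    def __post_init__(self) -> None:
        if self.parsed is None and not self.parse_failed:
            try:
                self.parsed = parse_hgvs_c(self.hgvs_c)
            except HgvsParseError:
                self.parse_failed = True

    @property
    def key(self) -> str:
        return variant_key(self.gene_symbol, self.transcript, self.hgvs_c)

    @property
    def consequence(self) -> ConsequenceCategory:
        return classify_consequence(self.parsed, self.hgvs_p)

    @property
    def protein_residue(self) -> str | None:
        """Residue part of the protein annotation (e.g. Arg123 of p.Arg123Cys)."""
        if not self.hgvs_p:
            return None
        m = re.search(r"([A-Z][a-z]{2}\d+)", self.hgvs_p)
        return m.group(1) if m else None


@dataclass(frozen=True)
class CompHetPair:
    """An unordered pair of candidate trans alleles in one recessive gene.

    A homozygous variant pairs with itself (``is_homozygous``); phase is
    known either for self-pairs or when an allele is trans-confirmed by
    segregation.
    """

    first: Variant
    second: Variant
    phase_known: bool

    @property
    def is_homozygous(self) -> bool:
        return self.first is self.second

    @property
    def variants(self) -> tuple[Variant, ...]:
        if self.is_homozygous:
            return (self.first,)
        return (self.first, self.second)


def potential_comp_het(
    variants: Sequence[Variant], inheritance: Inheritance
) -> list[CompHetPair]:
    """Enumerate potential compound-heterozygote pairs in one gene.

    Only meaningful for recessive-capable genes; all variants must belong to
    one patient and one gene.  Heterozygous variants form all unordered
    pairs; homozygous variants are returned as self-pairs.
    """
    if not variants:
        return []
    patients = {v.patient_id for v in variants}
    genes = {normalize_gene(v.gene_symbol) for v in variants}
    if len(patients) > 1 or len(genes) > 1:
        raise ValueError("comp-het enumeration requires one patient and one gene")
    if not inheritance.recessive_like:
        return []
    pairs: list[CompHetPair] = []
    hets = [v for v in variants if v.zygosity is Zygosity.HETEROZYGOUS]
    for v in variants:
        if v.zygosity is Zygosity.HOMOZYGOUS:
            pairs.append(CompHetPair(v, v, phase_known=True))
    for i in range(len(hets)):
        for j in range(i + 1, len(hets)):
            a, b = hets[i], hets[j]
            known = AlleleOrigin.TRANS_CONFIRMED in (a.allele_origin, b.allele_origin)
            pairs.append(CompHetPair(a, b, phase_known=known))
    return pairs


def group_by_gene(variants: Iterable[Variant]) -> dict[str, list[Variant]]:
    out: dict[str, list[Variant]] = {}
    for v in variants:
        out.setdefault(normalize_gene(v.gene_symbol), []).append(v)
    return out
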