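"""Missense variant parsing, validation and the annotation table.

Variants are protein-level (HGVS p. notation) on canonical full-length
numbering.  Each carries two independent annotations: a pathogenicity class
(pathogenic / benign / uncertain / unannotated) and a functional class
(loss-of-function / gain-of-function / complex / unannotated).  Only missense
substitutions are in scope; truncating, frameshift and splice notation is
rejected at parse time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._aa import AA1_TO_3, AA3_TO_1, to_one_letter
from .structures import GENE_TO_SUBUNIT, SUBUNIT_TO_GENE, check_subunit


class Pathogenicity(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    UNCERTAIN = "uncertain"
    UNANNOTATED = "unannotated"


class Functional(str, Enum):
    LOF = "LoF"
    GOF = "GoF"
    COMPLEX = "complex"
    UNANNOTATED = "unannotated"


# Heterogeneous source vocabularies normalised to the enums above.
PATHOGENICITY_SYNONYMS: dict[str, Pathogenicity] = {
    "pathogenic": Pathogenicity.PATHOGENIC,
    "likely pathogenic": Pathogenicity.PATHOGENIC,
    "likely_pathogenic": Pathogenicity.PATHOGENIC,
    "benign": Pathogenicity.BENIGN,
    "likely benign": Pathogenicity.BENIGN,
    "likely_benign": Pathogenicity.BENIGN,
    "uncertain": Pathogenicity.UNCERTAIN,
    "uncertain significance": Pathogenicity.UNCERTAIN,
    "uncertain_significance": Pathogenicity.UNCERTAIN,
    "vus": Pathogenicity.UNCERTAIN,
    "unannotated": Pathogenicity.UNANNOTATED,
    ".": Pathogenicity.UNANNOTATED,
    "": Pathogenicity.UNANNOTATED,
}
FUNCTIONAL_SYNONYMS: dict[str, Functional] = {
    "lof": Functional.LOF,
    "loss-of-function": Functional.LOF,
    "loss of function": Functional.LOF,
    "gof": Functional.GOF,
    "gain-of-function": Functional.GOF,
    "gain of function": Functional.GOF,
    "complex": Functional.COMPLEX,
    "unannotated": Functional.UNANNOTATED,
    ".": Functional.UNANNOTATED,
    "": Functional.UNANNOTATED,
}


def normalize_pathogenicity(token: str) -> Pathogenicity:
    try:
        return PATHOGENICITY_SYNONYMS[str(token).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown pathogenicity token {token!r}") from None


def normalize_functional(token: str) -> Functional:
    try:
        return FUNCTIONAL_SYNONYMS[str(token).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown functional token {token!r}") from None


@dataclass(frozen=True)
class ProteinVariant:
    """A missense substitution at a canonical position of one subunit."""

    subunit: str
    pos: int
    ref: str  # 1-letter
    alt: str  # 1-letter

    def __post_init__(self):
        check_subunit(self.subunit)
        object.__setattr__(self, "ref", to_one_letter(self.ref))
        object.__setattr__(self, "alt", to_one_letter(self.alt))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"not a substitution: {self.ref}{self.pos}{self.alt}")

    @property
    def gene(self) -> str:
        return SUBUNIT_TO_GENE[self.subunit]

    def hgvs_p(self) -> str:
        """Normalized three-letter HGVS form, e.g. 'p.(Gly459Arg)'."""
        return f"p.({AA1_TO_3[self.ref]}{self.pos}{AA1_TO_3[self.alt]})"

    def __str__(self) -> str:
        return f"{self.subunit} {self.hgvs_p()}"


_UNSUPPORTED = re.compile(
    r"(Ter|\*|fs|del|dup|ins|ext|=)", re.IGNORECASE
)
_HGVS3 = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$")
_HGVS1 = re.compile(r"^p\.\(?([A-Z])(\d+)([A-Z])\)?$")
_PREFIX = re.compile(r"^(?P<name>[A-Za-z0-9]+)\s*[: ]\s*(?P<rest>p\..*)$")


def parse_hgvs_p(text: str, subunit: str | None = None) -> ProteinVariant:
    """Parse missense HGVS p. notation.

    Accepts 'p.(Gly459Arg)', 'p.Gly459Arg' and one-letter 'p.G459R', with an
    optional 'GENE:' or subunit prefix ('GRIN2B:p.(Gly459Arg)').  Non-missense
    notation (stop, frameshift, indel) raises an unsupported-class error.
    """
    text = text.strip()
    m = _PREFIX.match(text)
    if m:
        name = m.group("name")
        prefix_subunit = GENE_TO_SUBUNIT.get(name.upper()) or (
            name if name in SUBUNIT_TO_GENE else None
        )
        if prefix_subunit is None:
            raise ValueError(f"unknown gene/subunit prefix {name!r}")
        if subunit is not None and subunit != prefix_subunit:
            raise ValueError(
                f"subunit mismatch: prefix says {prefix_subunit}, caller says {subunit}"
            )
        subunit = prefix_subunit
        text = m.group("rest")
    if subunit is None:
        raise ValueError(f"no subunit given for variant {text!r}")
    if _UNSUPPORTED.search(text):
        raise ValueError(
            f"unsupported variant class in {text!r}: only missense substitutions are handled"
        )
    m = _HGVS3.match(text) or _HGVS1.match(text)
    if not m:
        raise ValueError(f"cannot parse HGVS p. notation: {text!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    return ProteinVariant(subunit, pos, to_one_letter(ref), to_one_letter(alt))


@dataclass
class AnnotationRecord:
    pathogenicity: Pathogenicity = Pathogenicity.UNANNOTATED
    functional: Functional = Functional.UNANNOTATED
    source: str = ""

    def __post_init__(self):
        self.pathogenicity = Pathogenicity(self.pathogenicity)
        self.functional = Functional(self.functional)


class VariantDatabase:
    """Missense variants keyed by (subunit, pos, ref, alt) with annotations."""

    def __init__(self):
        self._records: dict[ProteinVariant, AnnotationRecord] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(sorted(self._records, key=lambda v: (v.subunit, v.pos, v.ref, v.alt)))

    def __contains__(self, v: ProteinVariant) -> bool:
        return v in self._records

    def annotation(self, v: ProteinVariant) -> AnnotationRecord:
        return self._records[v]

    def get(self, v: ProteinVariant, default=None):
        return self._records.get(v, default)

    def add(self, v: ProteinVariant, rec: AnnotationRecord, on_conflict: str = "error") -> None:
        old = self._records.get(v)
        if old is not None and (old.pathogenicity, old.functional) != (
            rec.pathogenicity,
            rec.functional,
        ):
            if on_conflict == "error":
                raise ValueError(
                    f"duplicate variant {v} with conflicting annotations: "
                    f"({old.pathogenicity.value}, {old.functional.value}) vs "
                    f"({rec.pathogenicity.value}, {rec.functional.value})"
                )
        self._records[v] = rec

    def items(self):
        return ((v, self._records[v]) for v in self)

    def variants_of(self, subunit: str) -> list[ProteinVariant]:
        return [v for v in self if v.subunit == subunit]


TABLE_COLUMNS = ["gene", "hgvs_p", "pathogenicity", "functional", "source"]


def read_variant_table(path: str | Path) -> VariantDatabase:
    """Read a GRINdb-like TSV (gene, hgvs_p, pathogenicity, functional[, source]).

    '.' marks a missing annotation.  Duplicate keys with conflicting
    annotations and unknown vocabulary tokens raise, naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks required columns: {missing}")
    db = VariantDatabase()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            subunit = GENE_TO_SUBUNIT.get(str(row.gene).upper())
            if subunit is None:
                raise ValueError(f"unknown gene {row.gene!r}")
            v = parse_hgvs_p(str(row.hgvs_p), subunit=subunit)
            rec = AnnotationRecord(
                normalize_pathogenicity(row.pathogenicity),
                normalize_functional(row.functional),
                getattr(row, "source", "") or "",
            )
            db.add(v, rec, on_conflict="error")
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return db


def write_variant_table(db: VariantDatabase, path: str | Path) -> None:
    rows = [
        {
            "gene": v.gene,
            "hgvs_p": v.hgvs_p(),
            "pathogenicity": rec.pathogenicity.value if rec.pathogenicity != Pathogenicity.UNANNOTATED else ".",
            "functional": rec.functional.value if rec.functional != Functional.UNANNOTATED else ".",
            "source": rec.source or ".",
        }
        for v, rec in db.items()
    ]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def validate_against_sequence(
    db: VariantDatabase, sequences: Mapping[str, str]
) -> list[tuple[ProteinVariant, str]]:
    """Variants whose reference residue disagrees with the canonical sequence.

    ``sequences`` maps subunit -> canonical protein sequence (1-based
    positions).  Returns (variant, observed_or_reason) tuples; empty list
    means every reference residue checks out.
    """
    mismatches = []
    for v in db:
        seq = sequences.get(v.subunit)
        if seq is None:
            raise ValueError(f"no canonical sequence provided for {v.subunit}")
        if v.pos > len(seq):
            mismatches.append((v, f"position beyond sequence end ({len(seq)})"))
        elif seq[v.pos - 1] != v.ref:
            mismatches.append((v, seq[v.pos - 1]))
    return mismatches
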