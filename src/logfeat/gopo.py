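"""GO/PO annotation categorization and frequency features.

Annotation records (GO process/function/component plus plant-ontology
anatomy and developmental-stage records) are matched against a small
lexicon of five categories — GO analyses, signaling pathways, gene
associations (regulatory-role words), PO anatomy and PO temporal —
with four kinds of subcategory word lists: signaling terms, 34 major
GO terms, regulatory-role words, and the database's own qualifier
vocabulary.  Per gene, hit counts are folded into a 10-feature
frequency vector.  The word lists ship as editable YAML; the defaults
are declared stand-ins for a release-specific lexicon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

try:  # Bio.UniProt.GOA handles GAF 2.x
    from Bio.UniProt import GOA as _goa
except ImportError:  # pragma: no cover
    _goa = None

__all__ = [
    "AnnotationRecord",
    "CategoryLexicon",
    "FEATURE_NAMES",
    "assign_categories",
    "category_frequency_vector",
    "read_gaf",
]

ASPECTS = ("GO", "PO-anatomy", "PO-temporal")

FEATURE_NAMES = (
    "n_go_records",
    "n_po_anatomy_records",
    "n_po_temporal_records",
    "n_go_major_hits",
    "n_signaling_hits",
    "n_regulatory_role_hits",
    "n_original_qualifier_hits",
    "n_distinct_go_terms",
    "n_distinct_po_terms",
    "n_category_kinds_hit",
)


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    aspect: str
    term: str  # identifier, e.g. GO:0009734
    term_name: str = ""
    qualifier: str = ""
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.aspect not in ASPECTS:
            raise ValueError(f"aspect must be one of {ASPECTS}, got {self.aspect!r}")


@dataclass
class CategoryLexicon:
    signaling_terms: tuple[str, ...]
    go_major_terms: tuple[str, ...]
    regulatory_role_terms: tuple[str, ...]
    original_qualifiers: tuple[str, ...]
    _patterns: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for attr in (
            "signaling_terms",
            "go_major_terms",
            "regulatory_role_terms",
            "original_qualifiers",
        ):
            vals = tuple(v.lower() for v in getattr(self, attr))
            if len(set(vals)) != len(vals):
                raise ValueError(f"duplicate entries in {attr}")
            object.__setattr__(self, attr, vals)
        if len(self.go_major_terms) != 34:
            raise ValueError(
                f"go_major_terms must have exactly 34 entries, "
                f"got {len(self.go_major_terms)}"
            )
        # whole-word, case-insensitive matchers compiled once
        for attr in ("signaling_terms", "go_major_terms", "regulatory_role_terms"):
            self._patterns[attr] = {
                w: re.compile(rf"\b{re.escape(w)}\b", re.IGNORECASE)
                for w in getattr(self, attr)
            }

    @classmethod
    def load(cls, path=None) -> "CategoryLexicon":
        if path is None:
            ref = resources.files("logfeat.data").joinpath("gopo_lexicon.yaml")
            doc = yaml.safe_load(ref.read_text())
        else:
            with open(path) as fh:
                doc = yaml.safe_load(fh)
        return cls(
            signaling_terms=tuple(doc["signaling_terms"]),
            go_major_terms=tuple(doc["go_major_terms"]),
            regulatory_role_terms=tuple(doc["regulatory_role_terms"]),
            original_qualifiers=tuple(doc["original_qualifiers"]),
        )


_KIND_TO_CATEGORY = {
    "signaling_terms": "signaling_pathways",
    "go_major_terms": "go_analyses",
    "regulatory_role_terms": "gene_associations",
}


def assign_categories(
    rec: AnnotationRecord, lex: CategoryLexicon
) -> set[tuple[str, str]]:
    """Match one record against the lexicon.

    Word lists match the term name and qualifier whole-word and
    case-insensitively; the original-qualifier subcategory matches the
    qualifier verbatim (case-insensitive).  PO records additionally
    hit their aspect category unconditionally.
    """
    text = f"{rec.term_name} {rec.qualifier}"
    hits: set[tuple[str, str]] = set()
    for kind, category in _KIND_TO_CATEGORY.items():
        for word, pat in lex._patterns[kind].items():
            if pat.search(text):
                hits.add((category, word))
    q = rec.qualifier.lower()
    if q and q in lex.original_qualifiers:
        hits.add(("original_attributes", q))
    if rec.aspect == "PO-anatomy":
        hits.add(("po_anatomy_genes", rec.term))
    elif rec.aspect == "PO-temporal":
        hits.add(("po_temporal_genes", rec.term))
    return hits


def category_frequency_vector(
    gene_id: str,
    records: Iterable[AnnotationRecord],
    lex: CategoryLexicon,
    dedupe: bool = False,
) -> dict[str, int]:
    """Fold a gene's annotation records into the 10 frequency features.

    Duplicate records count twice by default (frequency semantics);
    ``dedupe=True`` collapses identical records first.  A gene with no
    records yields the all-zero vector.
    """
    recs = [r for r in records if r.gene_id == gene_id]
    if dedupe:
        recs = list(dict.fromkeys(recs))
    counts = dict.fromkeys(FEATURE_NAMES, 0)
    categories_hit = set()
    go_terms, po_terms = set(), set()
    for r in recs:
        if r.aspect == "GO":
            counts["n_go_records"] += 1
            go_terms.add(r.term)
        elif r.aspect == "PO-anatomy":
            counts["n_po_anatomy_records"] += 1
            po_terms.add(r.term)
        else:
            counts["n_po_temporal_records"] += 1
            po_terms.add(r.term)
        for category, _sub in assign_categories(r, lex):
            categories_hit.add(category)
            if category == "go_analyses":
                counts["n_go_major_hits"] += 1
            elif category == "signaling_pathways":
                counts["n_signaling_hits"] += 1
            elif category == "gene_associations":
                counts["n_regulatory_role_hits"] += 1
            elif category == "original_attributes":
                counts["n_original_qualifier_hits"] += 1
    counts["n_distinct_go_terms"] = len(go_terms)
    counts["n_distinct_po_terms"] = len(po_terms)
    counts["n_category_kinds_hit"] = len(categories_hit)
    return counts


def _aspect_from_gaf(rec: Mapping) -> str:
    term = rec.get("GO_ID", "")
    aspect = rec.get("Aspect", "")
    if term.startswith("PO:"):
        return "PO-temporal" if aspect in ("T", "G") else "PO-anatomy"
    return "GO"


def read_gaf(path) -> list[AnnotationRecord]:
    """Read GO/PO annotation records from a GAF 2.x file.

    PO terms (``PO:`` identifiers) are routed to the anatomy aspect
    unless the GAF aspect column marks a growth/temporal record.
    """
    records: list[AnnotationRecord] = []
    if _goa is not None:
        with open(path) as fh:
            for rec in _goa.gafiterator(fh):
                qualifier = "|".join(q for q in rec.get("Qualifier", []) if q)
                records.append(
                    AnnotationRecord(
                        gene_id=rec["DB_Object_ID"],
                        aspect=_aspect_from_gaf(rec),
                        term=rec["GO_ID"],
                        term_name=rec.get("DB_Object_Name", ""),
                        qualifier=qualifier,
                        evidence=rec.get("Evidence", ""),
                    )
                )
        return records
    raise RuntimeError("biopython GAF reader unavailable")


def read_annotation_tsv(path) -> list[AnnotationRecord]:
    """Plain-TSV alternative reader (gene_id, aspect, term, term_name,
    qualifier, evidence)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        AnnotationRecord(
            gene_id=r.gene_id,
            aspect=r.aspect,
            term=r.term,
            term_name=getattr(r, "term_name", ""),
            qualifier=getattr(r, "qualifier", ""),
            evidence=getattr(r, "evidence", ""),
        )
        for r in df.itertuples(index=False)
    ]
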