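"""Biomolecular-condensate (LLPS) annotation features.

Proteins driving or joining liquid-liquid phase separation are
annotated with the condensates they form (nucleoli, P bodies, stress
granules, ...) and a functional type — scaffold (drives assembly),
client (recruited) or regulator (modulates).  A protein's set of
condensates, canonicalized to a sorted key, defines its LLPS type;
domain, functional-type and domain-dimer frequencies are tabulated
per type, small factors are matched as partial subsets of larger
multi-domain molecules, and 13 binary "special flags" summarize
domain properties relevant to condensate formation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CONDENSATE_VOCABULARY",
    "SPECIAL_FLAG_NAMES",
    "FUNCTIONAL_TYPES",
    "LLPSAnnotation",
    "llps_type_key",
    "count_type_frequencies",
    "partial_match_larger",
    "build_special_flags",
]

# ~40 condensate terms, snake_cased; "others" is a real category.
CONDENSATE_VOCABULARY = (
    "balbiani_bodies",
    "cajal_bodies",
    "centrosome_spindle_pole_bodies",
    "chromatin",
    "chromatoid_bodies",
    "cleavage_bodies",
    "ddx1_bodies",
    "dna_damage_foci",
    "droplets",
    "gemini_of_cajal_bodies",
    "germ_plasm_polar_granules",
    "histone_locus_bodies",
    "insulator_bodies",
    "microtubules",
    "mitochondrial_rna_granules",
    "neuronal_granules",
    "nuage",
    "nuclear_pore_complexes",
    "nuclear_speckles",
    "nuclear_stress_bodies",
    "nucleoli",
    "opt_domains",
    "others",
    "paraspeckles",
    "p_bodies",
    "pcg_bodies",
    "pericentriolar_matrices",
    "perinucleolar_compartments",
    "p_granules",
    "pml_nuclear_bodies",
    "post_synaptic_density",
    "pyrenoid_matrices",
    "receptor_clusters",
    "sam68_nuclear_bodies",
    "sirna_bodies",
    "spindle_apparatuses",
    "sponge_bodies",
    "stress_granules",
    "tam_bodies",
    "u_bodies",
)

FUNCTIONAL_TYPES = ("client", "regulator", "scaffold")

# 9 named domain-property flags + 4 configurable slots (defaults drawn
# from the physicochemical property list; a documented gap-filling
# choice, replaceable via the extra_flags argument).
SPECIAL_FLAG_NAMES = (
    "rna_binding_domain",
    "dna_binding_domain",
    "dmi",
    "low_complexity",
    "disordered_region",
    "repeat",
    "coiled_coil",
    "phosphorylation_site",
    "active_site",
    "transmembrane_helix",
    "signal_peptide",
    "domain_linker",
    "glycosylation",
)


def _normalize_term(term: str) -> str:
    return (
        term.strip()
        .lower()
        .replace("/", "_")
        .replace("-", "_")
        .replace(" ", "_")
    )


@dataclass(frozen=True)
class LLPSAnnotation:
    protein_id: str
    condensates: frozenset
    functional_type: str | None = None
    pfams: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.functional_type is not None and (
            self.functional_type not in FUNCTIONAL_TYPES
        ):
            raise ValueError(
                f"functional_type must be in {FUNCTIONAL_TYPES}, "
                f"got {self.functional_type!r}"
            )


def llps_type_key(
    ann: LLPSAnnotation | Iterable[str],
    vocabulary: Sequence[str] = CONDENSATE_VOCABULARY,
) -> str:
    """Canonical LLPS-type key: sorted condensate terms joined by ``|``.

    Order-free — identical condensate sets always yield the same key.
    """
    condensates = (
        ann.condensates if isinstance(ann, LLPSAnnotation) else frozenset(ann)
    )
    if not condensates:
        raise ValueError("LLPS-flagged protein has an empty condensate set")
    terms = sorted(_normalize_term(t) for t in condensates)
    unknown = [t for t in terms if t not in vocabulary]
    if unknown:
        raise ValueError(
            f"unknown condensate terms {unknown}; vocabulary: "
            f"{', '.join(vocabulary)}"
        )
    return "|".join(terms)


def count_type_frequencies(
    proteins: Sequence[LLPSAnnotation], mode: str = "domain"
) -> pd.DataFrame:
    """Frequency matrix of units x LLPS types.

    ``mode="domain"`` counts each Pfam occurrence of each protein under
    the protein's type; ``"functional_type"`` counts the functional
    role; ``"dimer"`` counts unordered within-protein Pfam pairs
    (self-pairs only when a Pfam occurs at least twice in the protein).
    Counts are additive over protein-set partitions.
    """
    counts: Counter = Counter()
    for ann in proteins:
        key = llps_type_key(ann)
        if mode == "domain":
            for pf in ann.pfams:
                counts[(pf, key)] += 1
        elif mode == "functional_type":
            if ann.functional_type is not None:
                counts[(ann.functional_type, key)] += 1
        elif mode == "dimer":
            for a, b in combinations(sorted(set(ann.pfams)), 2):
                counts[(f"{a}--{b}", key)] += 1
            for pf, k in Counter(ann.pfams).items():
                if k >= 2:
                    counts[(f"{pf}--{pf}", key)] += 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if not counts:
        return pd.DataFrame()
    df = pd.Series(counts).unstack(fill_value=0)
    df.index.name = "unit"
    df.columns.name = "llps_type"
    return df


def partial_match_larger(
    protein_pfams: Iterable[str],
    larger_molecules: Iterable[Iterable[str]],
) -> dict:
    """Match a protein into larger multi-domain molecules.

    The protein matches when its Pfam set is a subset of a candidate
    with strictly more Pfams (hetero-oligomers; factors that evolved
    from several genes).  Reports the largest matching candidate's
    Pfam count.
    """
    pset = set(protein_pfams)
    best = 0
    for cand in larger_molecules:
        cset = set(cand)
        if pset <= cset and len(cset) > len(pset):
            best = max(best, len(cset))
    return {"matched": best > 0, "n_pfam_of_match": best}


def build_special_flags(
    protein_id: str,
    pfams: Iterable[str],
    evidence: Mapping[str, object],
    flag_names: Sequence[str] = SPECIAL_FLAG_NAMES,
) -> dict[str, object]:
    """Derive the 13 special flags from per-flag evidence tables.

    ``evidence`` maps flag name -> either a set of Pfams carrying the
    property or a mapping protein_id -> bool/positions.  A flag whose
    evidence table is missing is emitted as ``"unknown"`` rather than
    silently false.
    """
    if len(flag_names) != 13:
        raise ValueError(f"exactly 13 flags expected, got {len(flag_names)}")
    pfset = set(pfams)
    out: dict[str, object] = {}
    for name in flag_names:
        if name not in evidence:
            out[name] = "unknown"
            continue
        ev = evidence[name]
        if isinstance(ev, (set, frozenset, list, tuple)):
            out[name] = bool(pfset & set(ev))
        elif isinstance(ev, Mapping):
            out[name] = bool(ev.get(protein_id))
        else:
            raise TypeError(
                f"evidence for {name!r} must be a Pfam set or protein mapping"
            )
    return out


def read_llps_table(path) -> list[LLPSAnnotation]:
    """Read protein LLPS annotations from TSV (protein_id, condensates
    ';'-joined, functional_type, pfams ';'-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            LLPSAnnotation(
                protein_id=row.protein_id,
                condensates=frozenset(
                    t for t in str(row.condensates).split(";") if t
                ),
                functional_type=(row.functional_type or None),
                pfams=tuple(p for p in str(row.pfams).split(";") if p),
            )
        )
    return out
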