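"""Protein assembly-cluster taxonomy and oligomerization features.

Assembly clusters are records of (stoichiometry, point-group symmetry,
obligacy) for structures sharing a Pfam architecture.  The taxonomy
distinguishes composition (*homo*: a single chain letter "A"; *hetero*:
multiple distinct letters) and assembly state (*monomer*: C1 with one
chain copy; *oligomer*: rotational symmetry order >= 2; *single*: an
asymmetric C1 assembly of several chains).  Per protein, the clusters
observed are folded into a composite oligomerization-type label (the
crystallographic-monomer case C1-A1 is labelled ``CMA``) and into a
19-value feature vector.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "AssemblyCluster",
    "OligomerClassLabel",
    "parse_stoichiometry",
    "symmetry_order",
    "classify_cluster",
    "compose_oligomer_label",
    "parse_oligomer_label",
    "derive_protcad_features",
    "DEFAULT_FEATURE_NAMES",
    "read_assembly_table",
]

_STOICH_RE = re.compile(r"([A-Z])(\d*)")
_SYM_RE = re.compile(r"^([A-Z])(\d*)$")

OBLIGACY_LEVELS = ("obligate", "moderate", "transient", "unknown")
STATE_ORDER = ("monomer", "single", "oligomer")


@dataclass(frozen=True)
class AssemblyCluster:
    group_id: str
    stoichiometry: str
    symmetry: str
    obligate_class: str = "unknown"
    pfam_architecture: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.obligate_class not in OBLIGACY_LEVELS:
            raise ValueError(
                f"obligate_class must be one of {OBLIGACY_LEVELS}, "
                f"got {self.obligate_class!r}"
            )


@dataclass
class OligomerClassLabel:
    label: str
    components: dict = field(default_factory=dict)


def parse_stoichiometry(s: str) -> dict[str, int]:
    """Parse a stoichiometry string like ``"A2BC"`` into {chain: copies}.

    An omitted count means one copy.  Malformed strings raise with the
    offset of the first bad character.
    """
    if not s:
        raise ValueError("empty stoichiometry string")
    out: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _STOICH_RE.match(s, pos)
        if not m:
            raise ValueError(f"malformed stoichiometry {s!r} at offset {pos}")
        letter, digits = m.groups()
        out[letter] = out.get(letter, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return out


def symmetry_order(symmetry: str, double_dihedral: bool = False) -> int:
    """Numeric order of a point-group token: C2 -> 2, D3 -> 3 (6 if
    ``double_dihedral``), C1 -> 1.  A token without a suffix reads as 1."""
    m = _SYM_RE.match(symmetry.strip())
    if not m:
        raise ValueError(f"malformed symmetry token {symmetry!r}")
    series, digits = m.groups()
    n = int(digits) if digits else 1
    if double_dihedral and series == "D":
        n *= 2
    return n


def classify_cluster(
    c: AssemblyCluster, double_dihedral: bool = False
) -> dict[str, str]:
    """Composition (homo/hetero) and assembly state of one cluster."""
    stoich = parse_stoichiometry(c.stoichiometry)
    order = symmetry_order(c.symmetry, double_dihedral)
    total = sum(stoich.values())
    composition = "homo" if len(stoich) == 1 else "hetero"
    if order >= 2:
        state = "oligomer"
    elif total == 1:
        state = "monomer"
    else:
        # asymmetric (order-1) assembly of several chains; the
        # canonical case is C1 from multiple sequences (e.g. C1-A2BC)
        state = "single"
    return {"composition": composition, "state": state}


def _is_cma(c: AssemblyCluster) -> bool:
    stoich = parse_stoichiometry(c.stoichiometry)
    return (
        symmetry_order(c.symmetry) == 1
        and len(stoich) == 1
        and sum(stoich.values()) == 1
    )


def compose_oligomer_label(clusters: Sequence[AssemblyCluster]) -> OligomerClassLabel:
    """Fold all clusters of one protein/group into a composite label.

    Grammar (deterministic, permutation-invariant, round-trippable via
    :func:`parse_oligomer_label`)::

        CMA                                   all clusters are C1-A1
        [C1_] <composition> _ <obl_front> _ <states...> _ <obl_back>

    where composition is ``homo`` / ``hetero`` / ``homo_hetero``,
    states are the observed assembly states in (monomer, single,
    oligomer) order, and the front/back obligacy tokens are the
    obligacies attached to the first and last state respectively (a
    single observed obligacy appears on both sides; obligacies tied to
    the same state order moderate-before-obligate).  ``C1_`` prefixes
    labels whose clusters include an asymmetric multi-sequence C1
    assembly.
    """
    if not clusters:
        raise ValueError("compose_oligomer_label requires at least one cluster")
    if all(_is_cma(c) for c in clusters):
        return OligomerClassLabel(
            label="CMA", components={"composition": "homo", "states": ["monomer"]}
        )

    cls = [classify_cluster(c) for c in clusters]
    compositions = sorted(
        {k["composition"] for k in cls}, key=["homo", "hetero"].index
    )
    states = sorted({k["state"] for k in cls}, key=STATE_ORDER.index)
    comp_part = "_".join(compositions)

    # obligacy of the earliest/latest state; conflicts resolved by
    # precedence (obligate > moderate > transient > unknown)
    def obligacy_for(state: str) -> str:
        obls = {
            c.obligate_class for c, k in zip(clusters, cls) if k["state"] == state
        }
        return min(obls, key=OBLIGACY_LEVELS.index)

    all_obls = sorted(
        {c.obligate_class for c in clusters}, key=OBLIGACY_LEVELS.index
    )
    front = obligacy_for(states[0])
    back = obligacy_for(states[-1])
    if front == back and len(all_obls) == 2:
        # both obligacies co-occur with the same state(s):
        # moderate brackets first, obligate last
        front, back = all_obls[1], all_obls[0]

    prefix = (
        "C1_"
        if any(
            k["state"] == "single" and k["composition"] == "hetero" for k in cls
        )
        else ""
    )
    label = f"{prefix}{comp_part}_{front}_" + "_".join(states) + f"_{back}"
    return OligomerClassLabel(
        label=label,
        components={
            "composition": compositions,
            "states": states,
            "obligacy_front": front,
            "obligacy_back": back,
            "c1_single": bool(prefix),
        },
    )


def parse_oligomer_label(label: str) -> dict:
    """Invert :func:`compose_oligomer_label` into its components."""
    if label == "CMA":
        return {"composition": ["homo"], "states": ["monomer"]}
    tokens = label.split("_")
    c1 = tokens[0] == "C1"
    if c1:
        tokens = tokens[1:]
    compositions = []
    while tokens and tokens[0] in ("homo", "hetero"):
        compositions.append(tokens.pop(0))
    if len(tokens) < 2:
        raise ValueError(f"unparseable oligomer label {label!r}")
    front, back = tokens[0], tokens[-1]
    states = tokens[1:-1]
    if front not in OBLIGACY_LEVELS or back not in OBLIGACY_LEVELS:
        raise ValueError(f"unparseable oligomer label {label!r}")
    if any(s not in STATE_ORDER for s in states):
        raise ValueError(f"unparseable oligomer label {label!r}")
    return {
        "composition": compositions,
        "states": states,
        "obligacy_front": front,
        "obligacy_back": back,
        "c1_single": c1,
    }


DEFAULT_FEATURE_NAMES = (
    "n_clusters",
    "n_homo",
    "n_hetero",
    "n_monomer",
    "n_single",
    "n_oligomer",
    "frac_oligomer",
    "max_symmetry_order",
    "mean_symmetry_order",
    "n_distinct_symmetries",
    "max_total_copies",
    "mean_total_copies",
    "max_distinct_chains",
    "n_distinct_stoichiometries",
    "n_obligate",
    "n_moderate",
    "n_transient",
    "n_unknown_obligacy",
    "has_cma",
)


def derive_protcad_features(
    clusters: Sequence[AssemblyCluster],
    double_dihedral: bool = False,
) -> dict[str, float]:
    """Aggregate a protein's clusters into the 19 summary features.

    The reduction (counts, fractions, maxima/means over symmetry order
    and chain-copy totals, obligacy tallies, CMA presence) condenses
    the raw per-cluster assembly variables; ``max_symmetry_order`` is
    the "maximum of symmetries" value reused by the interface-cluster
    comparison.
    """
    if not clusters:
        raise ValueError("derive_protcad_features requires at least one cluster")
    cls = [classify_cluster(c, double_dihedral) for c in clusters]
    orders = [symmetry_order(c.symmetry, double_dihedral) for c in clusters]
    stoichs = [parse_stoichiometry(c.stoichiometry) for c in clusters]
    totals = [sum(s.values()) for s in stoichs]
    obl = Counter(c.obligate_class for c in clusters)
    state = Counter(k["state"] for k in cls)
    comp = Counter(k["composition"] for k in cls)
    n = len(clusters)
    feats = {
        "n_clusters": float(n),
        "n_homo": float(comp["homo"]),
        "n_hetero": float(comp["hetero"]),
        "n_monomer": float(state["monomer"]),
        "n_single": float(state["single"]),
        "n_oligomer": float(state["oligomer"]),
        "frac_oligomer": state["oligomer"] / n,
        "max_symmetry_order": float(max(orders)),
        "mean_symmetry_order": sum(orders) / n,
        "n_distinct_symmetries": float(len({c.symmetry for c in clusters})),
        "max_total_copies": float(max(totals)),
        "mean_total_copies": sum(totals) / n,
        "max_distinct_chains": float(max(len(s) for s in stoichs)),
        "n_distinct_stoichiometries": float(
            len({c.stoichiometry for c in clusters})
        ),
        "n_obligate": float(obl["obligate"]),
        "n_moderate": float(obl["moderate"]),
        "n_transient": float(obl["transient"]),
        "n_unknown_obligacy": float(obl["unknown"]),
        "has_cma": float(any(_is_cma(c) for c in clusters)),
    }
    assert len(feats) == 19
    return feats


def read_assembly_table(path) -> pd.DataFrame:
    """Read a TSV of assembly clusters (group_id, protein_id,
    pfam_architecture, stoichiometry, symmetry, obligate_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    required = {"group_id", "stoichiometry", "symmetry"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assembly table missing columns: {sorted(missing)}")
    return df


def clusters_from_frame(df: pd.DataFrame) -> list[AssemblyCluster]:
    out = []
    for row in df.itertuples(index=False):
        arch = getattr(row, "pfam_architecture", "") or ""
        out.append(
            AssemblyCluster(
                group_id=row.group_id,
                stoichiometry=row.stoichiometry,
                symmetry=row.symmetry,
                obligate_class=getattr(row, "obligate_class", "unknown"),
                pfam_architecture=tuple(p for p in str(arch).split(";") if p),
            )
        )
    return out
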