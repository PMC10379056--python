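"""Domain-interaction interface statistics and region annotation.

Interface entries list the residue positions each side of a
domain-domain (DDI) or domain-motif (DMI) contact contributes.
Contiguous interface stretches ("fragments") are maximal runs with at
most three missing residues between consecutive kept positions.
Entries sharing a domain pair are split into a non-redundant cluster
(architectures where each member domain occurs once, e.g. Dom1-Dom2)
and a redundant cluster (a repeated member, e.g. Dom1-Dom2-Dom1), and
the two clusters are compared value-by-value with one-way ANOVA —
run regardless of normality, since the magnitude of the difference is
the quantity of interest.

The module also maps protein-level physicochemical/PTM annotations
onto domain and interdomain regions, and pools Pfam clans across a
protein's interaction partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InterfaceEntry",
    "Fragment",
    "PairClusterComparison",
    "RegionAnnotation",
    "split_fragments",
    "is_redundant_architecture",
    "entry_measures",
    "COMPARISON_VALUE_NAMES",
    "compare_interface_clusters",
    "map_features_to_regions",
    "clan_pool",
    "read_interface_table",
]


@dataclass(frozen=True)
class InterfaceEntry:
    """One DDI/DMI record: the unordered domain pair, the parent
    entry's domain architecture, and the interface residue positions
    (1-based, strictly increasing) on each side."""

    domain_pair: frozenset
    architecture: tuple[str, ...]
    side_positions: tuple[tuple[int, ...], tuple[int, ...]]
    kind: str = "DDI"
    max_symmetry: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("DDI", "DMI"):
            raise ValueError(f"kind must be DDI or DMI, got {self.kind!r}")
        for side in self.side_positions:
            if any(b <= a for a, b in zip(side, side[1:])):
                raise ValueError("side positions must be strictly increasing")


@dataclass(frozen=True)
class Fragment:
    positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.positions)


def split_fragments(
    positions: Sequence[int], max_gap: int = 3
) -> list[Fragment]:
    """Split interface positions into gap-limited fragments.

    A break occurs between consecutive positions p < q whenever more
    than ``max_gap`` residues are missing between them (q - p - 1 >
    max_gap); a gap of exactly ``max_gap`` does not split.
    """
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be sorted and distinct")
    frags: list[list[int]] = []
    for p in positions:
        if frags and p - frags[-1][-1] - 1 <= max_gap:
            frags[-1].append(p)
        else:
            frags.append([p])
    return [Fragment(tuple(f)) for f in frags]


def is_redundant_architecture(architecture: Sequence[str]) -> bool:
    """True when any member domain occurs more than once (Dom1-Dom2-Dom1)."""
    return len(set(architecture)) < len(architecture)


COMPARISON_VALUE_NAMES = (
    "n_interacting_domains",
    "n_interacting_motifs",
    "n_interface_residues",
    "n_fragments",
    "mean_fragment_length",
    "max_fragment_length",
    "min_fragment_length",
    "sd_fragment_length",
    "n_single_residue_fragments",
    "mean_inter_fragment_gap",
    "residues_side_a",
    "residues_side_b",
    "protcad_max_symmetry",
)


def entry_measures(entry: InterfaceEntry, max_gap: int = 3) -> dict[str, float]:
    """The 13 per-entry interface measurements compared across clusters."""
    frags = [
        f
        for side in entry.side_positions
        for f in split_fragments(side, max_gap)
    ]
    lengths = np.array([f.length for f in frags], dtype=float)
    sides = [len(s) for s in entry.side_positions]
    gaps = [
        b.positions[0] - a.positions[-1] - 1
        for side in entry.side_positions
        for a, b in zip(
            split_fragments(side, max_gap), split_fragments(side, max_gap)[1:]
        )
    ]
    return {
        "n_interacting_domains": float(
            sum(1 for side in entry.side_positions if side) if entry.kind == "DDI" else 1
        ),
        "n_interacting_motifs": float(entry.kind == "DMI"),
        "n_interface_residues": float(sum(sides)),
        "n_fragments": float(len(frags)),
        "mean_fragment_length": float(lengths.mean()) if len(frags) else 0.0,
        "max_fragment_length": float(lengths.max()) if len(frags) else 0.0,
        "min_fragment_length": float(lengths.min()) if len(frags) else 0.0,
        "sd_fragment_length": float(lengths.std(ddof=0)) if len(frags) else 0.0,
        "n_single_residue_fragments": float((lengths == 1).sum()),
        "mean_inter_fragment_gap": float(np.mean(gaps)) if gaps else 0.0,
        "residues_side_a": float(sides[0]),
        "residues_side_b": float(sides[1]),
        "protcad_max_symmetry": float(entry.max_symmetry),
    }


@dataclass
class PairClusterComparison:
    domain_pair: frozenset
    nr_size: int
    redundant_size: int
    per_cluster: pd.DataFrame  # (value, cluster) -> mean/sd/n
    anova: pd.DataFrame  # value -> F, p (NaN when not applicable)

    @property
    def anova_applicable(self) -> bool:
        return self.nr_size >= 1 and self.redundant_size >= 1


def _oneway(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p across two groups.

    Degenerate case: when both between- and within-group variance are
    zero (identical constant groups) the comparison carries no signal
    and is reported as F = 0, p = 1.
    """
    if len(a) < 1 or len(b) < 1 or len(a) + len(b) < 3:
        return float("nan"), float("nan")
    grand = np.concatenate([a, b])
    if np.allclose(grand, grand[0]):
        return 0.0, 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(a, b)
    return float(f), float(p)


def compare_interface_clusters(
    entries: Sequence[InterfaceEntry], max_gap: int = 3
) -> PairClusterComparison:
    """Split a domain pair's entries into NR vs redundant clusters and
    compare the 13 interface values with one-way ANOVA.

    Normality is not tested before the ANOVA; the F statistics are
    reported as effect-magnitude screens and carry that caveat.
    """
    if not entries:
        raise ValueError("no interface entries supplied")
    pairs = {e.domain_pair for e in entries}
    if len(pairs) != 1:
        raise ValueError(f"entries span multiple domain pairs: {len(pairs)}")

    nr_rows, red_rows = [], []
    for e in entries:
        (red_rows if is_redundant_architecture(e.architecture) else nr_rows).append(
            entry_measures(e, max_gap)
        )
    nr = pd.DataFrame(nr_rows, columns=list(COMPARISON_VALUE_NAMES))
    red = pd.DataFrame(red_rows, columns=list(COMPARISON_VALUE_NAMES))

    stats_rows, anova_rows = [], []
    for name in COMPARISON_VALUE_NAMES:
        a = nr[name].to_numpy(dtype=float)
        b = red[name].to_numpy(dtype=float)
        for cluster, vals in (("nr", a), ("redundant", b)):
            stats_rows.append(
                {
                    "value": name,
                    "cluster": cluster,
                    "mean": float(vals.mean()) if len(vals) else float("nan"),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n": len(vals),
                }
            )
        f, p = _oneway(a, b)
        anova_rows.append({"value": name, "F": f, "p": p})

    return PairClusterComparison(
        domain_pair=next(iter(pairs)),
        nr_size=len(nr),
        redundant_size=len(red),
        per_cluster=pd.DataFrame(stats_rows).set_index(["value", "cluster"]),
        anova=pd.DataFrame(anova_rows).set_index("value"),
    )


@dataclass(frozen=True)
class RegionAnnotation:
    protein_id: str
    kind: str  # "domain" | "interdomain"
    span: tuple[int, int]  # 1-based inclusive
    pfam: str | None = None
    positional_features: tuple = ()  # (feature_name, position)
    protein_level_features: Mapping[str, object] = field(default_factory=dict)


def _resolve_overlaps(domains: Sequence[tuple[str, int, int]]):
    """Keep the longer span when two domain annotations overlap."""
    kept: list[tuple[str, int, int]] = []
    discarded = []
    for d in sorted(domains, key=lambda d: (-(d[2] - d[1]), d[1])):
        if any(not (d[2] < k[1] or d[1] > k[2]) for k in kept):
            discarded.append(d)
        else:
            kept.append(d)
    return sorted(kept, key=lambda d: d[1]), discarded


def map_features_to_regions(
    protein_id: str,
    protein_length: int,
    domain_positions: Sequence[tuple[str, int, int]],
    positional_features: Iterable[tuple[str, int]] = (),
    protein_level_features: Mapping[str, object] | None = None,
) -> list[RegionAnnotation]:
    """Tile a protein into domain + interdomain regions and attach
    annotations.

    Domain spans are 1-based inclusive ``(pfam, start, end)``.
    Interdomain regions are the complement within [1, length].
    Position-borne features (PTM sites, glycosylation sites, ...) are
    assigned to the containing region; protein-global features (GRAVY,
    pI, subcellular location, ...) are attached to every region.
    Overlapping domain annotations keep the longer span.
    """
    for pf, s, e in domain_positions:
        if not (1 <= s <= e <= protein_length):
            raise ValueError(f"domain {pf} span ({s},{e}) outside [1,{protein_length}]")
    feats = list(positional_features)
    for name, pos in feats:
        if not (1 <= pos <= protein_length):
            raise ValueError(
                f"feature {name!r} position {pos} beyond protein length "
                f"{protein_length}"
            )
    domains, _discarded = _resolve_overlaps(list(domain_positions))

    spans: list[tuple[str, str | None, int, int]] = []
    cursor = 1
    for pf, s, e in domains:
        if s > cursor:
            spans.append(("interdomain", None, cursor, s - 1))
        spans.append(("domain", pf, s, e))
        cursor = e + 1
    if cursor <= protein_length:
        spans.append(("interdomain", None, cursor, protein_length))

    global_feats = dict(protein_level_features or {})
    out = []
    for kind, pf, s, e in spans:
        inside = tuple((n, p) for n, p in feats if s <= p <= e)
        out.append(
            RegionAnnotation(
                protein_id=protein_id,
                kind=kind,
                span=(s, e),
                pfam=pf,
                positional_features=inside,
                protein_level_features=global_feats,
            )
        )
    return out


def clan_pool(
    protein_id: str,
    ppi_edges: Iterable[tuple[str, str]],
    protein_pfams: Mapping[str, Iterable[str]],
    pfam_clan_map: Mapping[str, str],
) -> set[str]:
    """Union of Pfam clans over all interaction partners of a protein.

    Pfams without a clan assignment pass through as singleton
    pseudo-clans (the Pfam accession itself).  A protein absent from
    the edge list has an empty pool.
    """
    partners = set()
    for a, b in ppi_edges:
        if a == protein_id:
            partners.add(b)
        elif b == protein_id:
            partners.add(a)
    pool: set[str] = set()
    for p in partners:
        for pf in protein_pfams.get(p, ()):
            pool.add(pfam_clan_map.get(pf, pf))
    return pool


def read_interface_table(path) -> list[InterfaceEntry]:
    """Read interface entries from TSV (columns: domain_a, domain_b,
    architecture ';'-joined, positions_a/positions_b ','-joined, kind,
    optional max_symmetry)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for row in df.itertuples(index=False):
        pos_a = tuple(int(x) for x in str(row.positions_a).split(",") if x)
        pos_b = tuple(int(x) for x in str(row.positions_b).split(",") if x)
        entries.append(
            InterfaceEntry(
                domain_pair=frozenset((row.domain_a, row.domain_b)),
                architecture=tuple(str(row.architecture).split(";")),
                side_positions=(pos_a, pos_b),
                kind=getattr(row, "kind", "DDI"),
                max_symmetry=float(getattr(row, "max_symmetry", 1.0)),
            )
        )
    return entries
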