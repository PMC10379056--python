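"""TF-motif incidence counts and binding-site-to-gene-feature mapping.

Transcription-factor records carry a DNA-binding-domain sequence and a
set of motif types (ambiguous-DNA consensus strings); both marginals
of the TF x motif incidence matrix are tabulated.  Binding sites (BED,
0-based half-open) are mapped onto typed gene-feature intervals (CDS,
exon, UTR, intron, upstream, downstream) derived from GFF3 gene
models, counting a site toward every feature it overlaps by at least
one base pair — the overlap semantics of ``bedmap``.  All coordinates
are handled internally as 0-based half-open; GFF3's 1-based closed
spans are converted at the I/O edge.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "TFRecord",
    "BindingSite",
    "GeneModel",
    "FEATURE_TYPES",
    "count_motif_types",
    "map_sites_to_features",
    "read_bed",
    "read_gff3_gene_models",
    "read_tf_table",
]

FEATURE_TYPES = ("CDS", "exon", "UTR", "intron", "upstream", "downstream")

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class TFRecord:
    tf_id: str
    family: str = ""
    dbd_sequence: str = ""
    motifs: Mapping[str, str] = field(default_factory=dict)  # motif id -> consensus

    def __post_init__(self) -> None:
        for mid, consensus in self.motifs.items():
            bad = set(consensus.upper()) - _IUPAC_DNA
            if bad:
                raise ValueError(
                    f"motif {mid} of {self.tf_id} has non-IUPAC symbols {sorted(bad)}"
                )


@dataclass(frozen=True)
class BindingSite:
    chrom: str
    start: int  # 0-based half-open
    end: int
    tf_id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid site interval [{self.start},{self.end}) on {self.chrom}"
            )


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # gene span, 0-based half-open
    end: int
    strand: str
    features: list[tuple[str, int, int]] = field(default_factory=list)

    def with_flanks_and_introns(
        self, upstream_bp: int = 2000, downstream_bp: int = 2000,
        infer_utr: bool = True,
    ) -> "GeneModel":
        """Return a copy with introns (exon complement within the gene
        span), optional UTR inference (exon minus CDS), and
        strand-aware upstream/downstream windows added."""
        feats = list(self.features)
        exons = sorted([(s, e) for t, s, e in feats if t == "exon"])
        cds = sorted([(s, e) for t, s, e in feats if t == "CDS"])
        # introns: gaps between consecutive exons
        for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
            if s2 > e1:
                feats.append(("intron", e1, s2))
        if infer_utr and cds and not any(t == "UTR" for t, _s, _e in feats):
            for es, ee in exons:
                for us, ue in _subtract_interval((es, ee), cds):
                    feats.append(("UTR", us, ue))
        if self.strand == "-":
            up = ("upstream", self.end, self.end + upstream_bp)
            down = ("downstream", max(0, self.start - downstream_bp), self.start)
        else:
            up = ("upstream", max(0, self.start - upstream_bp), self.start)
            down = ("downstream", self.end, self.end + downstream_bp)
        for t, s, e in (up, down):
            if e > s:
                feats.append((t, s, e))
        return GeneModel(
            self.gene_id, self.chrom, self.start, self.end, self.strand, feats
        )


def _subtract_interval(iv, others):
    """Subtract a sorted list of intervals from one interval (half-open)."""
    s, e = iv
    out = []
    cursor = s
    for os_, oe in others:
        if oe <= cursor or os_ >= e:
            continue
        if os_ > cursor:
            out.append((cursor, os_))
        cursor = max(cursor, oe)
    if cursor < e:
        out.append((cursor, e))
    return out


def count_motif_types(tfs: Sequence[TFRecord]) -> dict[str, dict[str, int]]:
    """Both marginals of the TF x motif-type incidence matrix: how many
    motif types each TF binds, and how many TFs bind each motif type."""
    per_tf: dict[str, int] = {}
    per_motif: Counter = Counter()
    for tf in tfs:
        per_tf[tf.tf_id] = len(tf.motifs)
        for mid in tf.motifs:
            per_motif[mid] += 1
    return {"per_tf": per_tf, "per_motif": dict(per_motif)}


def map_sites_to_features(
    sites: Iterable[BindingSite],
    models: Sequence[GeneModel],
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
) -> tuple[pd.DataFrame, list[BindingSite]]:
    """Count binding sites per (gene, feature type).

    A site increments every feature interval it overlaps by >= 1 bp
    (half-open arithmetic: adjacent intervals share no position), and
    may hit several features and several genes.  Sites on chromosomes
    absent from the models are returned in the unmapped list.

    Returns a DataFrame with columns gene_id, feature, count and the
    unmapped sites.
    """
    if upstream_bp <= 0 or downstream_bp <= 0:
        raise ValueError("flank window widths must be positive")
    trees: dict[str, IntervalTree] = {}
    for m in models:
        mm = m.with_flanks_and_introns(upstream_bp, downstream_bp)
        tree = trees.setdefault(m.chrom, IntervalTree())
        for ftype, s, e in mm.features:
            if e > s:
                tree.addi(s, e, (m.gene_id, ftype))
    counts: Counter = Counter()
    unmapped: list[BindingSite] = []
    for site in sites:
        tree = trees.get(site.chrom)
        if tree is None:
            unmapped.append(site)
            continue
        for hit in tree.overlap(site.start, site.end):
            counts[hit.data] += 1
    df = pd.DataFrame(
        [
            {"gene_id": g, "feature": f, "count": c}
            for (g, f), c in sorted(counts.items())
        ],
        columns=["gene_id", "feature", "count"],
    )
    return df, unmapped


def read_bed(path) -> list[BindingSite]:
    """Read binding sites from BED (chrom, start, end[, name, score,
    strand]); BED is already 0-based half-open."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            sites.append(
                BindingSite(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    tf_id=parts[3] if len(parts) > 3 else "",
                    strand=parts[5] if len(parts) > 5 else ".",
                )
            )
    return sites


def read_gff3_gene_models(path) -> list[GeneModel]:
    """Read gene models from GFF3 via gffutils (in-memory db).

    GFF3 1-based closed spans become 0-based half-open here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        feats = []
        for child in db.children(gene):
            if child.featuretype in ("CDS", "exon") or "UTR" in child.featuretype:
                ftype = "UTR" if "UTR" in child.featuretype else child.featuretype
                feats.append((ftype, child.start - 1, child.end))
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                features=feats,
            )
        )
    return models


def read_tf_table(path) -> list[TFRecord]:
    """Read TF records from TSV (tf_id, family, dbd_sequence, motifs as
    'id:consensus' ';'-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    tfs = []
    for row in df.itertuples(index=False):
        motifs = {}
        for item in str(row.motifs).split(";"):
            if item:
                mid, _, consensus = item.partition(":")
                motifs[mid] = consensus
        tfs.append(
            TFRecord(
                tf_id=row.tf_id,
                family=getattr(row, "family", ""),
                dbd_sequence=getattr(row, "dbd_sequence", ""),
                motifs=motifs,
            )
        )
    return tfs
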