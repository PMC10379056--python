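"""Deterministic miniature snapshots of every source-table schema.

The generator emits an internally consistent bundle of plain-text
files — assembly clusters, interface entries, LLPS annotations, GO/PO
GAF records, TF records, PPI edges, binding sites (BED), gene models
(GFF3) and protein sequences (FASTA) — so the feature modules and the
end-to-end pipeline run and are tested without any database download.
Identifier namespaces are prefixed (PF_, PR_, TF_, G_) to make join
errors obvious.  All randomness flows through one seeded generator.

``inject_signal`` produces labeled mixed-categorical tables with a
controllable class-feature dependence: the joint law is
p(class, features) proportional to exp(effect * scale * #matches), so
given the features the class log-odds shift additively by
effect * scale per matching informative level; effect 0 gives exact
independence, effect 1 near-deterministic coupling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .llps import CONDENSATE_VOCABULARY
from .pipeline import FeatureTable

__all__ = [
    "FixtureConfig",
    "SignalSpec",
    "generate_bundle",
    "inject_signal",
    "bundle_feature_table",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_DNA = "ACGT"
_AMBIG = "ACGTRYSWKMBDHVN"

BUNDLE_FILES = (
    "assemblies.tsv",
    "interfaces.tsv",
    "llps.tsv",
    "gopo.gaf",
    "tfs.tsv",
    "ppi.tsv",
    "sites.bed",
    "genes.gff3",
    "proteins.fasta",
)


@dataclass
class FixtureConfig:
    seed: int
    n_proteins: int = 50
    n_pfams: int = 20
    n_tfs: int = 10
    n_genes: int = 12
    n_condensates: int = 8
    protein_length: tuple[int, int] = (80, 300)
    class_fractions: tuple[float, ...] | None = None  # imbalance preset

    def __post_init__(self) -> None:
        if self.n_pfams <= 0:
            raise ValueError("n_pfams must be positive when domains are requested")
        if self.n_proteins <= 0 or self.n_tfs <= 0 or self.n_genes <= 0:
            raise ValueError("entity counts must be positive")
        if self.n_condensates > len(CONDENSATE_VOCABULARY):
            raise ValueError("n_condensates exceeds the vocabulary size")


@dataclass
class SignalSpec:
    """Class-feature dependence for labeled tables.

    ``n_informative`` features carry the signal at strength ``effect``
    (0 = independent, 1 = near-deterministic at the default scale);
    ``n_noise`` features are independent of the class.
    """

    n_classes: int = 4
    n_informative: int = 3
    n_noise: int = 5
    n_levels: int = 4
    effect: float = 1.0
    scale: float = 4.0
    class_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.effect <= 1:
            raise ValueError("effect strength must be in [0, 1]")


def _random_seq(rng, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def generate_bundle(config: FixtureConfig, out_dir) -> dict:
    """Write the fixture bundle; returns the manifest (paths+checksums).

    Deterministic: the same config (including seed) produces
    byte-identical files.  Referential integrity holds across files —
    every Pfam in the interface table appears in some protein's domain
    list, PPI edges connect generated proteins, binding sites point at
    generated chromosomes, etc.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pfams = [f"PF_{i:04d}" for i in range(config.n_pfams)]
    proteins = [f"PR_{i:04d}" for i in range(config.n_proteins)]
    tfs = [f"TF_{i:03d}" for i in range(config.n_tfs)]
    genes = [f"G_{i:03d}" for i in range(config.n_genes)]
    condensates = list(
        rng.choice(CONDENSATE_VOCABULARY, size=config.n_condensates, replace=False)
    )

    lo, hi = config.protein_length
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    protein_pfams = {}
    seqs = {}
    domain_positions = {}
    for pid, L in zip(proteins, lengths):
        k = int(rng.integers(1, 4))
        protein_pfams[pid] = sorted(rng.choice(pfams, size=k, replace=False))
        seqs[pid] = _random_seq(rng, _AA, int(L))
        # non-overlapping domain spans
        spans, cursor = [], 1
        for pf in protein_pfams[pid]:
            width = int(rng.integers(15, 40))
            if cursor + width > L:
                break
            spans.append((pf, cursor, cursor + width - 1))
            cursor += width + int(rng.integers(5, 20))
        domain_positions[pid] = spans

    # --- assemblies ---------------------------------------------------
    sym_pool = ["C1", "C1", "C2", "C3", "D2", "D3"]
    obl_pool = ["obligate", "moderate", "transient", "unknown"]
    rows = []
    for i, pid in enumerate(proteins):
        for j in range(int(rng.integers(1, 4))):
            sym = str(rng.choice(sym_pool))
            if sym == "C1":
                stoich = str(rng.choice(["A", "A2", "A2BC", "AB"]))
            else:
                stoich = str(rng.choice(["A2", "A4", "A6", "A2B2"]))
            rows.append(
                {
                    "group_id": f"GRP_{i:04d}_{j}",
                    "protein_id": pid,
                    "pfam_architecture": ";".join(protein_pfams[pid]),
                    "stoichiometry": stoich,
                    "symmetry": sym,
                    "obligate_class": str(rng.choice(obl_pool)),
                }
            )
    pd.DataFrame(rows).to_csv(out / "assemblies.tsv", sep="\t", index=False)

    # --- interfaces ---------------------------------------------------
    rows = []
    for _ in range(config.n_proteins):
        a, b = rng.choice(pfams, size=2, replace=False)
        redundant = bool(rng.random() < 0.4)
        arch = [a, b, a] if redundant else [a, b]
        def _positions():
            start = int(rng.integers(1, 40))
            pos, p = [], start
            for _k in range(int(rng.integers(3, 12))):
                pos.append(p)
                p += int(rng.integers(1, 7))
            return pos
        rows.append(
            {
                "domain_a": a,
                "domain_b": b,
                "architecture": ";".join(arch),
                "positions_a": ",".join(map(str, _positions())),
                "positions_b": ",".join(map(str, _positions())),
                "kind": str(rng.choice(["DDI", "DDI", "DMI"])),
                "max_symmetry": int(rng.integers(1, 7)),
            }
        )
    pd.DataFrame(rows).to_csv(out / "interfaces.tsv", sep="\t", index=False)

    # --- llps ---------------------------------------------------------
    rows = []
    for pid in proteins:
        if rng.random() < 0.5:
            k = int(rng.integers(1, 4))
            cond = sorted(rng.choice(condensates, size=k, replace=False))
            rows.append(
                {
                    "protein_id": pid,
                    "condensates": ";".join(cond),
                    "functional_type": str(
                        rng.choice(["client", "regulator", "scaffold"])
                    ),
                    "pfams": ";".join(protein_pfams[pid]),
                }
            )
    pd.DataFrame(rows).to_csv(out / "llps.tsv", sep="\t", index=False)

    # --- gopo.gaf -----------------------------------------------------
    qualifiers = ["part_of", "involved_in", "enables", "acts_upstream_of"]
    names = [
        "response to abiotic stimulus",
        "signal transduction",
        "transcription suppressor activity",
        "hormone response activator",
        "ribosome biogenesis",
        "cell communication",
    ]
    lines = ["!gaf-version: 2.1"]
    for g in genes:
        for _ in range(int(rng.integers(1, 6))):
            is_po = rng.random() < 0.3
            term = (
                f"PO:{int(rng.integers(1, 5000)):07d}"
                if is_po
                else f"GO:{int(rng.integers(1, 9000000)):07d}"
            )
            aspect = str(rng.choice(["A", "T"])) if is_po else str(rng.choice(list("PFC")))
            name = str(rng.choice(names))
            q = str(rng.choice(qualifiers))
            lines.append(
                "\t".join(
                    [
                        "LOGDB", g, g, q, term, "LOGDB:ref", "IEA", "",
                        aspect, name, "", "gene", "taxon:3702",
                        "20230101", "LOGDB", "", "",
                    ]
                )
            )
    (out / "gopo.gaf").write_text("\n".join(lines) + "\n")

    # --- tfs ----------------------------------------------------------
    motif_types = [f"M_{i:02d}" for i in range(max(4, config.n_tfs // 2))]
    rows = []
    for tf in tfs:
        k = int(rng.integers(1, 4))
        chosen = rng.choice(motif_types, size=k, replace=False)
        motifs = ";".join(
            f"{m}:{_random_seq(rng, _AMBIG, int(rng.integers(6, 12)))}" for m in chosen
        )
        rows.append(
            {
                "tf_id": tf,
                "family": str(rng.choice(["bZIP", "MYB", "B3", "HLH"])),
                "dbd_sequence": _random_seq(rng, _AA, int(rng.integers(40, 80))),
                "motifs": motifs,
            }
        )
    pd.DataFrame(rows).to_csv(out / "tfs.tsv", sep="\t", index=False)

    # --- ppi ----------------------------------------------------------
    rows = []
    for _ in range(config.n_proteins * 2):
        a, b = rng.choice(proteins, size=2, replace=False)
        rows.append({"protein_a": a, "protein_b": b})
    pd.DataFrame(rows).drop_duplicates().to_csv(out / "ppi.tsv", sep="\t", index=False)

    # --- genes.gff3 + sites.bed --------------------------------------
    chrom = "Chr1"
    gff = ["##gff-version 3"]
    cursor = 5000
    gene_spans = {}
    for g in genes:
        glen = int(rng.integers(1200, 3000))
        start, end = cursor, cursor + glen  # 0-based half-open internally
        strand = str(rng.choice(["+", "-"]))
        gene_spans[g] = (start, end)
        gff.append(
            f"{chrom}\tlogfeat\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={g}"
        )
        # two exons with an intron between; CDS inside exons
        e1_end = start + int(rng.integers(200, glen // 2))
        e2_start = e1_end + int(rng.integers(80, 300))
        for i, (es, ee) in enumerate(((start, e1_end), (e2_start, end)), 1):
            gff.append(
                f"{chrom}\tlogfeat\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                f"ID={g}.exon{i};Parent={g}"
            )
        cds_s, cds_e = start + 60, end - 60
        gff.append(
            f"{chrom}\tlogfeat\tCDS\t{cds_s + 1}\t{cds_e}\t.\t{strand}\t0\t"
            f"ID={g}.cds;Parent={g}"
        )
        cursor = end + int(rng.integers(4000, 8000))
    (out / "genes.gff3").write_text("\n".join(gff) + "\n")

    bed = []
    for _ in range(config.n_genes * 6):
        g = str(rng.choice(genes))
        gs, ge = gene_spans[g]
        pos = int(rng.integers(max(0, gs - 2500), ge + 2500))
        width = int(rng.integers(6, 20))
        tf = str(rng.choice(tfs))
        bed.append(f"{chrom}\t{pos}\t{pos + width}\t{tf}\t0\t+")
    (out / "sites.bed").write_text("\n".join(bed) + "\n")

    # --- proteins.fasta ----------------------------------------------
    fasta = []
    for pid in proteins:
        fasta.append(f">{pid} pfams={';'.join(protein_pfams[pid])}")
        s = seqs[pid]
        fasta.extend(s[i : i + 60] for i in range(0, len(s), 60))
    (out / "proteins.fasta").write_text("\n".join(fasta) + "\n")

    # --- domain positions (supporting table) -------------------------
    rows = [
        {"protein_id": pid, "pfam": pf, "start": s, "end": e}
        for pid, spans in domain_positions.items()
        for pf, s, e in spans
    ]
    pd.DataFrame(rows).to_csv(out / "domains.tsv", sep="\t", index=False)

    manifest = {"seed": config.seed, "files": {}}
    for name in BUNDLE_FILES + ("domains.tsv",):
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        manifest["files"][name] = digest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def inject_signal(
    spec: SignalSpec, n: int, seed: int, class_col: str = "target"
) -> FeatureTable:
    """Sample a labeled mixed-categorical table with planted dependence.

    The class is drawn first (uniform unless ``class_fractions`` is
    given); each informative feature's level is then drawn from a
    multinomial whose log-odds are shifted by ``effect * scale``
    toward the level linked to the class (level index = class index
    modulo n_levels).  By the exponential-family symmetry of the joint
    this gives the class, conditionally on the features, exactly those
    additive log-odds shifts.  Noise features are uniform and
    independent of everything.
    """
    rng = np.random.default_rng(seed)
    k, L = spec.n_classes, spec.n_levels
    if spec.class_fractions is not None:
        p = np.asarray(spec.class_fractions, dtype=float)
        if len(p) != k or not np.isclose(p.sum(), 1.0):
            raise ValueError("class_fractions must have n_classes entries summing to 1")
    else:
        p = np.full(k, 1.0 / k)
    classes = rng.choice(k, size=n, p=p)

    data = {class_col: [f"class_{c}" for c in classes]}
    shift = spec.effect * spec.scale
    for j in range(spec.n_informative):
        logits = np.zeros((n, L))
        linked = classes % L
        logits[np.arange(n), linked] += shift
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        cum = probs.cumsum(axis=1)
        u = rng.random(n)
        levels = (u[:, None] > cum).sum(axis=1)
        data[f"informative_{j}"] = [f"level_{l}" for l in levels]
    for j in range(spec.n_noise):
        levels = rng.integers(0, L, size=n)
        data[f"noise_{j}"] = [f"level_{l}" for l in levels]
    df = pd.DataFrame(data)
    prov = {c: "synthetic" for c in df.columns}
    return FeatureTable(df=df, class_col=class_col, provenance=prov)


def bundle_feature_table(bundle_dir) -> FeatureTable:
    """Assemble a per-protein mixed categorical table from a bundle.

    Demonstration of the module composition the pipeline consumes:
    the class is the oligomerization type (composition + assembly
    states, the coarse reading of the composite label — full labels
    fragment a miniature snapshot into near-singleton classes) derived
    from the protein's assembly clusters; the features join the
    condensate-annotation module (LLPS membership, functional type,
    condensate count) with assembly summaries (domain count, maximum
    symmetry order, cluster count), all direct-mapped to categories.
    """
    from .llps import read_llps_table
    from .oligomer import (
        clusters_from_frame,
        compose_oligomer_label,
        derive_protcad_features,
        read_assembly_table,
    )

    bundle_dir = Path(bundle_dir)
    assemblies = read_assembly_table(bundle_dir / "assemblies.tsv")
    llps_by_protein = {
        a.protein_id: a for a in read_llps_table(bundle_dir / "llps.tsv")
    }
    rows = []
    for pid, sub in assemblies.groupby("protein_id"):
        clusters = clusters_from_frame(sub)
        feats = derive_protcad_features(clusters)
        ann = llps_by_protein.get(pid)
        label = compose_oligomer_label(clusters)
        if label.label == "CMA":
            target = "CMA"
        else:
            target = "_".join(
                label.components["composition"] + label.components["states"]
            )
        rows.append(
            {
                "protein_id": pid,
                "target": target,
                "n_domains": str(len(sub.iloc[0]["pfam_architecture"].split(";"))),
                "n_clusters": str(int(feats["n_clusters"])),
                "max_symmetry_order": str(int(feats["max_symmetry_order"])),
                "has_llps": str(ann is not None),
                "functional_type": ann.functional_type if ann else "none",
                "n_condensates": str(len(ann.condensates)) if ann else "0",
            }
        )
    df = pd.DataFrame(rows).set_index("protein_id").reset_index(drop=True)
    prov = {c: "bundle" for c in df.columns}
    return FeatureTable(df=df, class_col="target", provenance=prov)
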