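"""TF-motif incidence marginals and interval overlap mapping."""

import numpy as np
import pytest

from logfeat.tfmap import (
    BindingSite,
    GeneModel,
    TFRecord,
    count_motif_types,
    map_sites_to_features,
    read_bed,
)


class TestMotifMarginals:
    def test_both_marginals(self):
        tfs = [
            TFRecord("TF_1", motifs={"M1": "ACGT", "M2": "GGNN"}),
            TFRecord("TF_2", motifs={"M1": "ACGT"}),
        ]
        got = count_motif_types(tfs)
        assert got["per_tf"] == {"TF_1": 2, "TF_2": 1}
        assert got["per_motif"] == {"M1": 2, "M2": 1}

    def test_empty_input(self):
        got = count_motif_types([])
        assert got == {"per_tf": {}, "per_motif": {}}

    def test_non_iupac_consensus_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            TFRecord("TF_1", motifs={"M1": "ACGU"})


def _gene(gene_id="G_1", start=1000, end=2000, strand="+", exons=None, cds=None):
    feats = []
    for s, e in exons or []:
        feats.append(("exon", s, e))
    for s, e in cds or []:
        feats.append(("CDS", s, e))
    return GeneModel(gene_id, "Chr1", start, end, strand, feats)


def _naive_overlap_counts(sites, models, up=2000, down=2000):
    """All-pairs O(n*m) oracle over the same flattened feature intervals."""
    counts = {}
    for m in models:
        mm = m.with_flanks_and_introns(up, down)
        for ftype, fs, fe in mm.features:
            for site in sites:
                if site.chrom != m.chrom:
                    continue
                if min(site.end, fe) - max(site.start, fs) >= 1:
                    key = (m.gene_id, ftype)
                    counts[key] = counts.get(key, 0) + 1
    return counts


class TestIntervalMapping:
    def test_site_inside_exon(self):
        models = [_gene(exons=[(1000, 2000)])]
        df, unmapped = map_sites_to_features([BindingSite("Chr1", 1100, 1110)], models)
        row = df.set_index(["gene_id", "feature"])["count"]
        assert row[("G_1", "exon")] == 1 and not unmapped

    def test_half_open_boundary(self):
        """A site ending exactly where a feature starts does not
        overlap it; position `end` belongs to the next interval only."""
        models = [_gene(start=0, end=300, exons=[(0, 200), (250, 300)])]
        # intron is [200, 250); site [195, 205) overlaps exon1 and intron
        df, _ = map_sites_to_features([BindingSite("Chr1", 195, 205)], models)
        idx = df.set_index(["gene_id", "feature"])["count"]
        assert idx[("G_1", "exon")] == 1
        assert idx[("G_1", "intron")] == 1
        # site [190, 200) touches the exon only
        df2, _ = map_sites_to_features([BindingSite("Chr1", 190, 200)], models)
        idx2 = df2.set_index(["gene_id", "feature"])["count"]
        assert idx2[("G_1", "exon")] == 1
        assert ("G_1", "intron") not in idx2.index

    def test_unknown_chromosome_reported_unmapped(self):
        models = [_gene(exons=[(1000, 2000)])]
        _, unmapped = map_sites_to_features([BindingSite("ChrX", 10, 20)], models)
        assert len(unmapped) == 1

    def test_strand_aware_flanks(self):
        plus = _gene(start=5000, end=6000, strand="+")
        minus = _gene("G_2", start=5000, end=6000, strand="-")
        site = BindingSite("Chr1", 4500, 4510)  # left of both genes
        df_p, _ = map_sites_to_features([site], [plus])
        df_m, _ = map_sites_to_features([site], [minus])
        assert df_p.iloc[0]["feature"] == "upstream"
        assert df_m.iloc[0]["feature"] == "downstream"

    def test_oracle_equivalence_on_random_fixtures(self):
        """intervaltree engine equals the naive all-pairs overlap scan
        on randomized site/model sets."""
        rng = np.random.default_rng(77)
        models = []
        cursor = 1000
        for i in range(30):
            glen = int(rng.integers(500, 2000))
            e1 = cursor + int(rng.integers(100, glen // 2))
            e2 = e1 + int(rng.integers(50, 300))
            end = max(e2 + 100, cursor + glen)
            models.append(
                _gene(
                    f"G_{i}", cursor, end,
                    strand=str(rng.choice(["+", "-"])),
                    exons=[(cursor, e1), (e2, end)],
                    cds=[(cursor + 30, end - 30)],
                )
            )
            cursor = end + int(rng.integers(100, 3000))
        sites = []
        for _ in range(1000):
            pos = int(rng.integers(0, cursor + 3000))
            sites.append(BindingSite("Chr1", pos, pos + int(rng.integers(1, 30))))
        df, _ = map_sites_to_features(sites, models)
        got = {
            (r.gene_id, r.feature): int(r.count) for r in df.itertuples(index=False)
        }
        assert got == _naive_overlap_counts(sites, models)

    def test_counts_additive_over_site_partitions(self):
        rng = np.random.default_rng(8)
        models = [_gene(exons=[(1000, 1500), (1700, 2000)])]
        sites = [
            BindingSite("Chr1", int(p), int(p) + 10)
            for p in rng.integers(0, 4000, size=60)
        ]
        whole, _ = map_sites_to_features(sites, models)
        a, _ = map_sites_to_features(sites[:30], models)
        b, _ = map_sites_to_features(sites[30:], models)
        merged = (
            a.set_index(["gene_id", "feature"])["count"]
            .add(b.set_index(["gene_id", "feature"])["count"], fill_value=0)
            .astype(int)
        )
        assert merged.equals(whole.set_index(["gene_id", "feature"])["count"])

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            map_sites_to_features([], [], upstream_bp=0)

    def test_utr_inferred_from_exon_minus_cds(self):
        models = [_gene(start=0, end=1000, exons=[(0, 1000)], cds=[(100, 900)])]
        df, _ = map_sites_to_features([BindingSite("Chr1", 10, 20)], models)
        feats = set(df["feature"])
        assert "UTR" in feats  # [0,100) is untranslated

    def test_invalid_site_interval_rejected(self):
        with pytest.raises(ValueError, match="invalid site interval"):
            BindingSite("Chr1", 10, 10)


def test_read_bed_skips_headers(tmp_path):
    p = tmp_path / "sites.bed"
    p.write_text("track name=x\nChr1\t10\t20\tTF_1\t0\t+\n#c\nChr2\t5\t9\n")
    sites = read_bed(p)
    assert len(sites) == 2
    assert sites[0].tf_id == "TF_1" and sites[0].strand == "+"
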