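"""Interface fragments, NR/redundant cluster ANOVA, region tiling."""

import numpy as np
import pytest
from scipy import stats

from logfeat.ddi import (
    COMPARISON_VALUE_NAMES,
    InterfaceEntry,
    clan_pool,
    compare_interface_clusters,
    is_redundant_architecture,
    map_features_to_regions,
    split_fragments,
)


def _brute_force_fragments(positions, max_gap=3):
    """Independent gap scan: start a new fragment whenever more than
    max_gap residues are missing."""
    frags = []
    for p in positions:
        if frags and p - frags[-1][-1] - 1 <= max_gap:
            frags[-1] = frags[-1] + [p]
        else:
            frags.append([p])
    return [tuple(f) for f in frags]


class TestSplitFragments:
    def test_gap_of_three_does_not_split(self):
        frags = split_fragments([3, 4, 5, 9])
        assert [f.positions for f in frags] == [(3, 4, 5, 9)]

    def test_gap_of_four_splits(self):
        frags = split_fragments([3, 4, 5, 10])
        assert [f.positions for f in frags] == [(3, 4, 5), (10,)]

    def test_singleton(self):
        frags = split_fragments([7])
        assert len(frags) == 1 and frags[0].length == 1

    def test_unsorted_or_duplicate_errors(self):
        with pytest.raises(ValueError):
            split_fragments([5, 3])
        with pytest.raises(ValueError):
            split_fragments([3, 3])

    def test_oracle_equivalence_and_concatenation(self):
        """Fragments equal the brute-force scan, and their positions
        concatenate back to the input, on random position lists."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(1, 30))
            positions = sorted(
                rng.choice(np.arange(1, 120), size=n, replace=False).tolist()
            )
            frags = split_fragments(positions)
            assert [f.positions for f in frags] == _brute_force_fragments(positions)
            flat = [p for f in frags for p in f.positions]
            assert flat == positions

    def test_fragment_count_monotone_in_max_gap(self):
        rng = np.random.default_rng(6)
        positions = sorted(rng.choice(np.arange(1, 200), size=40, replace=False).tolist())
        counts = [len(split_fragments(positions, g)) for g in range(0, 10)]
        assert counts == sorted(counts, reverse=True)


def _entry(arch, pos_a, pos_b, kind="DDI", max_symmetry=1.0):
    return InterfaceEntry(
        domain_pair=frozenset(("PF_a", "PF_b")),
        architecture=tuple(arch),
        side_positions=(tuple(pos_a), tuple(pos_b)),
        kind=kind,
        max_symmetry=max_symmetry,
    )


def _manual_oneway_f(a, b):
    """Textbook one-way ANOVA F from sums of squares (independent of
    scipy.f_oneway)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    grand = np.concatenate([a, b]).mean()
    ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, len(a) + len(b) - 2
    f = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(f, df1, df2)
    return f, p


class TestClusterComparison:
    def test_redundancy_detection(self):
        assert not is_redundant_architecture(("PF_a", "PF_b"))
        assert is_redundant_architecture(("PF_a", "PF_b", "PF_a"))

    def test_thirteen_values(self):
        assert len(COMPARISON_VALUE_NAMES) == 13

    def test_identical_clusters_give_null_anova(self):
        """NR and redundant clusters with the same fragment statistics:
        no between-cluster signal, F ~ 0 and p ~ 1."""
        nr = [_entry(["PF_a", "PF_b"], [1, 2, 3 + i], [10, 11]) for i in range(5)]
        red = [_entry(["PF_a", "PF_b", "PF_a"], [1, 2, 3 + i], [10, 11]) for i in range(5)]
        cmp_ = compare_interface_clusters(nr + red)
        an = cmp_.anova.dropna()
        assert (an["F"] < 1e-9).all()
        assert (an["p"] > 1 - 1e-9).all()

    def test_separated_clusters_detected(self):
        """Interface sizes drawn from well-separated regimes give a
        strongly significant residue-count comparison."""
        rng = np.random.default_rng(42)
        nr = [
            _entry(["PF_a", "PF_b"], sorted(rng.choice(200, 5, replace=False) + 1), [1, 2])
            for _ in range(30)
        ]
        red = [
            _entry(["PF_a", "PF_b", "PF_a"],
                   sorted(rng.choice(200, 40, replace=False) + 1), [1, 2])
            for _ in range(30)
        ]
        cmp_ = compare_interface_clusters(nr + red)
        assert cmp_.anova.loc["n_interface_residues", "p"] < 1e-3

    def test_single_entry_marks_anova_not_applicable(self):
        cmp_ = compare_interface_clusters([_entry(["PF_a", "PF_b"], [1, 2], [5])])
        assert cmp_.nr_size == 1 and cmp_.redundant_size == 0
        assert cmp_.anova["F"].isna().all()
        assert not cmp_.anova_applicable

    def test_f_matches_manual_formula_on_random_pairs(self):
        """Implementation F/p agree with the textbook sums-of-squares
        formula to 1e-9 on random cluster pairs."""
        rng = np.random.default_rng(1234)
        for _ in range(100):
            n1, n2 = rng.integers(3, 15, size=2)
            nr = [
                _entry(["PF_a", "PF_b"],
                       sorted(rng.choice(300, int(rng.integers(2, 20)), replace=False) + 1),
                       [1, 2])
                for _ in range(n1)
            ]
            red = [
                _entry(["PF_a", "PF_b", "PF_a"],
                       sorted(rng.choice(300, int(rng.integers(2, 20)), replace=False) + 1),
                       [1, 2])
                for _ in range(n2)
            ]
            cmp_ = compare_interface_clusters(nr + red)
            a = [e.side_positions[0].__len__() + len(e.side_positions[1]) for e in nr]
            b = [len(e.side_positions[0]) + len(e.side_positions[1]) for e in red]
            if np.allclose(np.concatenate([a, b]), a[0]):
                continue
            f_exp, p_exp = _manual_oneway_f(a, b)
            assert cmp_.anova.loc["n_interface_residues", "F"] == pytest.approx(
                f_exp, abs=1e-9
            )
            assert cmp_.anova.loc["n_interface_residues", "p"] == pytest.approx(
                p_exp, abs=1e-9
            )

    def test_mixed_pairs_rejected(self):
        other = InterfaceEntry(
            domain_pair=frozenset(("PF_x", "PF_y")),
            architecture=("PF_x", "PF_y"),
            side_positions=((1,), (2,)),
        )
        with pytest.raises(ValueError, match="multiple domain pairs"):
            compare_interface_clusters([_entry(["PF_a", "PF_b"], [1], [2]), other])


class TestRegionMapping:
    def test_interdomain_complement(self):
        regions = map_features_to_regions(
            "PR_1", 100, [("PF_a", 10, 40), ("PF_b", 60, 90)]
        )
        spans = [(r.kind, r.span) for r in regions]
        assert spans == [
            ("interdomain", (1, 9)),
            ("domain", (10, 40)),
            ("interdomain", (41, 59)),
            ("domain", (60, 90)),
            ("interdomain", (91, 100)),
        ]

    def test_tiling_partitions_protein_exactly(self):
        """Domain + interdomain spans tile [1, L] with no gap/overlap on
        random domain layouts."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            L = int(rng.integers(50, 400))
            spans, cursor = [], 1
            while cursor < L - 20 and len(spans) < 5:
                s = cursor + int(rng.integers(0, 10))
                e = min(L, s + int(rng.integers(5, 40)))
                spans.append((f"PF_{len(spans)}", s, e))
                cursor = e + 1 + int(rng.integers(0, 15))
            regions = map_features_to_regions("p", L, spans)
            covered = []
            for r in regions:
                covered.extend(range(r.span[0], r.span[1] + 1))
            assert covered == list(range(1, L + 1))

    @pytest.mark.parametrize("pos,expected_kind,expected_span", [
        (25, "domain", (10, 40)),
        (50, "interdomain", (41, 59)),
    ])
    def test_positional_feature_containment(self, pos, expected_kind, expected_span):
        regions = map_features_to_regions(
            "PR_1", 100, [("PF_a", 10, 40), ("PF_b", 60, 90)],
            positional_features=[("phospho", pos)],
        )
        hit = [r for r in regions if r.positional_features]
        assert len(hit) == 1
        assert hit[0].kind == expected_kind and hit[0].span == expected_span

    def test_position_beyond_length_errors(self):
        with pytest.raises(ValueError, match="beyond protein length"):
            map_features_to_regions(
                "PR_1", 100, [("PF_a", 10, 40)], positional_features=[("p", 150)]
            )

    def test_overlapping_domains_keep_longer(self):
        regions = map_features_to_regions(
            "PR_1", 100, [("PF_short", 10, 20), ("PF_long", 15, 60)]
        )
        pfams = [r.pfam for r in regions if r.kind == "domain"]
        assert pfams == ["PF_long"]

    def test_protein_level_features_on_every_region(self):
        regions = map_features_to_regions(
            "PR_1", 50, [("PF_a", 10, 30)],
            protein_level_features={"gravy": -0.3, "location": "nucl"},
        )
        assert all(r.protein_level_features["location"] == "nucl" for r in regions)


class TestClanPool:
    EDGES = [("PR_1", "PR_2"), ("PR_3", "PR_1"), ("PR_4", "PR_5")]
    PFAMS = {"PR_2": ["PF_a", "PF_b"], "PR_3": ["PF_c"], "PR_5": ["PF_d"]}
    CLANS = {"PF_a": "CL_x", "PF_b": "CL_x"}

    def test_union_of_partner_clans(self):
        pool = clan_pool("PR_1", self.EDGES, self.PFAMS, self.CLANS)
        assert pool == {"CL_x", "PF_c"}  # PF_c passes through unmapped

    def test_absent_protein_has_empty_pool(self):
        assert clan_pool("PR_99", self.EDGES, self.PFAMS, self.CLANS) == set()
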