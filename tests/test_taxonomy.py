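"""Windowed-LCA taxonomy: hit filtering, depth caps, consensus voting."""

import numpy as np
import pandas as pd
import pytest

from amplitax.cluster import AbundanceMatrix
from amplitax.taxonomy import (
    RANKS, UNASSIGNED, AlignmentHit, LcaSpec, TaxonomyPath, aggregate_taxa,
    classify_all, depth_cap, filter_hits, lca_assign, rank_vote,
    read_blast_table, read_reference_taxonomy,
)

LINEAGE_A = TaxonomyPath(["Bacteria", "Bacteroidetes", "Bacteroidia",
                          "Bacteroidales", "Bacteroidaceae", "Bacteroides",
                          "Bacteroides fragilis"])
LINEAGE_B = TaxonomyPath(["Bacteria", "Bacteroidetes", "Bacteroidia",
                          "Bacteroidales", "Prevotellaceae", "Prevotella",
                          "Prevotella copri"])
LINEAGE_C = TaxonomyPath(["Bacteria", "Firmicutes", "Clostridia",
                          "Clostridiales", "Lachnospiraceae", "Blautia",
                          "Blautia obeum"])


def hit(subject, pident, query="q1", bitscore=0.0):
    return AlignmentHit(query, subject, pident, 250, bitscore)


class TestTaxonomyPath:
    def test_truncation_invariant_enforced(self):
        path = TaxonomyPath(["Bacteria", "?", "Clostridia"])
        assert path == ("Bacteria",) + (UNASSIGNED,) * 6
        assert path.depth == 1

    def test_greengenes_prefixes_stripped(self):
        path = TaxonomyPath.from_lineage_string(
            "k__Bacteria; p__Firmicutes; c__Clostridia; o__; f__; g__; s__")
        assert path[:3] == ("Bacteria", "Firmicutes", "Clostridia")
        assert path.depth == 3

    def test_lineage_string_round_trip(self):
        assert TaxonomyPath.from_lineage_string(
            LINEAGE_A.to_lineage_string()) == LINEAGE_A


class TestFilterHits:
    def test_window_boundary(self):
        hits = [hit("best", 99.0), hit("in", 97.6), hit("out", 97.4)]
        kept = {h.subject_id for h in filter_hits(hits, LcaSpec())}
        assert kept == {"best", "in"}

    def test_hit_cap_after_window(self):
        hits = [hit(f"s{i:03d}", 98.0) for i in range(250)]
        kept = filter_hits(hits, LcaSpec())
        assert len(kept) == 200
        # deterministic tie-break: subject id ascending
        assert [h.subject_id for h in kept[:2]] == ["s000", "s001"]

    def test_single_hit_retained(self):
        assert len(filter_hits([hit("only", 91.0)], LcaSpec())) == 1

    def test_multiple_hsps_collapse_to_one_vote(self):
        hits = [hit("dup", 99.0), hit("dup", 98.2), hit("other", 98.5)]
        kept = filter_hits(hits, LcaSpec())
        assert sorted((h.subject_id, h.percent_identity) for h in kept) \
            == [("dup", 99.0), ("other", 98.5)]

    def test_empty_and_mixed_queries(self):
        assert filter_hits([], LcaSpec()) == []
        with pytest.raises(ValueError):
            filter_hits([hit("a", 99, query="q1"), hit("b", 99, query="q2")],
                        LcaSpec())


class TestDepthCap:
    @pytest.mark.parametrize("identity,rank", [
        (97.0, "species"), (96.0, "genus"), (95.0, "genus"),
        (94.0, "family"), (93.0, "family"), (92.0, "order"),
        (90.0, "class"), (80.0, "phylum"), (70.0, "domain"),
    ])
    def test_default_caps(self, identity, rank):
        assert depth_cap(identity, LcaSpec().depth_caps) == rank

    def test_monotone_in_identity(self):
        caps = LcaSpec().depth_caps
        depths = [RANKS.index(depth_cap(x, caps))
                  for x in np.arange(60, 100.5, 0.5)]
        assert depths == sorted(depths)

    def test_printed_caps_variant_available(self):
        caps = LcaSpec.printed_caps().depth_caps
        assert caps["class"] == 91.0 and caps["order"] == 88.0


class TestRankVote:
    def tax(self, n_a, n_b, rank="genus"):
        taxonomy = {}
        hits = []
        for i in range(n_a):
            taxonomy[f"a{i}"] = LINEAGE_A
            hits.append(hit(f"a{i}", 99.0))
        for i in range(n_b):
            taxonomy[f"b{i}"] = LINEAGE_B
            hits.append(hit(f"b{i}", 99.0))
        return hits, taxonomy

    def test_ninety_percent_is_not_enough(self):
        """The consensus is strict: 9 of 10 is not > 90%."""
        hits, taxonomy = self.tax(9, 1)
        name, _ = rank_vote(hits, taxonomy, "genus", 0.9)
        assert name is None

    def test_unanimous_vote_passes(self):
        hits, taxonomy = self.tax(10, 0)
        name, _ = rank_vote(hits, taxonomy, "genus", 0.9)
        assert name == "Bacteroides"

    def test_single_annotated_reference_rule(self):
        """References without species annotation abstain, so one
        species-named reference among unannotated ones assigns it."""
        partial = TaxonomyPath(list(LINEAGE_A[:6]))  # species unassigned
        taxonomy = {"named": LINEAGE_A,
                    **{f"u{i}": partial for i in range(4)}}
        hits = [hit(s, 99.0) for s in taxonomy]
        name, tally = rank_vote(hits, taxonomy, "species", 0.9)
        assert name == "Bacteroides fragilis"
        assert tally == {"Bacteroides fragilis": 1}

    def test_zero_voters_gives_none(self):
        partial = TaxonomyPath(["Bacteria"])
        taxonomy = {"u1": partial, "u2": partial}
        name, _ = rank_vote([hit("u1", 99), hit("u2", 99)],
                            taxonomy, "genus", 0.9)
        assert name is None

    def test_missing_subject_errors_with_id(self):
        with pytest.raises(KeyError, match="mystery"):
            rank_vote([hit("mystery", 99)], {}, "genus", 0.9)


class TestLcaAssign:
    def test_unanimous_high_identity_full_path(self):
        taxonomy = {f"s{i}": LINEAGE_A for i in range(5)}
        hits = [hit(f"s{i}", 99.0) for i in range(5)]
        assert lca_assign(hits, taxonomy) == LINEAGE_A

    def test_96_percent_truncates_after_genus(self):
        """A 96%-identity best hit is trusted to genus but not species."""
        taxonomy = {f"s{i}": LINEAGE_A for i in range(5)}
        hits = [hit(f"s{i}", 96.0) for i in range(5)]
        path = lca_assign(hits, taxonomy)
        assert path.depth == 6
        assert path.name_at("genus") == "Bacteroides"
        assert path.name_at("species") == UNASSIGNED

    def test_split_vote_stops_at_domain(self):
        taxonomy = {"a": LINEAGE_A, "c": LINEAGE_C}
        hits = [hit("a", 99.0), hit("c", 99.0)]
        path = lca_assign(hits, taxonomy)
        assert path == ("Bacteria",) + (UNASSIGNED,) * 6

    def test_empty_hits_fully_unassigned(self):
        assert lca_assign([], {}) == TaxonomyPath.unassigned()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        taxonomy = {"a0": LINEAGE_A, "a1": LINEAGE_A, "b0": LINEAGE_B}
        hits = [hit("a0", 99.0), hit("a1", 98.7), hit("b0", 98.2)]
        baseline = lca_assign(hits, taxonomy)
        for _ in range(10):
            rng.shuffle(hits)
            assert lca_assign(hits, taxonomy) == baseline


def oracle_lca(hits, taxonomy, spec):
    """Independent recount: explicit window arithmetic and per-rank
    exhaustive tallies over the retained references."""
    from collections import Counter
    best_by_subject = {}
    for h in hits:
        prev = best_by_subject.get(h.subject_id)
        if prev is None or (h.percent_identity, h.bitscore) > (
                prev.percent_identity, prev.bitscore):
            best_by_subject[h.subject_id] = h
    pool = list(best_by_subject.values())
    if not pool:
        return tuple([UNASSIGNED] * 7)
    top = max(h.percent_identity for h in pool)
    pool = [h for h in pool if top - h.percent_identity <= spec.identity_window]
    pool = sorted(pool, key=lambda h: (-h.percent_identity, -h.bitscore,
                                       h.subject_id))[:spec.max_hits]
    allowed = 0  # number of assignable ranks counting domain
    for depth, rank in enumerate(RANKS):
        cap = spec.depth_caps.get(rank)
        if cap is None or cap <= top:
            allowed = depth + 1
    result = []
    for rank_i in range(7):
        if rank_i >= allowed:
            break
        counter = Counter()
        for h in pool:
            name = taxonomy[h.subject_id][rank_i]
            if name != UNASSIGNED:
                counter[name] += 1
        total = sum(counter.values())
        if total == 0:
            break
        name, cnt = max(counter.items(), key=lambda kv: (kv[1], kv[0]))
        if cnt <= spec.consensus_fraction * total:
            break
        result.append(name)
    return tuple(result + [UNASSIGNED] * (7 - len(result)))


def random_hit_tables(n_tables, seed, max_identity=100.0):
    rng = np.random.default_rng(seed)
    lineages = [LINEAGE_A, LINEAGE_B, LINEAGE_C,
                TaxonomyPath(list(LINEAGE_A[:4])),
                TaxonomyPath(list(LINEAGE_C[:6])),
                TaxonomyPath(["Bacteria"])]
    for _ in range(n_tables):
        n_subjects = int(rng.integers(1, 12))
        taxonomy = {f"s{j}": lineages[rng.integers(len(lineages))]
                    for j in range(n_subjects)}
        n_hits = int(rng.integers(1, 21))
        hits = [
            AlignmentHit("q", f"s{int(rng.integers(n_subjects))}",
                         float(rng.uniform(75, max_identity)),
                         250, float(np.round(rng.uniform(100, 500), 1)))
            for _ in range(n_hits)
        ]
        yield hits, taxonomy


class TestOracleEquivalence:
    def test_matches_exhaustive_recount_on_random_tables(self):
        spec = LcaSpec()
        for hits, taxonomy in random_hit_tables(500, seed=13):
            assert tuple(lca_assign(hits, taxonomy, spec)) \
                == oracle_lca(hits, taxonomy, spec)


class TestClassifyAll:
    def test_composition_and_missing_seeds(self):
        taxonomy = {f"s{i}": LINEAGE_A for i in range(5)}
        table = {"otu1": [hit(f"s{i}", 99.0, query="otu1") for i in range(5)],
                 "otu2": [hit(f"s{i}", 96.0, query="otu2") for i in range(5)]}
        out = classify_all(["otu1", "otu2", "otu3"], table, taxonomy)
        assert out["otu1"] == LINEAGE_A
        assert out["otu2"].depth == 6
        assert out["otu3"] == TaxonomyPath.unassigned()

    def test_duplicate_hit_lines_idempotent(self):
        taxonomy = {"s0": LINEAGE_A}
        hits = [hit("s0", 99.0, query="otu1")] * 3
        out = classify_all(["otu1"], {"otu1": hits}, taxonomy)
        assert out["otu1"] == LINEAGE_A

    def test_unknown_query_warned_and_skipped(self):
        taxonomy = {"s0": LINEAGE_A}
        with pytest.warns(UserWarning, match="ghost"):
            out = classify_all(["otu1"], {"ghost": [hit("s0", 99, query="ghost")]},
                               taxonomy)
        assert out == {"otu1": TaxonomyPath.unassigned()}


class TestBlastTable:
    def test_outfmt6_parse(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "otu1\tref1\t99.20\t250\t2\t0\t1\t250\t1\t250\t1e-120\t443.0\n"
            "otu1\tref2\t97.60\t250\t6\t0\t1\t250\t1\t250\t1e-110\t421.0\n"
            "otu2\tref1\t88.00\t240\t30\t2\t1\t240\t5\t244\t1e-60\t200.0\n")
        table = read_blast_table(p)
        assert set(table) == {"otu1", "otu2"}
        assert table["otu1"][0].percent_identity == 99.2
        assert table["otu2"][0].bitscore == 200.0

    def test_reference_taxonomy_reader(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("ref1\tk__Bacteria;p__Firmicutes;c__;o__;f__;g__;s__\n"
                     "ref2\tBacteria;Bacteroidetes\n")
        taxonomy = read_reference_taxonomy(p)
        assert taxonomy["ref1"].depth == 2
        assert taxonomy["ref2"][1] == "Bacteroidetes"
        dup = tmp_path / "dup.tsv"
        dup.write_text("ref1\tBacteria\nref1\tBacteria\n")
        with pytest.raises(ValueError, match="ref1"):
            read_reference_taxonomy(dup)


class TestAggregate:
    @pytest.fixture
    def matrix(self):
        return AbundanceMatrix(["o1", "o2", "o3"], ["s1", "s2"],
                               np.array([[5, 1], [2, 2], [0, 7]]))

    def test_same_genus_rows_sum(self, matrix):
        assignments = {"o1": LINEAGE_A, "o2": LINEAGE_A, "o3": LINEAGE_C}
        out = aggregate_taxa(matrix, assignments, "genus")
        assert out.loc["Bacteroides"].tolist() == [7, 3]
        assert out.loc["Blautia"].tolist() == [0, 7]

    def test_unassigned_pooled(self, matrix):
        assignments = {"o1": LINEAGE_A, "o2": TaxonomyPath(list(LINEAGE_A[:5])),
                       "o3": LINEAGE_C}
        out = aggregate_taxa(matrix, assignments, "genus")
        assert out.loc["unassigned"].tolist() == [2, 2]

    def test_totals_preserved_at_every_rank(self, matrix):
        assignments = {"o1": LINEAGE_A, "o2": LINEAGE_B,
                       "o3": TaxonomyPath.unassigned()}
        for rank in RANKS:
            out = aggregate_taxa(matrix, assignments, rank)
            assert int(out.values.sum()) == matrix.total()
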