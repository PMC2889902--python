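"""Annotation joins: cutoffs, best-hit ties, Venn algebra, slim rollup, id routes."""

import itertools

import pandas as pd
import pytest

from teleoarray.annotation import (
    assign_annotation,
    best_hits,
    map_to_model_ids,
    read_blast_tabular,
    rollup_go_slim,
    slim_class_counts,
    unique_model_ids,
    venn_counts,
)


def hit(q, s, evalue, bit=100.0, db="nr", sstart=1, send=100, qstart=1, qend=100):
    return {
        "qseqid": q, "sseqid": s, "pident": 95.0, "length": 100, "mismatch": 2,
        "gapopen": 0, "qstart": qstart, "qend": qend, "sstart": sstart,
        "send": send, "evalue": evalue, "bitscore": bit, "db": db,
    }


def frame(rows):
    from teleoarray.annotation import add_strand_sign

    return add_strand_sign(pd.DataFrame(rows))


class TestBlastReader:
    def test_roundtrip_with_strand(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\ts1\t98.5\t100\t1\t0\t1\t100\t200\t101\t1e-30\t180\n"
            "q2\ts2\t90.0\t80\t5\t0\t1\t80\t50\t129\t1e-10\t90\n"
        )
        hits = read_blast_tabular(str(path), db="nt")
        assert list(hits["strand_sign"]) == [-1, 1]
        assert (hits["db"] == "nt").all()

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\ts1\tnot-a-number\n")
        with pytest.raises(ValueError, match="bad.tsv:1"):
            read_blast_tabular(str(path))

    def test_frame_column_overrides_coordinates(self, tmp_path):
        path = tmp_path / "framed.tsv"
        path.write_text("q1\ts1\t98.5\t100\t1\t0\t1\t100\t1\t100\t1e-30\t180\t-2\n")
        hits = read_blast_tabular(str(path))
        assert list(hits["strand_sign"]) == [-1]


class TestAssignAnnotation:
    def test_protein_priority_over_nucleotide(self):
        hits = frame([
            hit("q1", "P1", 1e-5, db="SwissProt"),
            hit("q1", "N1", 1e-20, db="nt"),
        ])
        table = assign_annotation(hits, ["q1"])
        assert table.loc["q1", "status"] == "protein-annotated"
        assert table.loc["q1", "best_protein_hit"] == "P1"

    def test_nucleotide_cutoff_is_strict(self):
        table = assign_annotation(frame([hit("q1", "N1", 1e-4, db="nt")]), ["q1"])
        assert table.loc["q1", "status"] == "unannotated"
        # just under the cutoff passes
        table = assign_annotation(frame([hit("q1", "N1", 9e-6, db="nt")]), ["q1"])
        assert table.loc["q1", "status"] == "nucleotide-only"

    def test_statuses_partition_the_catalog(self):
        hits = frame([
            hit("q1", "P1", 1e-5, db="nr"),
            hit("q2", "N1", 1e-9, db="nt"),
        ])
        table = assign_annotation(hits, ["q1", "q2", "q3"])
        assert table["status"].value_counts().sum() == 3
        assert set(table["status"]) == {
            "protein-annotated", "nucleotide-only", "unannotated",
        }

    def test_threshold_monotonicity(self):
        hits = frame([hit(f"q{i}", "P", 10.0 ** -i, db="nr") for i in range(1, 9)])
        ids = [f"q{i}" for i in range(1, 9)]
        loose = assign_annotation(hits, ids, protein_cutoff=1e-3)
        strict = assign_annotation(hits, ids, protein_cutoff=1e-6)
        n = lambda t: (t["status"] == "protein-annotated").sum()
        assert n(strict) <= n(loose)

    def test_best_hit_tie_break_deterministic_under_row_order(self):
        rows = [
            hit("q1", "B", 1e-10, bit=200.0, db="nr"),
            hit("q1", "A", 1e-10, bit=200.0, db="nr"),
            hit("q1", "C", 1e-10, bit=300.0, db="nr"),
        ]
        for perm in itertools.permutations(rows):
            best = best_hits(frame(list(perm)))
            assert best.iloc[0]["sseqid"] == "C"  # max bit score wins
        # equal e-value and bit score: lexicographic subject
        tied = [hit("q1", "B", 1e-10, db="nr"), hit("q1", "A", 1e-10, db="nr")]
        for perm in itertools.permutations(tied):
            assert best_hits(frame(list(perm))).iloc[0]["sseqid"] == "A"


def test_venn_counts_match_exhaustive_set_algebra():
    dbs = ("nr", "SwissProt", "TrEMBL")
    rows = [
        hit("q1", "s", 1e-9, db="nr"),
        hit("q2", "s", 1e-9, db="nr"),
        hit("q2", "s", 1e-9, db="SwissProt"),
        hit("q3", "s", 1e-2, db="TrEMBL"),  # fails the 1e-3 cutoff
    ]
    counts = venn_counts(frame(rows), dbs)
    membership = {"q1": {"nr"}, "q2": {"nr", "SwissProt"}}
    for r in range(1, 4):
        for combo in itertools.combinations(dbs, r):
            region = frozenset(combo)
            expected = sum(1 for m in membership.values() if m == region)
            assert counts[region] == expected


class TestGoSlim:
    slim = pd.DataFrame(
        {
            "term": ["GO:1", "GO:2", "GO:3", "GO:3"],
            "slim": ["S1", "S1", "S2", "S1"],
            "namespace": ["BP", "BP", "MF", "BP"],
        }
    )

    def test_empty_annotations_give_zero_classes(self):
        table, unmapped = rollup_go_slim(
            pd.DataFrame(columns=["transcript_id", "term"]), self.slim
        )
        assert table.empty and unmapped == []
        assert slim_class_counts(table) == {}

    def test_shared_ancestor_counts_once(self):
        annotations = pd.DataFrame(
            {"transcript_id": ["t1", "t2"], "term": ["GO:1", "GO:2"]}
        )
        table, unmapped = rollup_go_slim(annotations, self.slim)
        assert unmapped == []
        bp = table[table["namespace"] == "BP"]
        assert len(bp) == 1 and bp.iloc[0]["slim"] == "S1"
        assert bp.iloc[0]["n_transcripts"] == 2 and bp.iloc[0]["n_terms"] == 2

    def test_toy_map_matches_exhaustive_traversal(self):
        annotations = pd.DataFrame(
            {
                "transcript_id": ["t1", "t1", "t2", "t3"],
                "term": ["GO:1", "GO:3", "GO:3", "GO:9"],
            }
        )
        table, unmapped = rollup_go_slim(annotations, self.slim)
        assert unmapped == ["GO:9"]
        # brute force: expand each (transcript, term) to its slim rows
        expected = {}
        raw = {"GO:1": [("S1", "BP")], "GO:3": [("S2", "MF"), ("S1", "BP")]}
        for tid, term in zip(annotations["transcript_id"], annotations["term"]):
            for s, ns in raw.get(term, []):
                expected.setdefault((ns, s), set()).add(tid)
        for (ns, s), tids in expected.items():
            row = table[(table["namespace"] == ns) & (table["slim"] == s)]
            assert row.iloc[0]["n_transcripts"] == len(tids)
        assert slim_class_counts(table) == {"BP": 1, "MF": 1}


class TestIdRoutes:
    def test_indirect_route_composes_best_hits(self):
        to_ga = frame([hit("q1", "ga1", 1e-30)])
        ga_to_hs = frame([hit("ga1", "h9", 1e-40)])
        mapping = map_to_model_ids(
            "via-stickleback-human", to_intermediate=to_ga,
            intermediate_to_target=ga_to_hs,
        )
        assert mapping.to_dict("records") == [
            {"transcript_id": "q1", "route": "via-stickleback-human", "model_id": "h9"}
        ]

    def test_raw_vs_unique_counts(self):
        direct = frame([hit("q1", "h1", 1e-30), hit("q2", "h1", 1e-25)])
        mapping = map_to_model_ids("direct-human", direct_hits=direct)
        assert unique_model_ids(mapping) == (2, 1)

    def test_all_routes_match_brute_force_joins(self):
        to_ga = frame([
            hit("q1", "ga1", 1e-30), hit("q2", "ga2", 1e-20),
            hit("q2", "ga9", 1e-10),  # worse hit, must lose
            hit("q3", "ga3", 1e-15),
        ])
        ga_to_target = frame([hit("ga1", "m1", 1e-50), hit("ga2", "m2", 1e-9)])
        direct = frame([hit("q1", "m7", 1e-12), hit("q4", "m8", 1e-22)])
        # brute-force compose
        best_first = {"q1": "ga1", "q2": "ga2", "q3": "ga3"}
        best_second = {"ga1": "m1", "ga2": "m2"}
        expected = {
            q: best_second[ga] for q, ga in best_first.items() if ga in best_second
        }
        for route in ("via-stickleback-human", "via-stickleback-zebrafish"):
            mapping = map_to_model_ids(
                route, to_intermediate=to_ga, intermediate_to_target=ga_to_target
            )
            assert dict(zip(mapping["transcript_id"], mapping["model_id"])) == expected
        for route in ("direct-human", "direct-zebrafish"):
            mapping = map_to_model_ids(route, direct_hits=direct)
            assert dict(zip(mapping["transcript_id"], mapping["model_id"])) == {
                "q1": "m7", "q4": "m8",
            }

    def test_missing_tables_raise(self):
        with pytest.raises(ValueError):
            map_to_model_ids("via-stickleback-human", to_intermediate=None)
        with pytest.raises(ValueError):
            map_to_model_ids("sideways")
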