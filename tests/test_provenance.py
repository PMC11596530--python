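import numpy as np
import pytest

from _oracles import exhaustive_nearest
from conftest import make_table, random_dna
from primertrace import (
    AsvRecord,
    classify_origin,
    resolve_unique,
    source_summary_frame,
    summarize_composition,
    summarize_unique_sources,
)
from primertrace.provenance import OriginAssignment, SourceResolution
from primertrace.align import PDistance


def _assignment(asv_id, category, reads, major_threshold=600):
    flags = {
        "Common": (True, True),
        "FromSoil": (True, False),
        "FromSubstrate": (False, True),
        "Unique": (False, False),
    }[category]
    return OriginAssignment(asv_id, *flags, category, reads, reads > major_threshold)


class TestClassifyOrigin:
    @pytest.fixture
    def communities(self):
        #           asv0 asv1 asv2 asv3
        # primer     10    5    7    3
        # soil        4    2    0    0
        # substrate   6    0    1    0
        primer = make_table([[10, 5, 7, 3]], ["primer"])
        soil = make_table([[4, 2, 0, 0]], ["soil"], substrate_type=["none"])
        substrate = make_table([[6, 0, 1, 0]], ["substrate"], soil_type=["none"])
        return primer, soil, substrate

    def test_four_way_partition(self, communities):
        assignments = {a.asv_id: a.category for a in classify_origin(*communities)}
        assert assignments == {
            "asv0": "Common",
            "asv1": "FromSoil",
            "asv2": "FromSubstrate",
            "asv3": "Unique",
        }

    def test_presence_min_threshold(self, communities):
        # with presence_min=3 the soil's 2 reads of asv1 no longer count
        assignments = {
            a.asv_id: a.category for a in classify_origin(*communities, presence_min=3)
        }
        assert assignments["asv1"] == "Unique"
        assert assignments["asv0"] == "Common"  # 4 and 6 reads still present

    def test_presence_pooled_over_replicates(self):
        primer = make_table([[5]], ["primer"])
        # one read in each of two soil replicates: pooled presence of 2
        soil = make_table([[1], [1]], ["soil", "soil"], substrate_type=["none", "none"])
        substrate = make_table([[0]], ["substrate"], soil_type=["none"])
        (a,) = classify_origin(primer, soil, substrate, presence_min=2)
        assert a.category == "FromSoil"

    def test_empty_primer_rejected(self, communities):
        _, soil, substrate = communities
        empty = make_table([[0, 0, 0, 0]], ["primer"])
        with pytest.raises(ValueError, match="no detected"):
            classify_origin(empty, soil, substrate)

    def test_read_totals_conserved(self, communities):
        primer = communities[0]
        assignments = classify_origin(*communities)
        assert sum(a.primer_reads for a in assignments) == int(primer.counts.sum().sum())

    def test_end_to_end_truth_recovery_without_dropout(self):
        """With every taxon detected and no novelty the classifier must agree
        with the generator's truth on every primer ASV."""
        from primertrace import SimulationParams, generate_primer, generate_sources

        params = SimulationParams(
            n_soil_taxa=50, n_substrate_taxa=15, n_shared_taxa=5, n_primer_taxa=40,
            recruit_soil=0.70, recruit_substrate=0.10, recruit_shared=0.20,
            recruit_novel=0.0, seq_length=100,
            depth_source=300_000, depth_primer=300_000, seed=11,
        )
        sources = generate_sources(params)
        primer = generate_primer(sources, params)
        assignments = classify_origin(
            primer.table,
            sources.table.select_role("soil").drop_absent_asvs(),
            sources.table.select_role("substrate").drop_absent_asvs(),
        )
        mapped = {"Common": "Common", "FromSoil": "FromSoil", "FromSubstrate": "FromSubstrate"}
        assert all(a.category == mapped[primer.truth.origin[a.asv_id]] for a in assignments)


class TestResolveUnique:
    def test_identical_to_soil_reference(self, rng):
        seq = random_dna(rng, 120)
        query = AsvRecord("q", seq)
        soil = [AsvRecord("soil1", seq), AsvRecord("soil2", random_dna(rng, 120))]
        sub = [AsvRecord("sub1", random_dna(rng, 120))]
        (res,) = resolve_unique([query], soil, sub)
        assert res.nearest_asv_id == "soil1"
        assert res.distance.value == 0.0
        assert res.possible_source == "Soil"

    def test_cominimal_references_across_pools_yield_common(self, rng):
        seq = random_dna(rng, 120)
        query = AsvRecord("q", seq)
        res, = resolve_unique(
            [query], [AsvRecord("s", seq)], [AsvRecord("t", seq)]
        )
        assert res.possible_source == "Common"

    def test_reference_in_both_pools_yields_common(self, rng):
        seq = random_dna(rng, 120)
        shared = AsvRecord("shared", seq)
        (res,) = resolve_unique([AsvRecord("q", seq)], [shared], [shared])
        assert res.possible_source == "Common"

    def test_empty_reference_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            resolve_unique([AsvRecord("q", random_dna(rng, 60))], [], [])

    def test_matches_exhaustive_search(self, rng):
        """Nearest-neighbour output equals an independently coded exhaustive
        search on mutated and unrelated queries alike."""
        refs = [AsvRecord(f"r{i}", random_dna(rng, 80)) for i in range(30)]
        soil_ids = {r.asv_id for r in refs[:20]}
        sub_ids = {r.asv_id for r in refs[20:]}
        queries = []
        for i in range(8):
            base = refs[int(rng.integers(len(refs)))].sequence
            mutated = "".join(
                rng.choice([c for c in "ACGT" if c != x]) if rng.random() < 0.03 else x
                for x in base
            )
            queries.append(AsvRecord(f"q{i}", mutated))
        queries += [AsvRecord(f"q{8 + i}", random_dna(rng, 80)) for i in range(4)]
        results = resolve_unique(queries, refs[:20], refs[20:], soil_ids, sub_ids)
        for query, res in zip(queries, results):
            oid, od, osrc = exhaustive_nearest(query, refs, soil_ids, sub_ids)
            assert (res.nearest_asv_id, res.distance.value, res.possible_source) == (
                oid,
                od,
                osrc,
            )

    def test_short_overlap_references_ineligible(self, rng):
        """An unrelated reference whose best alignment is a tiny perfect
        overlap must not beat a full-length near-identical parent."""
        parent = random_dna(rng, 200)
        query_seq = parent[:100] + ("A" if parent[100] != "A" else "C") + parent[101:]
        # decoy: its suffix equals the query's prefix -> short perfect overlap
        decoy = random_dna(rng, 180) + query_seq[:12]
        results = resolve_unique(
            [AsvRecord("q", query_seq)],
            [AsvRecord("parent", parent)],
            [AsvRecord("decoy", decoy)],
        )
        assert results[0].nearest_asv_id == "parent"


class TestSummaries:
    def test_single_resolution_statistics(self):
        res = SourceResolution("u1", "r1", PDistance(0.02, 100), "Soil")
        rows = summarize_unique_sources([res], [_assignment("u1", "Unique", 100)])
        (row,) = rows
        assert (row.possible_source, row.n_reads) == ("Soil", 100)
        assert row.mean_distance == row.q3_distance == row.max_distance == 0.02

    def test_q3_linear_interpolation(self):
        dists = [0.0, 0.02, 0.04, 0.06]
        res = [
            SourceResolution(f"u{i}", "r", PDistance(d, 100), "Soil")
            for i, d in enumerate(dists)
        ]
        assignments = [_assignment(f"u{i}", "Unique", 10) for i in range(4)]
        (row,) = summarize_unique_sources(res, assignments)
        assert row.mean_distance == pytest.approx(0.03)
        assert row.q3_distance == pytest.approx(0.045)
        assert row.max_distance == pytest.approx(0.06)

    def test_rows_ordered_common_soil_substrate(self):
        res = [
            SourceResolution("u1", "r", PDistance(0.1, 100), "Substrate"),
            SourceResolution("u2", "r", PDistance(0.1, 100), "Common"),
            SourceResolution("u3", "r", PDistance(0.1, 100), "Soil"),
        ]
        assignments = [_assignment(f"u{i}", "Unique", 5) for i in (1, 2, 3)]
        rows = summarize_unique_sources(res, assignments)
        assert [r.possible_source for r in rows] == ["Common", "Soil", "Substrate"]

    def test_empty_resolutions_empty_summary(self):
        assert summarize_unique_sources([], []) == []

    def test_non_unique_resolution_rejected(self):
        res = SourceResolution("c1", "r1", PDistance(0.02, 100), "Soil")
        with pytest.raises(ValueError, match="non-Unique"):
            summarize_unique_sources([res], [_assignment("c1", "Common", 100)])

    def test_summary_frame_layout(self):
        res = [SourceResolution("u1", "r1", PDistance(0.02, 100), "Soil")]
        frame = source_summary_frame(summarize_unique_sources(res, [_assignment("u1", "Unique", 7)]))
        assert list(frame.columns) == ["possible_source", "n_reads", "mean", "q3", "max"]


class TestComposition:
    def test_major_boundary_is_strict(self):
        assignments = [
            _assignment("a", "Common", 601),
            _assignment("b", "Common", 600),
        ]
        comp = summarize_composition(assignments).set_index(["category", "size_class"])
        assert comp.loc[("Common", "major"), "n_asvs"] == 1
        assert comp.loc[("Common", "minor"), "n_asvs"] == 1

    def test_reads_conserved_over_cells(self, small_simulation):
        _, sources, primer = small_simulation
        assignments = classify_origin(
            primer.table,
            sources.table.select_role("soil").drop_absent_asvs(),
            sources.table.select_role("substrate").drop_absent_asvs(),
        )
        comp = summarize_composition(assignments)
        assert comp["reads"].sum() == sum(a.primer_reads for a in assignments)
        assert comp["n_asvs"].sum() == len(assignments)

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            summarize_composition([], major_threshold=0)
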