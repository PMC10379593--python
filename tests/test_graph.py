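"""Triple extraction, graph construction, fold splitting, pathology masking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birads_tensor import (
    AnnotationRecord,
    GeneratorConfig,
    Triple,
    annotation_to_triples,
    build_graph,
    cohort_records,
    mask_test_pathology,
    read_triples,
    simulate_cohort,
    split_folds,
    write_triples,
)
from birads_tensor.records import CHARACTERISTICS, SchemaError


def _full_record(pathology="malignant"):
    return AnnotationRecord(
        case_id="caseA",
        image_id="img0",
        annotator="senior",
        pathology=pathology,
        characteristics={c: "present" for c in CHARACTERISTICS},
    )


class TestAnnotationToTriples:
    def test_single_characteristic_becomes_one_patient_triple(self):
        """One reading maps to one (patient, characteristic, value) triple,
        with the tail namespaced by its relation."""
        rec = AnnotationRecord("caseA", "img0", "senior", "benign", {"shape": "present"})
        triples = annotation_to_triples(rec, include_pathology=False)
        assert triples == [Triple("caseA::img0", "shape", "shape=present")]

    def test_full_record_yields_eleven_triples(self):
        triples = annotation_to_triples(_full_record())
        assert len(triples) == 11
        assert Triple("caseA::img0", "pathology", "malignant") in triples

    def test_pathology_only_record_yields_one_triple(self):
        rec = AnnotationRecord("caseA", "img0", "senior", "benign", {})
        assert annotation_to_triples(rec) == [Triple("caseA::img0", "pathology", "benign")]

    def test_unknown_characteristic_is_schema_error(self):
        with pytest.raises(SchemaError):
            AnnotationRecord("c", "i", "senior", "benign", {"echo_pattern": "x"})


class TestBuildGraph:
    def test_shared_head_distinct_tails(self):
        g = build_graph([Triple("h", "r1", "t1"), Triple("h", "r2", "t2")])
        assert len(g.entities) == 3
        assert g.m <= 2

    def test_duplicates_collapse(self):
        t = Triple("h", "r", "t")
        g = build_graph([t, t])
        assert g.n == 1

    def test_two_characteristic_lesion_graph_counts(self):
        """A miniature report graph — several lesions described by two
        characteristics plus benign/malignant tails — has exactly the
        hand-enumerated entity and relation counts."""
        triples = []
        for pid, label in (("L1", "malignant"), ("L2", "malignant"), ("L3", "benign")):
            v = "present" if label == "malignant" else "absent"
            triples.append(Triple(pid, "shape", f"shape={v}"))
            triples.append(Triple(pid, "margin", f"margin={v}"))
            triples.append(Triple(pid, "pathology", label))
        g = build_graph(triples)
        assert g.p == 3  # lesions
        # tails: shape=present, shape=absent, margin=present, margin=absent,
        # malignant, benign
        assert g.q == 6
        assert g.m == 3
        assert g.n == 9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_graph([])

    def test_triple_count_bounded_by_images(self, small_cohort):
        recs = cohort_records(small_cohort, "senior")
        triples = [t for r in recs for t in annotation_to_triples(r)]
        g = build_graph(triples)
        assert g.n <= len(recs) * 11

    def test_serialization_round_trip(self, tmp_path, small_cohort):
        recs = cohort_records(small_cohort, "junior")
        g = build_graph([t for r in recs for t in annotation_to_triples(r)])
        path = tmp_path / "triples.tsv"
        write_triples(g.triples, path)
        assert read_triples(path) == g.triples
        g2 = build_graph(read_triples(path))
        assert g2.entity_index == g.entity_index
        assert g2.relation_index == g.relation_index


class TestSplitFolds:
    def test_ten_cases_five_folds_two_each(self):
        folds = split_folds([f"c{i}" for i in range(10)], k=5, seed=0)
        sizes = [len(folds.fold_cases(f)) for f in range(5)]
        assert sizes == [2] * 5

    @given(n=st.integers(3, 40), k=st.integers(1, 5), seed=st.integers(0, 10))
    @settings(max_examples=30, deadline=None)
    def test_folds_partition_cases(self, n, k, seed):
        if k > n:
            return
        cases = [f"c{i}" for i in range(n)]
        folds = split_folds(cases, k=k, seed=seed)
        all_folds = [set(folds.fold_cases(f)) for f in range(k)]
        assert set().union(*all_folds) == set(cases)
        assert sum(len(s) for s in all_folds) == n
        assert max(len(s) for s in all_folds) - min(len(s) for s in all_folds) <= 1

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            split_folds(["a", "b"], k=3)

    def test_images_of_a_case_share_a_fold(self, small_cohort):
        """No case-level leakage: every image of a case lands in the fold
        of its case by construction."""
        folds = split_folds([c.case_id for c in small_cohort], k=5, seed=3)
        for case in small_cohort:
            assert {folds.assignment[case.case_id]} == {
                folds.assignment[case.case_id] for _ in case.image_ids
            }


class TestMaskTestPathology:
    def _graph(self, cohort):
        recs = cohort_records(cohort, "senior")
        return build_graph([t for r in recs for t in annotation_to_triples(r)])

    def test_one_held_out_case_loses_one_pathology_triple(self):
        cases = simulate_cohort(GeneratorConfig(n_cases=4, seed=1))
        g = self._graph(cases)
        train, queries = mask_test_pathology(g, [cases[0].case_id])
        assert g.n - len(train) == len(cases[0].image_ids) == len(queries)

    def test_no_pathology_overlap_between_train_and_queries(self, small_cohort):
        g = self._graph(small_cohort)
        test_cases = [c.case_id for c in small_cohort[:10]]
        train, queries = mask_test_pathology(g, test_cases)
        train_path_heads = {t.head for t in train if t.relation == "pathology"}
        assert train_path_heads.isdisjoint({q.head for q in queries})
        # characteristic triples of test cases stay visible
        query_heads = {q.head for q in queries}
        assert query_heads <= {t.head for t in train}

    def test_five_fold_sweep_queries_every_image_exactly_once(self, small_cohort):
        g = self._graph(small_cohort)
        folds = split_folds([c.case_id for c in small_cohort], k=5, seed=7)
        seen = []
        for f in range(5):
            _, queries = mask_test_pathology(g, folds.fold_cases(f))
            seen.extend(q.head for q in queries)
        all_heads = {t.head for t in g.triples}
        assert sorted(seen) == sorted(all_heads)

    def test_unknown_test_case_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            mask_test_pathology(self._graph(small_cohort), ["not-a-case"])
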