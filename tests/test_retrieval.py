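"""Exact retrieval, tie-breaking, and the scan-level accuracy metrics."""

import numpy as np
import pandas as pd
import pytest

from lgfusion.fixtures import make_toy_retrieval_case
from lgfusion.retrieval import (
    RetrievalRun,
    ScanPartition,
    build_index,
    eta_p,
    eta_tot,
    eta_w,
    evaluate_run,
    leave_one_out_run,
    query_topk,
    recall_at_k,
)


def manifest_for(n, classes=None, scans=None):
    return pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(n)],
            "class": classes if classes is not None else [0] * n,
            "scan": scans if scans is not None else [0] * n,
        }
    )


def brute_force_topk(db, queries, k):
    """Double-loop Euclidean ranking oracle with database-order tie-break."""
    out = []
    for q in queries:
        dists = [float(np.sum((q - d) ** 2)) for d in db]
        order = sorted(range(len(db)), key=lambda j: (dists[j], j))
        out.append(order[:k])
    return np.array(out)


class TestIndexAndQuery:
    def test_small_index_builds(self, rng):
        vecs = rng.standard_normal((3, 4))
        index = build_index(vecs, manifest_for(3))
        assert len(index.ids) == 3

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_index(np.zeros((0, 4)), manifest_for(0))

    def test_duplicate_ids_rejected(self, rng):
        manifest = manifest_for(3)
        manifest.loc[2, "id"] = "v0"
        with pytest.raises(ValueError, match="duplicate"):
            build_index(rng.standard_normal((3, 4)), manifest)

    def test_exact_self_match_ranks_first(self, rng):
        vecs = rng.standard_normal((5, 4))
        index = build_index(vecs, manifest_for(5))
        run = query_topk(index, vecs[2:3], ["q"], k=1)
        assert run.retrieved["q"] == ("v2",)

    def test_equidistant_neighbors_break_ties_by_database_order(self):
        db = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 5.0]])
        index = build_index(db, manifest_for(3))
        run = query_topk(index, np.array([[1.0, 0.0]]), ["q"], k=2)
        assert run.retrieved["q"] == ("v0", "v1")

    @pytest.mark.parametrize("backend", ["numpy", "sklearn"])
    def test_backend_matches_brute_force_double_loop(self, backend, rng):
        db = rng.standard_normal((100, 16))
        queries = rng.standard_normal((7, 16))
        index = build_index(db, manifest_for(100))
        run = query_topk(index, queries, list(range(7)), k=10, backend=backend)
        expected = brute_force_topk(db, queries, 10)
        for qi in range(7):
            assert run.retrieved[qi] == tuple(f"v{j}" for j in expected[qi])

    def test_oversized_k_truncates_with_warning(self, rng):
        index = build_index(rng.standard_normal((4, 3)), manifest_for(4))
        with pytest.warns(UserWarning, match="truncating"):
            run = query_topk(index, rng.standard_normal((1, 3)), ["q"], k=9)
        assert len(run.retrieved["q"]) == 4

    def test_leave_one_out_excludes_self(self, rng):
        vecs = rng.standard_normal((6, 4))
        index = build_index(vecs, manifest_for(6))
        run = leave_one_out_run(index, k=2)
        for q, ranked in run.retrieved.items():
            assert q not in ranked and len(ranked) == 2


class TestScanMetrics:
    def test_toy_case_hand_enumeration(self):
        """The packaged 2-scan, 5-patch case: 0.8 / 0.75 / 0.6 exactly."""
        run, part = make_toy_retrieval_case()
        ep, ew = eta_p(run, part), eta_w(run, part)
        assert ep == 0.8
        assert ew == 0.75
        assert eta_tot(ep, ew) == pytest.approx(0.6)

    def test_all_hits_and_no_hits(self):
        part = ScanPartition(gamma={"a": ("p0", "p1"), "b": ("p2", "p3")})
        perfect = RetrievalRun(
            {"p0": ("p1",), "p1": ("p0",), "p2": ("p3",), "p3": ("p2",)}, k=1
        )
        assert eta_p(perfect, part) == 1.0 and eta_w(perfect, part) == 1.0
        wrong = RetrievalRun(
            {"p0": ("p2",), "p1": ("p3",), "p2": ("p0",), "p3": ("p1",)}, k=1
        )
        assert eta_p(wrong, part) == 0.0 and eta_w(wrong, part) == 0.0

    def test_equal_scan_sizes_make_both_metrics_equal(self, rng):
        """With |Γ_s| constant, eta_p == eta_w exactly (algebraic identity)."""
        ids = [f"p{i}" for i in range(24)]
        part = ScanPartition(
            gamma={s: tuple(ids[6 * s : 6 * s + 6]) for s in range(4)}
        )
        for _ in range(5):
            retrieved = {
                q: (rng.choice([i for i in ids if i != q]),) for q in ids
            }
            run = RetrievalRun(retrieved, k=1)
            assert eta_p(run, part) == pytest.approx(eta_w(run, part), abs=1e-12)

    def test_query_missing_from_partition_rejected(self):
        part = ScanPartition(gamma={"a": ("p0",)})
        run = RetrievalRun({"zz": ("p0",)}, k=1)
        with pytest.raises(ValueError, match="missing"):
            eta_p(run, part)

    def test_partition_invariants(self):
        with pytest.raises(ValueError, match="multiple"):
            ScanPartition(gamma={"a": ("p0",), "b": ("p0", "p1")})
        with pytest.raises(ValueError, match="no patches"):
            ScanPartition(gamma={"a": ()})
        part = ScanPartition(gamma={"a": ("p0", "p1"), "b": ("p2",)})
        assert part.n_tot == 3

    def test_metrics_are_pure(self):
        run, part = make_toy_retrieval_case()
        assert eta_p(run, part) == eta_p(run, part)
        assert eta_w(run, part) == eta_w(run, part)


class TestRecall:
    def test_rank_profile(self):
        """4 queries: 2 correct at rank 1, all correct by rank 3."""
        class_of = {"q0": 0, "q1": 0, "q2": 1, "q3": 1,
                    "a": 0, "b": 1, "c": 0, "d": 1}
        run = RetrievalRun(
            {
                "q0": ("a", "b", "c"),
                "q1": ("b", "d", "a"),
                "q2": ("d", "a", "b"),
                "q3": ("a", "c", "b"),
            },
            k=3,
        )
        assert recall_at_k(run, class_of, 1) == 0.5
        assert recall_at_k(run, class_of, 2) == 0.5  # second hits arrive at rank 3
        assert recall_at_k(run, class_of, 3) == 1.0

    def test_recall_non_decreasing_in_k(self, rng):
        ids = [f"p{i}" for i in range(20)]
        class_of = {p: i % 4 for i, p in enumerate(ids)}
        retrieved = {
            q: tuple(rng.permutation([i for i in ids if i != q])[:5]) for q in ids
        }
        run = RetrievalRun(retrieved, k=5)
        values = [recall_at_k(run, class_of, k) for k in range(1, 6)]
        assert all(0.0 <= v <= 1.0 for v in values)
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_empty_query_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            recall_at_k(RetrievalRun({}, k=1), {}, 1)


def test_evaluate_run_bundles_all_metrics():
    run, part = make_toy_retrieval_case()
    class_of = {p: 0 for p in ("p0", "p1")} | {p: 1 for p in ("p2", "p3", "p4")}
    report = evaluate_run(run, part, class_of)
    assert report["eta_p"] == 0.8 and report["eta_w"] == 0.75
    assert report["eta_tot"] == pytest.approx(0.6)
    assert report["recall_at_1"] == 0.8
    assert set(report["per_scan"]) == {"s0", "s1"}
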