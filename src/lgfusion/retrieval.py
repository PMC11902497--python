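"""Exact nearest-neighbour retrieval and the scan-level accuracy metrics.

The retrieval unit is a patch descriptor; ground truth comes at two
granularities: a class label (tissue type) and a scan label (which
whole-slide image the patch was cropped from).  Three metrics are
computed from the top-ranked results of every query:

* Recall@K — fraction of queries with at least one same-class item among
  the top K.
* patch-to-scan accuracy  eta_p = sum_s |R ∩ Γ_s| / n_tot, the fraction
  of all queried patches whose retrieved patch comes from their own scan;
* whole-scan accuracy     eta_w = (1/|S|) sum_s |R ∩ Γ_s| / n_Γs, the
  unweighted mean over scans of the per-scan hit fraction;
* overall accuracy        eta_tot = eta_p * eta_w.

The scan metrics are defined for top-1 retrieval; at depth d > 1 each
query contributes its hit fraction |top-d ∩ Γ_s| / d, which reduces to
the top-1 definition at d = 1.

The index contract is exact brute-force Euclidean ranking with ties
broken by database order; the optional scikit-learn backend must (and
does) reproduce that ranking bit-for-bit on unit-norm descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanPartition",
    "RetrievalRun",
    "EmbeddingIndex",
    "build_index",
    "query_topk",
    "leave_one_out_run",
    "eta_p",
    "eta_w",
    "eta_tot",
    "recall_at_k",
    "evaluate_run",
]


@dataclass(frozen=True)
class ScanPartition:
    """Ground-truth grouping of patch ids into scans.

    ``gamma`` maps each scan label to the ids of its patches; the sets
    must be disjoint and non-empty.
    """

    gamma: dict[object, tuple]

    def __post_init__(self):
        seen: set = set()
        for scan, ids in self.gamma.items():
            if len(ids) == 0:
                raise ValueError(f"scan {scan!r} has no patches")
            overlap = seen.intersection(ids)
            if overlap:
                raise ValueError(f"patches assigned to multiple scans: {sorted(overlap)}")
            seen.update(ids)
        object.__setattr__(self, "gamma", {s: tuple(ids) for s, ids in self.gamma.items()})

    @property
    def scans(self) -> list:
        return list(self.gamma)

    @property
    def n_tot(self) -> int:
        return sum(len(ids) for ids in self.gamma.values())

    def scan_of(self, patch_id) -> object:
        for scan, ids in self.gamma.items():
            if patch_id in ids:
                return scan
        raise KeyError(f"patch {patch_id!r} missing from partition")


@dataclass(frozen=True)
class RetrievalRun:
    """Ranked retrieval results: query id -> ordered database ids."""

    retrieved: dict[object, tuple]
    k: int

    def __post_init__(self):
        object.__setattr__(
            self, "retrieved", {q: tuple(r) for q, r in self.retrieved.items()}
        )
        for q, ranked in self.retrieved.items():
            if q in ranked:
                raise ValueError(f"query {q!r} retrieved itself")


@dataclass(frozen=True)
class EmbeddingIndex:
    """Exact Euclidean index over a descriptor matrix."""

    matrix: np.ndarray
    ids: tuple
    class_of: dict
    scan_of: dict


def build_index(descriptors: np.ndarray, manifest) -> EmbeddingIndex:
    """Build an exact index from a descriptor matrix and a manifest.

    ``manifest`` is a pandas DataFrame (or mapping of columns) with
    columns ``id``, ``class`` and ``scan``, one row per descriptor row.
    """
    import pandas as pd

    manifest = pd.DataFrame(manifest)
    descriptors = np.asarray(descriptors, dtype=np.float64)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    if descriptors.ndim != 2 or len(manifest) != descriptors.shape[0]:
        raise ValueError(
            f"descriptor rows ({descriptors.shape}) do not match manifest "
            f"({len(manifest)} rows)"
        )
    ids = tuple(manifest["id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in manifest")
    return EmbeddingIndex(
        matrix=descriptors,
        ids=ids,
        class_of=dict(zip(ids, manifest["class"])),
        scan_of=dict(zip(ids, manifest["scan"])),
    )


def _ranked_neighbors(
    db: np.ndarray, queries: np.ndarray, k: int, backend: str
) -> np.ndarray:
    """Top-k database row indices per query, ascending distance, ties by row order."""
    if backend == "numpy":
        # squared distances via direct differencing (chunked over queries),
        # bit-identical to a per-pair double loop; stable argsort preserves
        # database order among exact ties
        rows = []
        chunk = max(1, int(2e7) // max(1, db.size))
        for start in range(0, len(queries), chunk):
            q = queries[start : start + chunk]
            d2 = ((q[:, None, :] - db[None, :, :]) ** 2).sum(axis=-1)
            rows.append(np.argsort(d2, axis=1, kind="stable")[:, :k])
        return np.concatenate(rows, axis=0)
    if backend == "sklearn":
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=min(k, len(db)), algorithm="brute")
        nn.fit(db)
        dist, idx = nn.kneighbors(queries)
        # re-impose the database-order tie-break the contract requires
        out = np.empty_like(idx)
        for row, (d_row, i_row) in enumerate(zip(dist, idx)):
            order = np.lexsort((i_row, np.round(d_row, 9)))
            out[row] = i_row[order]
        return out
    raise ValueError(f"unknown backend {backend!r}")


def query_topk(
    index: EmbeddingIndex,
    queries: np.ndarray,
    query_ids,
    k: int,
    backend: str = "numpy",
) -> RetrievalRun:
    """Rank the database for each query vector by Euclidean distance."""
    if k < 1:
        raise ValueError("k must be >= 1")
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if k > len(index.ids):
        import warnings

        warnings.warn(
            f"k={k} exceeds index size {len(index.ids)}; truncating", stacklevel=2
        )
        k = len(index.ids)
    idx = _ranked_neighbors(index.matrix, queries, k, backend)
    retrieved = {
        qid: tuple(index.ids[j] for j in row) for qid, row in zip(query_ids, idx)
    }
    return RetrievalRun(retrieved=retrieved, k=k)


def leave_one_out_run(index: EmbeddingIndex, k: int = 1, backend: str = "numpy") -> RetrievalRun:
    """Each indexed patch queries the remaining database (self excluded)."""
    idx = _ranked_neighbors(index.matrix, index.matrix, k + 1, backend)
    retrieved = {}
    for row, qid in zip(idx, index.ids):
        ranked = [index.ids[j] for j in row if index.ids[j] != qid]
        retrieved[qid] = tuple(ranked[:k])
    return RetrievalRun(retrieved=retrieved, k=k)


def _per_scan_hits(run: RetrievalRun, part: ScanPartition) -> dict:
    """Fractional hit count per scan: sum over queries of |top-d ∩ Γ_s| / d."""
    scan_of = {}
    for scan, ids in part.gamma.items():
        for pid in ids:
            scan_of[pid] = scan
    hits = {scan: 0.0 for scan in part.gamma}
    for q, ranked in run.retrieved.items():
        if q not in scan_of:
            raise ValueError(f"query {q!r} missing from scan partition")
        if not ranked:
            continue
        scan = scan_of[q]
        same = sum(1 for r in ranked if scan_of.get(r) == scan)
        hits[scan] += same / len(ranked)
    return hits


def eta_p(run: RetrievalRun, part: ScanPartition) -> float:
    """Patch-to-scan accuracy: correct-scan retrievals over all patches."""
    hits = _per_scan_hits(run, part)
    return sum(hits.values()) / part.n_tot


def eta_w(run: RetrievalRun, part: ScanPartition) -> float:
    """Whole-scan accuracy: mean over scans of the per-scan hit fraction."""
    hits = _per_scan_hits(run, part)
    return sum(hits[s] / len(part.gamma[s]) for s in part.gamma) / len(part.gamma)


def eta_tot(eta_p_value: float, eta_w_value: float) -> float:
    """Overall accuracy: the product of the two scan accuracies."""
    return eta_p_value * eta_w_value


def recall_at_k(run: RetrievalRun, class_of: dict, k: int) -> float:
    """Fraction of queries with >= 1 same-class item among the top k."""
    if not run.retrieved:
        raise ValueError("empty query set")
    if k > run.k:
        raise ValueError(f"run holds top-{run.k}, cannot evaluate Recall@{k}")
    hit = 0
    for q, ranked in run.retrieved.items():
        cls = class_of[q]
        if any(class_of[r] == cls for r in ranked[:k]):
            hit += 1
    return hit / len(run.retrieved)


def evaluate_run(run: RetrievalRun, part: ScanPartition, class_of: dict) -> dict:
    """Bundle all metrics (plus a per-scan table) into one report."""
    hits = _per_scan_hits(run, part)
    ep = sum(hits.values()) / part.n_tot
    ew = sum(hits[s] / len(part.gamma[s]) for s in part.gamma) / len(part.gamma)
    report = {
        "recall_at_1": recall_at_k(run, class_of, 1),
        "eta_p": ep,
        "eta_w": ew,
        "eta_tot": eta_tot(ep, ew),
        "per_scan": {
            str(s): {"hits": hits[s], "size": len(part.gamma[s])} for s in part.gamma
        },
    }
    return report
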