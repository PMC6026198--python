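"""Greedy incremental clustering of the verified edge set.

The verified edges (center -> member pairs that satisfied the acceptance
criteria) are made undirected.  Sequences are processed by decreasing
length (ties: smallest id); each unassigned sequence in turn founds a new
cluster as its representative and absorbs all of its still-unassigned
neighbors.  Representatives are therefore always the longest sequence of
their cluster, so they are likely to contain all protein domains of their
members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from linclust.align import AcceptParams, Edge, accept_edge, local_align


@dataclass(frozen=True)
class Clustering:
    """A partition of sequence ids into representative-led clusters."""

    assignments: dict[int, int]  # member id -> representative id
    clusters: dict[int, list[int]]  # representative id -> member ids

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _edge_pairs(edges: Iterable) -> Iterable[tuple[int, int]]:
    for e in edges:
        if isinstance(e, Edge):
            yield e.center_id, e.member_id
        else:
            a, b = e
            yield int(a), int(b)


def greedy_cluster(seq_lengths: Sequence[int], edges: Iterable) -> Clustering:
    """Cluster ``len(seq_lengths)`` sequences given passed edges.

    ``edges`` holds Edge objects or (center, member) id pairs; reverse
    edges are added implicitly.  Ids outside [0, N) raise.  Sequences with
    no surviving neighbor become singletons.
    """
    n = len(seq_lengths)
    adj: dict[int, set[int]] = {}
    for a, b in _edge_pairs(edges):
        if not (0 <= a < n and 0 <= b < n):
            raise ValueError(f"edge ({a}, {b}) references unknown sequence id")
        if a == b:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    order = sorted(range(n), key=lambda i: (-seq_lengths[i], i))
    assignments: dict[int, int] = {}
    clusters: dict[int, list[int]] = {}
    for rep in order:
        if rep in assignments:
            continue
        assignments[rep] = rep
        members = [rep]
        for nb in sorted(adj.get(rep, ())):
            if nb not in assignments:
                assignments[nb] = rep
                members.append(nb)
        clusters[rep] = members
    return Clustering(assignments=assignments, clusters=clusters)


def verify_clustering(
    clustering: Clustering,
    sequences: Sequence[np.ndarray],
    params: AcceptParams,
    scores: np.ndarray,
    max_reported: int = 20,
) -> dict:
    """Recompute the acceptance decision for every member-representative pair.

    ``sequences`` are full-alphabet code arrays indexed by sequence id.
    A pair is linked by the pipeline when either the gapped-alignment
    criteria hold or the pair Hamming-pre-accepts along a diagonal, so
    both paths are recomputed (the Hamming path over all diagonals, as
    the seeded diagonal is no longer known).  Returns a report with the
    number checked, failed, the failure fraction and a capped list of
    failing pairs with their violated criteria.
    """
    from linclust import _kernels

    n_checked = 0
    failures: list[tuple[int, int, tuple[str, ...]]] = []
    for rep, members in clustering.clusters.items():
        for member in members:
            if member == rep:
                continue
            n_checked += 1
            aln = local_align(
                sequences[rep],
                sequences[member],
                scores,
                params.gap_open,
                params.gap_extend,
            )
            edge = accept_edge(
                aln,
                q_len=sequences[rep].shape[0],
                t_len=sequences[member].shape[0],
                params=params,
                center_id=rep,
                member_id=member,
            )
            if not edge.passed and not _kernels.hamming_preaccept_any_diagonal(
                sequences[rep],
                sequences[member],
                params.min_seq_id,
                params.c,
                params.cov_mode,
            ):
                failures.append((rep, member, edge.failed_criteria))
    return {
        "n_checked": n_checked,
        "n_failed": len(failures),
        "failure_fraction": (len(failures) / n_checked) if n_checked else 0.0,
        "failures": failures[:max_reported],
    }


def pairwise_metrics(
    assignments: Mapping[int, int], truth_labels: Sequence[int]
) -> tuple[float, float]:
    """Pairwise (recall, precision) of a clustering against truth labels.

    Recall: fraction of same-family pairs placed in the same cluster.
    Precision: fraction of co-clustered pairs that are same-family.
    """
    from collections import Counter

    contingency: Counter[tuple[int, int]] = Counter()
    cluster_sizes: Counter[int] = Counter()
    family_sizes: Counter[int] = Counter()
    for i, fam in enumerate(truth_labels):
        rep = assignments[i]
        contingency[(rep, fam)] += 1
        cluster_sizes[rep] += 1
        family_sizes[fam] += 1

    def pairs(k: int) -> int:
        return k * (k - 1) // 2

    together_true = sum(pairs(v) for v in contingency.values())
    predicted = sum(pairs(v) for v in cluster_sizes.values())
    actual = sum(pairs(v) for v in family_sizes.values())
    recall = together_true / actual if actual else 1.0
    precision = together_true / predicted if predicted else 1.0
    return recall, precision
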