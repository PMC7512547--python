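"""Order-stable greedy clustering of FL-ASVs at each rank threshold.

The clustering is deliberately naive: sequences are processed strictly in
input order, and each sequence joins the FIRST existing centroid it matches
at or above the threshold, else founds a new centroid. This "first match"
rule — not "best match" — is what makes the clustering prefix-stable:
appending new sequences can never change the assignment of an earlier one,
so placeholder names minted from centroids survive database updates.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .records import (
    CLUSTERED_RANKS,
    ClusterSet,
    RankThresholds,
    SeqRecord,
)
from .seqcore import AlignScoring, DEFAULT_SCORING, global_identity


def greedy_cluster(
    seqs_in_order: Sequence[SeqRecord],
    threshold: float,
    rank: str | None = None,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> ClusterSet:
    """Greedy first-match centroid clustering at a percent-identity threshold.

    Identity exactly at the threshold joins the cluster (>=). Deterministic
    for a fixed input order; prefix-stable under appends.
    """
    assignments: dict[str, str] = {}
    centroid_order: list[str] = []
    centroids: list[SeqRecord] = []
    for rec in seqs_in_order:
        target = None
        for c in centroids:
            if global_identity(rec, c, scoring) >= threshold:
                target = c.id
                break
        if target is None:
            centroids.append(rec)
            centroid_order.append(rec.id)
            target = rec.id
        assignments[rec.id] = target
    return ClusterSet(
        rank=rank,
        threshold=threshold,
        assignments=assignments,
        centroid_order=centroid_order,
    )


def cluster_all_ranks(
    flasvs: Sequence[SeqRecord],
    thresholds: RankThresholds = RankThresholds(),
    scoring: AlignScoring = DEFAULT_SCORING,
) -> Mapping[str, ClusterSet]:
    """Independent greedy clusterings at every rank threshold.

    Input must be in canonical FL-ASV numeric order (FLASV1, FLASV2, ...):
    the denoiser acceptance order, which the placeholder naming rule and the
    stability guarantee key on. Kingdom has no identity threshold; every
    sequence is assigned to a single cluster seeded by the first FL-ASV,
    used only as a fallback when the backbone provides no kingdom.
    """
    out: dict[str, ClusterSet] = {}
    if flasvs:
        first = flasvs[0].id
        out["kingdom"] = ClusterSet(
            rank="kingdom",
            threshold=None,
            assignments={rec.id: first for rec in flasvs},
            centroid_order=[first],
        )
    else:
        out["kingdom"] = ClusterSet(
            rank="kingdom", threshold=None, assignments={}, centroid_order=[]
        )
    for rank in CLUSTERED_RANKS:
        out[rank] = greedy_cluster(flasvs, thresholds[rank], rank=rank, scoring=scoring)
    return out
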