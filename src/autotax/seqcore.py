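"""Sequence-level computation.

Percent identity is defined over a global Needleman-Wunsch alignment
(match +1, mismatch -2, gap open -10, gap extend -1, terminal gaps free):
identity = matches / alignment columns, where terminal-gap columns are
excluded and internal-gap columns count as differences. This mirrors the
identity definition USEARCH applies in ``-usearch_global`` searches.

The denoiser follows the UNOISE abundance-skew rule: a unique sequence M
merges into an already-accepted centroid C when

    size(M) / size(C) <= beta(d) = 1 / 2^(alpha * d + 1)

with d the Levenshtein distance between M and C (unit costs, via edlib).

Chimera screening is a deliberately simplified two-parent reference model
(see :func:`chimera_screen`), not a reimplementation of UCHIME2 scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import Align

from .records import DenoiseParams, Hit, SeqRecord, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignScoring:
    """Global-alignment scoring constants (USEARCH-like defaults)."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -10.0
    gap_extend: float = -1.0


DEFAULT_SCORING = AlignScoring()

_aligner_cache: dict[AlignScoring, Align.PairwiseAligner] = {}


def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    try:
        return _aligner_cache[scoring]
    except KeyError:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = scoring.match
        a.mismatch_score = scoring.mismatch
        a.open_gap_score = scoring.gap_open
        a.extend_gap_score = scoring.gap_extend
        a.end_gap_score = 0  # terminal gaps are free
        _aligner_cache[scoring] = a
        return a


def _identity_from_rows(row_a: str, row_b: str) -> tuple[float, int]:
    """Identity percent and counted columns from two gapped alignment rows."""
    n = len(row_a)
    first = 0
    while first < n and (row_a[first] == "-" or row_b[first] == "-"):
        first += 1
    last = n - 1
    while last >= 0 and (row_a[last] == "-" or row_b[last] == "-"):
        last -= 1
    if last < first:  # alignment is all terminal gaps (disjoint placement)
        return 0.0, 0
    cols = last - first + 1
    matches = sum(
        1
        for i in range(first, last + 1)
        if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    return 100.0 * matches / cols, cols


def global_identity(
    a: SeqRecord | str,
    b: SeqRecord | str,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> float:
    """Percent identity of two sequences under global alignment."""
    return global_identity_cols(a, b, scoring)[0]


def global_identity_cols(
    a: SeqRecord | str,
    b: SeqRecord | str,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> tuple[float, int]:
    """Identity plus the number of counted (non-terminal-gap) columns."""
    sa = a.seq if isinstance(a, SeqRecord) else a
    sb = b.seq if isinstance(b, SeqRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    if sa == sb:
        return 100.0, len(sa)
    if sb < sa:  # canonical operand order: identity is symmetric, but the
        sa, sb = sb, sa  # aligner's co-optimal tie-break depends on order
    aln = _aligner(scoring).align(sa, sb)[0]
    return _identity_from_rows(str(aln[0]), str(aln[1]))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def orient(
    seqs: Iterable[SeqRecord],
    reference_db: Sequence[SeqRecord] | Sequence[str],
    k: int = 12,
) -> list[SeqRecord]:
    """Orient sequences to the reference strand by shared k-mer counts.

    Each sequence is emitted as-is or reverse-complemented, whichever strand
    shares more k-mers with the reference set (forward wins ties). Sequences
    sharing no k-mer on either strand are dropped and logged.
    """
    refs = [r.seq if isinstance(r, SeqRecord) else r for r in reference_db]
    if not refs:
        raise ValueError("orient requires a non-empty reference database")
    ref_kmers: set[str] = set()
    for seq in refs:
        ref_kmers |= _kmers(seq, k)
    out: list[SeqRecord] = []
    n_dropped = n_flipped = 0
    for rec in seqs:
        fwd = len(_kmers(rec.seq, k) & ref_kmers)
        rc = reverse_complement(rec.seq)
        rev = len(_kmers(rc, k) & ref_kmers)
        if fwd == 0 and rev == 0:
            n_dropped += 1
            logger.info("orient: dropping %s (no shared %d-mers)", rec.id, k)
            continue
        if rev > fwd:
            out.append(SeqRecord(id=rec.id, seq=rc, size=rec.size))
            n_flipped += 1
        else:
            out.append(rec)
    logger.info(
        "orient: kept %d, flipped %d, dropped %d", len(out), n_flipped, n_dropped
    )
    return out


def dereplicate(seqs: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Collapse exact duplicates (plus strand only) into sized uniques.

    Output is sorted by size descending, ties by first appearance, so a
    single-threaded rerun is byte-reproducible.
    """
    classes: dict[str, tuple[int, str, int]] = {}
    for idx, rec in enumerate(seqs):
        if rec.seq in classes:
            first_idx, first_id, count = classes[rec.seq]
            classes[rec.seq] = (first_idx, first_id, count + 1)
        else:
            classes[rec.seq] = (idx, rec.id, 1)
    ordered = sorted(classes.items(), key=lambda kv: (-kv[1][2], kv[1][0]))
    return [
        SeqRecord(id=first_id, seq=seq, size=count)
        for seq, (first_idx, first_id, count) in ordered
    ]


def unoise_beta(d: int, alpha: float = 2.0) -> float:
    """UNOISE abundance-skew threshold beta(d) = 1 / 2^(alpha*d + 1)."""
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def denoise(
    uniques: Sequence[SeqRecord], params: DenoiseParams = DenoiseParams()
) -> list[SeqRecord]:
    """UNOISE-style greedy denoising of sized uniques into FL-ASVs.

    Uniques are visited in descending-abundance order (input order breaks
    ties). A unique merges into the first accepted centroid whose skew test
    passes; otherwise it founds a new centroid if size >= minsize. Centroid
    sizes are the founding sizes (not accumulated), keeping the pass
    order-deterministic. Accepted centroids are renamed FLASV1..FLASVn in
    acceptance order.
    """
    if any(u.size is None for u in uniques):
        raise ValueError("denoise requires sized uniques (run dereplicate first)")
    ordered = sorted(
        range(len(uniques)), key=lambda i: (-uniques[i].size, i)
    )  # stable: size desc, then input order
    centroids: list[SeqRecord] = []
    for i in ordered:
        u = uniques[i]
        merged = False
        for c in centroids:
            d = edlib.align(u.seq, c.seq, task="distance")["editDistance"]
            if u.size / c.size <= unoise_beta(d, params.alpha):
                merged = True
                break
        if not merged and u.size >= params.minsize:
            centroids.append(u)
    return [
        SeqRecord(id=f"FLASV{n}", seq=c.seq, size=c.size)
        for n, c in enumerate(centroids, start=1)
    ]


def cluster_otus_99(
    uniques: Sequence[SeqRecord], threshold: float = 99.0
) -> list[SeqRecord]:
    """Greedy 99%-identity centroid clustering of sized uniques (pre-chimera
    FL-OTU candidates). Input is visited size-descending; singletons are
    eligible (no minsize — rare-biosphere coverage is the point)."""
    from .denovo_cluster import greedy_cluster

    if any(u.size is None for u in uniques):
        raise ValueError("cluster_otus_99 requires sized uniques")
    ordered = sorted(range(len(uniques)), key=lambda i: (-uniques[i].size, i))
    in_order = [uniques[i] for i in ordered]
    cs = greedy_cluster(in_order, threshold)
    by_id = {u.id: u for u in in_order}
    return [by_id[cid] for cid in cs.centroid_order]


def _match_profile(
    candidate: str, parent: str, scoring: AlignScoring
) -> np.ndarray:
    """Boolean per-candidate-position match array against one parent."""
    aln = _aligner(scoring).align(candidate, parent)[0]
    row_c, row_p = str(aln[0]), str(aln[1])
    out = np.zeros(len(candidate), dtype=bool)
    pos = 0
    for cc, pc in zip(row_c, row_p):
        if cc != "-":
            if pc != "-" and cc == pc:
                out[pos] = True
            pos += 1
    return out


def chimera_screen(
    candidates: Sequence[SeqRecord],
    reference_flasvs: Sequence[SeqRecord],
    divergence_margin: float = 1.0,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Simplified two-parent reference chimera screen.

    For each candidate, s1 is the best single-parent identity and s2 the best
    two-segment model identity: a prefix explained by one reference and a
    suffix by another, maximised over ordered reference pairs and the
    breakpoint. A candidate is flagged when the chimeric model is perfect
    while no single parent is (s2 = 100 > s1), or when the chimeric model
    beats the best single parent by at least ``divergence_margin`` points.

    Both identities here are matches over candidate length (the per-position
    match-profile combination); this is a documented simplification of
    UCHIME2's vote model. Candidates identical to a reference sequence are
    removed from the kept set (exact-match deduplication), never flagged.

    Returns ``(kept, flagged)``.
    """
    if not reference_flasvs:
        raise ValueError("chimera_screen requires a non-empty reference set")
    ref_seqs = {r.seq for r in reference_flasvs}
    kept: list[SeqRecord] = []
    flagged: list[SeqRecord] = []
    for cand in candidates:
        if cand.seq in ref_seqs:
            logger.info("chimera_screen: %s identical to an FL-ASV, deduplicated", cand.id)
            continue
        n = len(cand.seq)
        profiles = [
            _match_profile(cand.seq, ref.seq, scoring) for ref in reference_flasvs
        ]
        totals = np.array([p.sum() for p in profiles])
        s1 = 100.0 * totals.max() / n
        cums = [np.concatenate(([0], np.cumsum(p))) for p in profiles]
        best = 0
        for i, cum_l in enumerate(cums):
            for j, cum_r in enumerate(cums):
                if i == j:
                    continue
                # matches(L-prefix) + matches(R-suffix), maximised over split
                combined = (cum_l - cum_r).max() + totals[j]
                if combined > best:
                    best = combined
        s2 = 100.0 * best / n
        is_chimera = (s2 >= 100.0 and s1 < 100.0) or (
            s2 > s1 and s2 - s1 >= divergence_margin
        )
        (flagged if is_chimera else kept).append(cand)
    return kept, flagged


def top_hit(
    query: SeqRecord,
    db: Sequence[SeqRecord],
    scoring: AlignScoring = DEFAULT_SCORING,
) -> Hit:
    """Exhaustive best match of ``query`` against every ``db`` record.

    No heuristic rejection or early termination; ties broken by database
    input order (first wins).
    """
    if not db:
        raise ValueError("top_hit requires a non-empty database")
    best_identity = -1.0
    best_cols = 0
    best_target = db[0].id
    for rec in db:
        ident, cols = global_identity_cols(query, rec, scoring)
        if ident > best_identity:
            best_identity, best_cols, best_target = ident, cols, rec.id
    return Hit(
        query_id=query.id,
        target_id=best_target,
        identity=best_identity,
        aligned_cols=best_cols,
    )
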