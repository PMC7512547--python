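"""Classifier benchmarking: a SINTAX-style k-mer bootstrap classifier,
*in silico* amplicon extraction, amplicon self-classification, and
leave-one-out validation with the standard per-rank metrics

    accuracy = TP / (K + OC)      misclassification rate   = MC / K
    overclassification rate = OC / L    true-positive rate = TP / K
    underclassification rate = UC / K

where K is the number of test sequences with a known taxonomy at the rank
and L the number without.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .records import (
    RANKS,
    RankThresholds,
    SeqRecord,
    TaxProfile,
    reverse_complement,
)
from .seqcore import AlignScoring, DEFAULT_SCORING, top_hit
from .taxonomy_engine import trim_taxonomy


@dataclass(frozen=True)
class MetricCounts:
    """Per-rank confusion counts for a classification benchmark."""

    K: int
    L: int
    TP: int
    MC: int
    OC: int
    UC: int

    def __post_init__(self) -> None:
        for fieldname in ("K", "L", "TP", "MC", "OC", "UC"):
            if getattr(self, fieldname) < 0:
                raise ValueError(f"{fieldname} must be non-negative")
        if self.TP + self.MC + self.UC > self.K:
            raise ValueError("TP + MC + UC cannot exceed K")
        if self.OC > self.L:
            raise ValueError("OC cannot exceed L")


def classification_metrics(c: MetricCounts) -> dict[str, float | None]:
    """The five benchmark rates; ``None`` marks an undefined denominator."""
    k_rate = lambda x: x / c.K if c.K > 0 else None  # noqa: E731
    return {
        "accuracy": c.TP / (c.K + c.OC) if (c.K + c.OC) > 0 else None,
        "mc_rate": k_rate(c.MC),
        "oc_rate": c.OC / c.L if c.L > 0 else None,
        "tp_rate": k_rate(c.TP),
        "uc_rate": k_rate(c.UC),
    }


@dataclass(frozen=True)
class PrimerPair:
    """An amplicon primer pair; reverse is given 5'->3' on the reverse strand."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            if not primer or not re.fullmatch(r"[ACGTUMRWSYKVHDBN]+", primer.upper()):
                raise ValueError(f"primer {primer!r} is not an IUPAC DNA string")


#: Commonly used 16S primer pairs by variable region. The V1-V3 pair
#: (27F/534R) is the pair used for the short-read benchmarking; the other
#: sequences are the standard published primers for those region names.
PRIMER_SETS: dict[str, PrimerPair] = {
    "V1-V3": PrimerPair("V1-V3", "AGAGTTTGATCCTGGCTCAG", "ATTACCGCGGCTGCTGG"),
    "V3-V4": PrimerPair("V3-V4", "CCTACGGGNGGCWGCAG", "GACTACHVGGGTATCTAATCC"),
    "V4": PrimerPair("V4", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT"),
    "V4-V5": PrimerPair("V4-V5", "GTGYCAGCMGCCGCGGTAA", "CCGYCAATTYMTTTRAGTTT"),
    "V3-V5": PrimerPair("V3-V5", "CCTACGGGAGGCAGCAG", "CCGTCAATTCMTTTRAGT"),
    "V5-V7": PrimerPair("V5-V7", "AACMGGATTAGATACCCKG", "ACGTCATCCCCACCTTCC"),
    "V5-V8": PrimerPair("V5-V8", "AAACTYAAAKGAATTGRCGG", "ACGGGCGGTGTGTRC"),
    "V1-V8": PrimerPair("V1-V8", "AGAGTTTGATCCTGGCTCAG", "ACGGGCGGTGTGTRC"),
    "V1-V9": PrimerPair("V1-V9", "AGAGTTTGATCCTGGCTCAG", "GGTTACCTTGTTACGACTT"),
}


def _iupac_regex(primer: str) -> re.Pattern[str]:
    return re.compile(
        "".join(f"[{ambiguous_dna_values[ch]}]" for ch in primer.upper())
    )


def extract_amplicon(
    seq: SeqRecord | str,
    primers: PrimerPair,
    trunc_len: int | None = None,
    direction: str = "merged",
    keep_reverse_site: bool = False,
) -> str | None:
    """*In silico* PCR: the region between primer sites on the plus strand.

    Primer matching is IUPAC-aware and exact (0 mismatches). The forward
    primer is removed; the reverse priming site is removed by default
    (``keep_reverse_site`` retains it). ``direction`` selects the read:
    ``merged`` returns the whole amplicon, ``fwd`` the first ``trunc_len``
    bases, ``rev`` the first ``trunc_len`` bases read from the reverse
    primer (reverse-complemented). Returns ``None`` when either priming site
    is absent.
    """
    s = seq.seq if isinstance(seq, SeqRecord) else seq.upper()
    fwd = _iupac_regex(primers.forward).search(s)
    if fwd is None:
        return None
    rev = _iupac_regex(reverse_complement(primers.reverse)).search(s, fwd.end())
    if rev is None:
        return None
    end = rev.end() if keep_reverse_site else rev.start()
    amplicon = s[fwd.end() : end]
    if not amplicon:
        return None
    if direction == "merged":
        return amplicon
    if trunc_len is None:
        raise ValueError(f"direction {direction!r} requires trunc_len")
    if direction == "fwd":
        return amplicon[:trunc_len]
    if direction == "rev":
        return reverse_complement(amplicon)[:trunc_len]
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class SintaxParams:
    """Bootstrap constants of the k-mer classifier."""

    k: int = 8
    bootstraps: int = 100
    subset_size: int = 32
    cutoff: float = 0.8


class SintaxClassifier:
    """SINTAX-style bootstrap classifier over a reference database.

    Each bootstrap iteration draws a random subset of the query's k-mers
    (with replacement), scores every reference by how many drawn k-mers it
    contains, and takes the top-scoring reference's lineage as one vote
    (ties go to the earlier reference). Per-rank confidence is the fraction
    of votes for the winning lineage prefix, so confidence is monotone
    non-increasing with rank depth. Ranks at or above the cutoff are
    reported; both strands are tried and the better one kept.
    """

    def __init__(
        self,
        reference_db: Sequence[tuple[SeqRecord, TaxProfile]],
        params: SintaxParams = SintaxParams(),
    ) -> None:
        if not reference_db:
            raise ValueError("reference database is empty")
        self.params = params
        self.records = list(reference_db)
        self.ref_kmers = [
            frozenset(
                rec.seq[i : i + params.k]
                for i in range(len(rec.seq) - params.k + 1)
            )
            for rec, _ in self.records
        ]
        self.all_kmers: frozenset[str] = frozenset().union(*self.ref_kmers)

    def _query_kmers(self, seq: str) -> list[str]:
        k = self.params.k
        return [seq[i : i + k] for i in range(len(seq) - k + 1)]

    def classify(
        self, query: SeqRecord | str, seed: int = 0, both_strands: bool = True
    ) -> tuple[TaxProfile, dict[str, float]]:
        """Classify one query; returns (reported profile, per-rank confidence)."""
        s = query.seq if isinstance(query, SeqRecord) else query.upper()
        p = self.params
        if len(s) < p.k:
            return TaxProfile(), {rank: 0.0 for rank in RANKS}
        strand_seq = s
        if both_strands:
            rc = reverse_complement(s)
            fwd_overlap = len(set(self._query_kmers(s)) & self.all_kmers)
            rev_overlap = len(set(self._query_kmers(rc)) & self.all_kmers)
            if rev_overlap > fwd_overlap:
                strand_seq = rc
        kmers = self._query_kmers(strand_seq)
        if not set(kmers) & self.all_kmers:
            return TaxProfile(), {rank: 0.0 for rank in RANKS}
        rng = np.random.default_rng(seed)
        votes: list[tuple[str, ...]] = []
        for _ in range(p.bootstraps):
            drawn = rng.integers(0, len(kmers), p.subset_size)
            sampled = [kmers[i] for i in drawn]
            best_score, best_idx = -1, 0
            for idx, ref_set in enumerate(self.ref_kmers):
                score = sum(1 for km in sampled if km in ref_set)
                if score > best_score:
                    best_score, best_idx = score, idx
            votes.append(self.records[best_idx][1].ranks)
        confidences: dict[str, float] = {}
        names: list[str] = []
        prefix: tuple[str, ...] = ()
        for depth, rank in enumerate(RANKS):
            counts: dict[tuple[str, ...], int] = {}
            for v in votes:
                if v[:depth] == prefix:
                    key = v[: depth + 1]
                    counts[key] = counts.get(key, 0) + 1
            if not counts:
                confidences[rank] = 0.0
                continue
            best_prefix = max(counts, key=lambda kk: (counts[kk], kk))
            conf = counts[best_prefix] / p.bootstraps
            confidences[rank] = conf
            if conf >= p.cutoff:
                names.append(best_prefix[-1])
                prefix = best_prefix
            else:
                break
        return TaxProfile.from_names(names, provenance="backbone"), confidences


def sintax_classify(
    query: SeqRecord | str,
    reference_db: Sequence[tuple[SeqRecord, TaxProfile]],
    cutoff: float = 0.8,
    seed: int = 0,
    params: SintaxParams | None = None,
    both_strands: bool = True,
) -> tuple[TaxProfile, dict[str, float]]:
    """One-shot wrapper around :class:`SintaxClassifier`."""
    if params is None:
        params = SintaxParams(cutoff=cutoff)
    clf = SintaxClassifier(reference_db, params)
    return clf.classify(query, seed=seed, both_strands=both_strands)


def self_classification_test(
    flasv_db: Sequence[tuple[SeqRecord, TaxProfile]],
    primers: PrimerPair,
    direction: str = "merged",
    trunc_len: int | None = 200,
    cutoff: float = 0.8,
    seed: int = 0,
    params: SintaxParams | None = None,
) -> pd.DataFrame:
    """Extract amplicons from every reference and classify them back.

    For each rank, the fraction of amplifiable references whose amplicon is
    classified to the same name (correct), a different name (wrong), or no
    name (unclassified); the three fractions sum to 1.
    """
    for _, profile in flasv_db:
        if not profile.is_complete():
            raise ValueError("self-classification requires complete taxonomies")
    if params is None:
        params = SintaxParams(cutoff=cutoff)
    clf = SintaxClassifier(flasv_db, params)
    tallies = {rank: {"correct": 0, "wrong": 0, "unclassified": 0} for rank in RANKS}
    n_amplifiable = 0
    for idx, (rec, truth) in enumerate(flasv_db):
        amplicon = extract_amplicon(
            rec.seq, primers, trunc_len=trunc_len, direction=direction
        )
        if amplicon is None:
            continue
        n_amplifiable += 1
        predicted, _ = clf.classify(amplicon, seed=seed + idx)
        for rank in RANKS:
            pred = predicted.name(rank)
            if not pred:
                tallies[rank]["unclassified"] += 1
            elif pred == truth.name(rank):
                tallies[rank]["correct"] += 1
            else:
                tallies[rank]["wrong"] += 1
    rows = []
    for rank in RANKS:
        t = tallies[rank]
        denom = n_amplifiable if n_amplifiable else 1
        rows.append(
            {
                "rank": rank,
                "n_amplifiable": n_amplifiable,
                "correct": t["correct"] / denom,
                "wrong": t["wrong"] / denom,
                "unclassified": t["unclassified"] / denom,
            }
        )
    return pd.DataFrame(rows)


_IMPROPER_RE = re.compile(
    r"uncultured|unknown|incertae\s*sedis|possible", re.IGNORECASE
)


def is_improper_name(name: str) -> bool:
    """Names that disqualify a database entry from benchmark truth."""
    return bool(_IMPROPER_RE.search(name))


def leave_one_out(
    clean_db: Sequence[tuple[SeqRecord, TaxProfile]],
    n_test: int,
    seed: int = 0,
    thresholds: RankThresholds = RankThresholds(),
    scoring: AlignScoring = DEFAULT_SCORING,
) -> tuple[dict[str, MetricCounts], pd.DataFrame]:
    """Leave-one-out benchmark of the top-hit + trimming assignment path.

    ``n_test`` records are sampled without replacement (seeded) as the test
    set; each is classified against the remainder via exhaustive top-hit
    search followed by threshold trimming, and tallied per rank against its
    held-out taxonomy.
    """
    if n_test >= len(clean_db):
        raise ValueError("n_test must be smaller than the database")
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(len(clean_db), size=n_test, replace=False).tolist())
    train = [(rec, tax) for i, (rec, tax) in enumerate(clean_db) if i not in test_idx]
    train_recs = [rec for rec, _ in train]
    train_tax = {rec.id: tax for rec, tax in train}
    counts = {rank: {"K": 0, "L": 0, "TP": 0, "MC": 0, "OC": 0, "UC": 0} for rank in RANKS}
    for i in sorted(test_idx):
        rec, truth = clean_db[i]
        hit = top_hit(rec, train_recs, scoring)
        predicted = trim_taxonomy(train_tax[hit.target_id], hit.identity, thresholds)
        for rank in RANKS:
            true_name = truth.name(rank)
            pred_name = predicted.name(rank)
            c = counts[rank]
            if true_name:
                c["K"] += 1
                if not pred_name:
                    c["UC"] += 1
                elif pred_name == true_name:
                    c["TP"] += 1
                else:
                    c["MC"] += 1
            else:
                c["L"] += 1
                if pred_name:
                    c["OC"] += 1
    metric_counts = {rank: MetricCounts(**c) for rank, c in counts.items()}
    rows = []
    for rank, mc in metric_counts.items():
        row = {"rank": rank, **{f: getattr(mc, f) for f in ("K", "L", "TP", "MC", "OC", "UC")}}
        row.update(classification_metrics(mc))
        rows.append(row)
    return metric_counts, pd.DataFrame(rows)
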