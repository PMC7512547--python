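"""Core domain types shared across the pipeline.

The pipeline manipulates three kinds of objects: nucleotide sequence records
(optionally carrying a dereplication abundance), seven-rank taxonomic
profiles with per-rank provenance, and the rank-specific percent-identity
thresholds that gate both taxonomy trimming and *de novo* clustering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: one-letter rank codes used in placeholder names and SINTAX headers
RANK_CODES: Mapping[str, str] = dict(zip(RANKS, "kpcofgs"))

#: ranks that have an identity threshold (kingdom has none)
CLUSTERED_RANKS: tuple[str, ...] = RANKS[1:]

PROV_BACKBONE = "backbone"
PROV_TYPESTRAIN = "typestrain"
PROV_DENOVO = "denovo"
PROV_EMPTY = "empty"

_PROVENANCES = frozenset({PROV_BACKBONE, PROV_TYPESTRAIN, PROV_DENOVO, PROV_EMPTY})

_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-ambiguous) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


@dataclass
class SeqRecord:
    """A named nucleotide sequence, optionally with a ``;size=N;`` abundance.

    ``id`` must contain no whitespace; ``seq`` is stored uppercase DNA.
    """

    id: str
    seq: str
    size: int | None = None

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")
        self.seq = normalize_seq(self.seq)
        if self.size is not None and self.size < 1:
            raise ValueError(f"size must be >= 1, got {self.size} for {self.id!r}")

    def with_id(self, new_id: str) -> "SeqRecord":
        return SeqRecord(id=new_id, seq=self.seq, size=self.size)


# FL-ASV canonical ids are FLASV1, FLASV2, ...
_FLASV_RE = re.compile(r"^FLASV(\d+)$")


def flasv_number(flasv_id: str) -> int:
    """Canonical FL-ASV number from an id such as ``FLASV12``."""
    m = _FLASV_RE.match(flasv_id)
    if not m:
        raise ValueError(f"not a canonical FL-ASV id: {flasv_id!r}")
    return int(m.group(1))


@dataclass(frozen=True)
class TaxProfile:
    """Seven ordered rank names with per-rank provenance.

    An empty string marks a missing rank; provenance is ``empty`` iff the
    rank name is empty. After the final merge, names must be contiguous from
    kingdom down (no gap above a filled rank).
    """

    ranks: tuple[str, ...] = ("",) * 7
    provenance: tuple[str, ...] = (PROV_EMPTY,) * 7

    def __post_init__(self) -> None:
        if len(self.ranks) != 7 or len(self.provenance) != 7:
            raise ValueError("TaxProfile requires exactly 7 ranks")
        for name, prov in zip(self.ranks, self.provenance):
            if prov not in _PROVENANCES:
                raise ValueError(f"unknown provenance {prov!r}")
            if (name == "") != (prov == PROV_EMPTY):
                raise ValueError(
                    f"provenance {prov!r} inconsistent with name {name!r}"
                )

    @classmethod
    def from_names(
        cls, names: list[str] | tuple[str, ...], provenance: str = PROV_BACKBONE
    ) -> "TaxProfile":
        """Build a profile from up to 7 top-down names, one provenance."""
        if len(names) > 7:
            raise ValueError(f"at most 7 ranks, got {len(names)}")
        padded = tuple(names) + ("",) * (7 - len(names))
        provs = tuple(provenance if n else PROV_EMPTY for n in padded)
        return cls(ranks=padded, provenance=provs)

    def name(self, rank: str) -> str:
        return self.ranks[RANKS.index(rank)]

    def prov(self, rank: str) -> str:
        return self.provenance[RANKS.index(rank)]

    def replace(self, rank: str, name: str, provenance: str) -> "TaxProfile":
        i = RANKS.index(rank)
        ranks = self.ranks[:i] + (name,) + self.ranks[i + 1 :]
        provs = self.provenance[:i] + (provenance,) + self.provenance[i + 1 :]
        return TaxProfile(ranks=ranks, provenance=provs)

    def is_complete(self) -> bool:
        return all(self.ranks)

    def is_contiguous(self) -> bool:
        """No empty rank above a non-empty rank."""
        seen_empty = False
        for name in self.ranks:
            if not name:
                seen_empty = True
            elif seen_empty:
                return False
        return True

    def items(self) -> Iterator[tuple[str, str, str]]:
        yield from zip(RANKS, self.ranks, self.provenance)


_YARZA = {
    "phylum": 75.0,
    "class": 78.5,
    "order": 82.0,
    "family": 86.5,
    "genus": 94.5,
    "species": 98.7,
}


@dataclass(frozen=True)
class RankThresholds:
    """Rank-specific percent-identity cutoffs (the 16S literature's
    statistically derived values by default).

    Used both to trim adopted backbone taxonomy (retain rank iff best-hit
    identity >= threshold) and as the *de novo* clustering radii. Kingdom has
    no threshold. Values must be strictly increasing from phylum to species.
    """

    by_rank: Mapping[str, float] = field(default_factory=lambda: dict(_YARZA))

    def __post_init__(self) -> None:
        if tuple(self.by_rank) != CLUSTERED_RANKS:
            raise ValueError(
                f"thresholds must cover exactly {CLUSTERED_RANKS} in order"
            )
        vals = list(self.by_rank.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must be strictly increasing phylum->species")
        if not all(0 < v <= 100 for v in vals):
            raise ValueError("thresholds must be percentages in (0, 100]")

    def __getitem__(self, rank: str) -> float:
        return self.by_rank[rank]

    def items(self):
        return self.by_rank.items()


@dataclass(frozen=True)
class Hit:
    """Best global-alignment match of a query against a database."""

    query_id: str
    target_id: str
    identity: float
    aligned_cols: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity out of range: {self.identity}")


@dataclass(frozen=True)
class DenoiseParams:
    """UNOISE parameters: minimum abundance to found a centroid, and alpha."""

    minsize: int = 2
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.minsize < 1:
            raise ValueError("minsize must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class ClusterSet:
    """Per-rank greedy clustering result over FL-ASVs, order-stable.

    ``assignments`` maps every member id to its centroid id; every centroid
    is its own member. ``centroid_order`` lists centroids in founding order.
    """

    rank: str | None
    threshold: float | None
    assignments: dict[str, str]
    centroid_order: list[str]

    def members_of(self, centroid_id: str) -> list[str]:
        return [m for m, c in self.assignments.items() if c == centroid_id]

    def __len__(self) -> int:
        return len(self.centroid_order)
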