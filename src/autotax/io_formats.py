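"""Readers and writers for every file dialect the pipeline touches.

Dialects: plain FASTA with the USEARCH ``;size=N;`` abundance suffix, the
SILVA-style backbone FASTA whose headers carry ``ACCESSION Name1;...;NameK``
lineages, SINTAX reference FASTA (``;tax=k:...,p:...;`` headers), the QIIME
two-file database (FASTA + tab-separated taxonomy), and aligned FASTA
exports in which ``.`` marks terminal gaps (truncated sequences).

Taxon names are sanitised on write: delimiter characters (comma, colon,
semicolon, whitespace) become underscores so downstream parsers never see
them inside a name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .records import (
    PROV_EMPTY,
    RANK_CODES,
    RANKS,
    SeqRecord,
    TaxProfile,
)

#: FASTA line-wrap width used by all writers (0 = no wrapping)
FASTA_WRAP = 80

#: 1-based inclusive alignment windows used to select full-length sequences
#: from the global SILVA alignment (bacterial 27F..1391R, archaeal
#: 20F..SSU1000ArR primer sites).
BACTERIA_WINDOW = (1044, 41788)
ARCHAEA_WINDOW = (1041, 32818)

_SIZE_RE = re.compile(r";size=(\d+);?$")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending location."""


@dataclass(frozen=True)
class BackboneRecord:
    """A backbone reference sequence with its parsed (<= 6 rank) taxonomy."""

    accession: str
    seq: str
    tax: TaxProfile


def _check_plain_text(path: Path) -> None:
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header before sequence data"
                )
            return


def read_fasta(path: str | PathLike, parse_size: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects, order preserved.

    With ``parse_size`` the USEARCH ``;size=N;`` suffix is stripped from the
    id and stored in the ``size`` field. Duplicate ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_plain_text(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        size = None
        if parse_size:
            m = _SIZE_RE.search(rid)
            if m:
                size = int(m.group(1))
                rid = rid[: m.start()]
        if not rec.seq:
            raise FastaParseError(f"{path}: record {rid!r} has an empty sequence")
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        records.append(SeqRecord(id=rid, seq=str(rec.seq), size=size))
    return records


def _wrap(seq: str) -> str:
    if FASTA_WRAP <= 0:
        return seq
    return "\n".join(seq[i : i + FASTA_WRAP] for i in range(0, len(seq), FASTA_WRAP))


def write_fasta(
    records: Iterable[SeqRecord], path: str | PathLike, write_size: bool = False
) -> None:
    """Write records as FASTA; ``write_size`` appends ``;size=N;`` suffixes."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if write_size and rec.size is not None:
                header = f"{rec.id};size={rec.size};"
            fh.write(f">{header}\n{_wrap(rec.seq)}\n")


def sanitize_name(name: str) -> str:
    """Replace delimiter characters in a taxon name with underscores."""
    return re.sub(r"[,:;\s]", "_", name.strip())


def parse_backbone_header(header: str) -> tuple[str, TaxProfile]:
    """Parse ``>ACCESSION Name1;...;NameK`` (K <= 6) backbone headers.

    The backbone taxonomy is not curated at the species level, so species is
    always left empty and a 7-field lineage is rejected rather than kept.
    """
    header = header.lstrip(">").strip()
    if not header:
        raise ValueError("empty backbone header")
    parts = header.split(None, 1)
    accession = parts[0]
    names: list[str] = []
    if len(parts) == 2:
        names = [n.strip() for n in parts[1].split(";")]
        while names and not names[-1]:
            names.pop()
        if any(not n for n in names):
            raise ValueError(f"empty rank name in backbone header {header!r}")
    if len(names) > 6:
        raise ValueError(
            f"backbone header {accession!r} carries {len(names)} ranks; "
            "species-level text in backbone lineages is rejected (max 6)"
        )
    return accession, TaxProfile.from_names(names)


def read_backbone_fasta(path: str | PathLike) -> list[BackboneRecord]:
    """Read a backbone reference FASTA with semicolon-lineage headers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_plain_text(path)
    out: list[BackboneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, tax = parse_backbone_header(rec.description)
        if accession in seen:
            raise FastaParseError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        out.append(
            BackboneRecord(
                accession=accession,
                seq=SeqRecord(id=accession, seq=str(rec.seq)).seq,
                tax=tax,
            )
        )
    return out


def write_backbone_fasta(records: Iterable[BackboneRecord], path: str | PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            names = [n for n in rec.tax.ranks if n]
            fh.write(f">{rec.accession} {';'.join(names)}\n{_wrap(rec.seq)}\n")


def _require_complete(profile: TaxProfile, rid: str) -> None:
    if not profile.is_complete():
        missing = [r for r, n, _ in profile.items() if not n]
        raise ValueError(
            f"record {rid!r} has an incomplete taxonomy (missing {missing}); "
            "database writers require all 7 ranks"
        )


def write_sintax_db(
    records: Sequence[tuple[SeqRecord, TaxProfile]], path: str | PathLike
) -> None:
    """Write a SINTAX-formatted reference FASTA.

    Headers look like ``>ID;tax=k:K,p:P,c:C,o:O,f:F,g:G,s:S;`` with one-letter
    rank codes; every profile must be complete.
    """
    with open(path, "w") as fh:
        for rec, profile in records:
            _require_complete(profile, rec.id)
            tax = ",".join(
                f"{RANK_CODES[rank]}:{sanitize_name(name)}"
                for rank, name, _ in profile.items()
            )
            fh.write(f">{rec.id};tax={tax};\n{_wrap(rec.seq)}\n")


def write_qiime_db(
    records: Sequence[tuple[SeqRecord, TaxProfile]],
    fasta_path: str | PathLike,
    tax_path: str | PathLike,
) -> None:
    """Write the QIIME two-file database: plain FASTA + tab-separated taxonomy.

    Taxonomy rows look like ``ID<TAB>k__K; p__P; c__C; o__O; f__F; g__G; s__S``.
    """
    with open(fasta_path, "w") as ffh, open(tax_path, "w") as tfh:
        for rec, profile in records:
            _require_complete(profile, rec.id)
            ffh.write(f">{rec.id}\n{_wrap(rec.seq)}\n")
            tax = "; ".join(
                f"{RANK_CODES[rank]}__{sanitize_name(name)}"
                for rank, name, _ in profile.items()
            )
            tfh.write(f"{rec.id}\t{tax}\n")


def read_qiime_tax(path: str | PathLike) -> dict[str, TaxProfile]:
    """Parse a QIIME taxonomy TSV back into complete :class:`TaxProfile`s."""
    out: dict[str, TaxProfile] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                rid, tax = line.split("\t")
            except ValueError as exc:
                raise FastaParseError(f"{path}: line {lineno}: not two columns") from exc
            names = []
            for rank, fieldtext in zip(RANKS, tax.split("; ")):
                prefix = f"{RANK_CODES[rank]}__"
                if not fieldtext.startswith(prefix):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected {prefix!r} prefix"
                    )
                names.append(fieldtext[len(prefix) :])
            out[rid] = TaxProfile.from_names(names)
    return out


def read_sintax_db(path: str | PathLike) -> list[tuple[SeqRecord, TaxProfile]]:
    """Parse a SINTAX reference FASTA back into records + profiles."""
    path = Path(path)
    _check_plain_text(path)
    out: list[tuple[SeqRecord, TaxProfile]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        m = re.search(r";tax=([^;]*);?", header)
        if not m:
            raise FastaParseError(f"{path}: record {rec.id!r} lacks a tax= annotation")
        rid = header.split(";tax=")[0].rstrip(";")
        names = ["" for _ in RANKS]
        for fieldtext in m.group(1).split(","):
            code, _, name = fieldtext.partition(":")
            idx = "kpcofgs".index(code)
            names[idx] = name
        out.append(
            (SeqRecord(id=rid, seq=str(rec.seq)), TaxProfile.from_names(names))
        )
    return out


def select_full_length(
    aligned_fasta: str | PathLike, start_col: int, end_col: int
) -> list[str]:
    """Ids of aligned rows with no ``.`` inside columns [start_col, end_col].

    ``.`` marks terminal gaps in ARB exports and therefore flags truncated
    sequences; column coordinates are 1-based inclusive (ARB convention).
    Defaults for the bacterial and archaeal windows of the global SILVA
    alignment are :data:`BACTERIA_WINDOW` and :data:`ARCHAEA_WINDOW`.
    """
    path = Path(aligned_fasta)
    _check_plain_text(path)
    rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        return []
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged alignment (row lengths {sorted(lengths)})")
    (length,) = lengths
    if not (1 <= start_col < end_col <= length):
        raise ValueError(
            f"invalid window [{start_col}, {end_col}] for alignment of width {length}"
        )
    return [
        rid for rid, seq in rows if "." not in seq[start_col - 1 : end_col]
    ]


def write_cluster_tsv(cluster_sets: dict, path: str | PathLike) -> None:
    """Serialise ClusterSets as a (member, rank, centroid) TSV."""
    with open(path, "w") as fh:
        fh.write("member\trank\tcentroid\n")
        for rank, cs in cluster_sets.items():
            for member, centroid in cs.assignments.items():
                fh.write(f"{member}\t{rank}\t{centroid}\n")


def write_taxonomy_tsv(
    rows: Sequence[tuple[str, TaxProfile, float | None]], path: str | PathLike
) -> None:
    """Write the 9-column output TSV: id, 7 ranks, best-hit identity."""
    with open(path, "w") as fh:
        fh.write("\t".join(["flasv"] + list(RANKS) + ["identity"]) + "\n")
        for rid, profile, identity in rows:
            ident = "" if identity is None else f"{identity:.2f}"
            fh.write("\t".join([rid] + list(profile.ranks) + [ident]) + "\n")


def write_provenance_tsv(
    rows: Sequence[tuple[str, TaxProfile]], path: str | PathLike
) -> None:
    """Write per-rank provenance (backbone/typestrain/denovo) as TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(["flasv"] + list(RANKS)) + "\n")
        for rid, profile in rows:
            provs = [p if p != PROV_EMPTY else "" for p in profile.provenance]
            fh.write("\t".join([rid] + provs) + "\n")
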