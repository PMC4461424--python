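"""Best-hit taxonomic assignment against a local reference database.

OTU centroids (and raw reads, for confirming which species actually made
it into the sequence data) are compared against a small per-community
FASTA of V4 reference sequences by exact local alignment, not a seeded
heuristic: the databases here hold at most hundreds of records, so a full
Smith-Waterman against every reference is cheap and fully deterministic.

A hit is *positive* when percent identity is at least 90 and the local
alignment spans at least 330 columns; identity counts gap columns in the
denominator (conservative).  References are ranked by alignment score
first (as a similarity-search tool would), because raw identity would let
a spurious handful-of-bases perfect match outrank a genuine full-length
hit at 95% identity; score ties are broken toward higher identity, then
the longer alignment, then the lexicographically smaller species id.
IUPAC ambiguity codes inside references match no base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from ._align import local_align_counts
from .demux_filter import RawRead
from .otu_cluster import ClusteringResult

__all__ = [
    "ReferenceDB",
    "TaxonomicHit",
    "read_reference_db",
    "best_hit",
    "assign_otus",
    "screen_raw_reads",
    "write_assignments",
    "write_rawscreen",
]

MIN_IDENTITY = 90.0
MIN_ALIGNMENT_LENGTH = 330


@dataclass(frozen=True)
class ReferenceDB:
    records: dict[str, str]  # species_id -> reference sequence

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference database is empty")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceDB":
        records = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate reference id {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
        return cls(records)


def read_reference_db(path) -> ReferenceDB:
    return ReferenceDB.from_fasta(path)


@dataclass(frozen=True)
class TaxonomicHit:
    query_id: str
    best_species: str | None
    percent_identity: float
    alignment_length: int
    positive: bool


def best_hit(
    query: str,
    db: ReferenceDB,
    query_id: str = "query",
    min_identity: float = MIN_IDENTITY,
    min_alignment_length: int = MIN_ALIGNMENT_LENGTH,
) -> TaxonomicHit:
    """Best local-alignment hit of a query against every reference."""
    if not query:
        raise ValueError("empty query sequence")
    best: tuple[int, float, int, str] | None = None
    for species_id in sorted(db.records):
        score, match_cols, aligned_cols = local_align_counts(
            query, db.records[species_id]
        )
        if aligned_cols == 0:
            continue
        identity = match_cols / aligned_cols * 100.0
        key = (score, identity, aligned_cols)
        if best is None or key > best[:3]:
            best = (score, identity, aligned_cols, species_id)
    if best is None:
        return TaxonomicHit(query_id, None, 0.0, 0, False)
    _score, identity, aligned_cols, species_id = best
    positive = identity >= min_identity and aligned_cols >= min_alignment_length
    return TaxonomicHit(
        query_id=query_id,
        best_species=species_id,
        percent_identity=identity,
        alignment_length=aligned_cols,
        positive=positive,
    )


def assign_otus(
    result: ClusteringResult,
    db: ReferenceDB,
    min_identity: float = MIN_IDENTITY,
    min_alignment_length: int = MIN_ALIGNMENT_LENGTH,
) -> list[TaxonomicHit]:
    """One best hit per OTU centroid; non-positive hits mean 'no local hit'."""
    return [
        best_hit(
            otu.centroid,
            db,
            query_id=otu.otu_id,
            min_identity=min_identity,
            min_alignment_length=min_alignment_length,
        )
        for otu in result.otus
    ]


def screen_raw_reads(
    reads: Iterable[RawRead],
    db: ReferenceDB,
    min_identity: float = MIN_IDENTITY,
    min_alignment_length: int = MIN_ALIGNMENT_LENGTH,
) -> dict[str, int]:
    """Species confirmed present among tag/primer-stripped raw reads.

    A species counts as successfully amplified and sequenced when at least
    one read yields a positive hit to it.  Returns species -> number of
    supporting reads.  Identical read sequences are collapsed before
    alignment (the hit depends only on the sequence), so cost scales with
    unique sequences, not reads.
    """
    by_seq: dict[str, int] = {}
    for read in reads:
        by_seq[read.sequence] = by_seq.get(read.sequence, 0) + 1
    support: dict[str, int] = {}
    for seq in sorted(by_seq):
        hit = best_hit(
            seq,
            db,
            min_identity=min_identity,
            min_alignment_length=min_alignment_length,
        )
        if hit.positive and hit.best_species is not None:
            support[hit.best_species] = (
                support.get(hit.best_species, 0) + by_seq[seq]
            )
    return support


def write_assignments(path, hits: Sequence[TaxonomicHit]) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tspecies\tidentity\taln_length\tpositive\n")
        for h in hits:
            label = h.best_species if h.positive else "NA"
            fh.write(
                f"{h.query_id}\t{label}\t{h.percent_identity:.2f}"
                f"\t{h.alignment_length}\t{int(h.positive)}\n"
            )


def write_rawscreen(path, support: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn_supporting_reads\n")
        for species in sorted(support):
            fh.write(f"{species}\t{support[species]}\n")
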