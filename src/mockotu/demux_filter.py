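"""Read demultiplexing, trimming, expected-error filtering, dereplication.

The processing chain mirrors the standard greedy-clustering amplicon
workflow for tagged pyrosequencing reads:

1. assign each read to a sample by an exact match of its 10-nt MID tag
   followed by the forward primer (IUPAC degeneracies honoured, zero
   mismatches), stripping the tag+primer region;
2. trim to a fixed length (default 400 nt), discarding shorter reads so
   every retained sequence is globally comparable;
3. discard reads whose expected error count E = sum_i 10^(-Q_i/10),
   computed over the retained positions, exceeds a cutoff (default 0.5);
4. collapse identical sequences to uniques with abundances;
5. optionally drop singletons (uniques observed exactly once within the
   set being clustered).

Reads that fail a stage are counted, never corrected; tag/primer matching
is exact because error-bearing tags cannot be attributed to a sample
safely.  Phred encoding is +33 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "IUPAC",
    "RawRead",
    "FilteredRead",
    "UniqueSequence",
    "FilterConfig",
    "FilterStats",
    "read_fastq",
    "read_tagmap",
    "iupac_match",
    "demultiplex_and_strip",
    "trim_to_length",
    "expected_error",
    "expected_error_filter",
    "dereplicate",
    "apply_singleton_policy",
    "run_filter_chain",
    "write_derep",
    "write_filterstats",
]

# IUPAC nucleotide codes -> the set of bases each matches
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")
        if self.qualities and not (
            0 <= min(self.qualities) and max(self.qualities) <= 60
        ):
            raise ValueError("Phred scores must lie in [0, 60]")


@dataclass(frozen=True)
class FilteredRead:
    read_id: str
    sample_id: str
    sequence: str
    expected_errors: float


@dataclass(frozen=True)
class UniqueSequence:
    sequence: str
    abundance: int
    member_read_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError("abundance must be positive")
        if self.member_read_ids and len(self.member_read_ids) != self.abundance:
            raise ValueError("abundance must equal number of member reads")


@dataclass(frozen=True)
class FilterConfig:
    trim_length: int = 400
    max_expected_errors: float = 0.5
    singleton_policy: str = "include"

    def __post_init__(self) -> None:
        if self.trim_length <= 0 or self.max_expected_errors <= 0:
            raise ValueError("trim_length and max_expected_errors must be > 0")
        if self.singleton_policy not in ("include", "exclude"):
            raise ValueError("singleton_policy must be include/exclude")


@dataclass
class FilterStats:
    """Stage counts, overall and per sample (monotone non-increasing)."""

    raw: int = 0
    tag_primer_pass: int = 0
    length_pass: int = 0
    ee_pass: int = 0
    unique: int = 0
    singleton: int = 0
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)

    def sample(self, sample_id: str) -> dict[str, int]:
        return self.per_sample.setdefault(
            sample_id,
            {
                "tag_primer_pass": 0,
                "length_pass": 0,
                "ee_pass": 0,
                "unique": 0,
                "singleton": 0,
            },
        )


def read_fastq(path) -> list[RawRead]:
    """Load Phred+33 FASTQ records."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            RawRead(
                rec.id,
                str(rec.seq),
                tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def read_tagmap(path) -> list[tuple[str, str, str]]:
    """Load a tag map TSV: sample_id, MID ('-' for untagged), fwd primer."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ValueError("tagmap must start with a sample_id header line")
        for line in fh:
            if not line.strip():
                continue
            sample_id, mid, primer = line.rstrip("\n").split("\t")
            rows.append((sample_id, "" if mid == "-" else mid, primer))
    return rows


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff seq matches the IUPAC pattern base-for-base."""
    if len(seq) < len(pattern):
        return False
    return all(s in IUPAC.get(p, "") for p, s in zip(pattern, seq))


def demultiplex_and_strip(
    reads: Iterable[RawRead],
    tagmap: Sequence[tuple[str, str, str]],
    stats: FilterStats | None = None,
) -> tuple[dict[str, list[RawRead]], FilterStats]:
    """Assign reads to samples by exact MID + degenerate primer match.

    The MID+primer prefix is removed from both sequence and qualities;
    unmatched reads are discarded and counted.
    """
    mids = [mid for _s, mid, _p in tagmap]
    if len(set(mids)) != len(mids):
        raise ValueError("duplicate MIDs in tag map")
    if stats is None:
        stats = FilterStats()
    by_sample: dict[str, list[RawRead]] = {s: [] for s, _m, _p in tagmap}
    for read in reads:
        stats.raw += 1
        for sample_id, mid, primer in tagmap:
            if mid and not read.sequence.startswith(mid):
                continue
            if not iupac_match(primer, read.sequence[len(mid) :]):
                continue
            cut = len(mid) + len(primer)
            by_sample[sample_id].append(
                RawRead(read.read_id, read.sequence[cut:], read.qualities[cut:])
            )
            stats.tag_primer_pass += 1
            stats.sample(sample_id)["tag_primer_pass"] += 1
            break
    return by_sample, stats


def trim_to_length(read: RawRead, trim_length: int) -> RawRead | None:
    """Truncate to exactly trim_length; reads shorter are discarded."""
    if len(read.sequence) < trim_length:
        return None
    return RawRead(
        read.read_id, read.sequence[:trim_length], read.qualities[:trim_length]
    )


def expected_error(qualities: Sequence[int]) -> float:
    """Expected number of errors implied by Phred scores."""
    return float(sum(10.0 ** (-q / 10.0) for q in qualities))


def expected_error_filter(
    read: RawRead, max_expected_errors: float, sample_id: str = ""
) -> FilteredRead | None:
    """Keep the read iff its expected error count is within the cutoff."""
    ee = expected_error(read.qualities)
    if ee > max_expected_errors:
        return None
    return FilteredRead(read.read_id, sample_id, read.sequence, ee)


def dereplicate(reads: Iterable[FilteredRead]) -> list[UniqueSequence]:
    """Collapse identical sequences, sorted by decreasing abundance.

    Ties are ordered lexicographically by sequence so the output is
    independent of input read order.
    """
    groups: dict[str, list[str]] = {}
    for read in reads:
        groups.setdefault(read.sequence, []).append(read.read_id)
    uniques = [
        UniqueSequence(seq, len(ids), tuple(sorted(ids)))
        for seq, ids in groups.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def apply_singleton_policy(
    uniques: Sequence[UniqueSequence], policy: str
) -> list[UniqueSequence]:
    """Drop abundance-1 uniques under the 'exclude' policy."""
    if policy == "include":
        return list(uniques)
    if policy == "exclude":
        return [u for u in uniques if u.abundance > 1]
    raise ValueError(f"unknown singleton policy: {policy!r}")


def run_filter_chain(
    reads: Iterable[RawRead],
    tagmap: Sequence[tuple[str, str, str]],
    config: FilterConfig,
) -> tuple[dict[str, list[FilteredRead]], FilterStats]:
    """Demultiplex then trim and expected-error-filter each sample.

    Dereplication and the singleton policy are applied downstream by the
    caller on whichever pooling of samples is being clustered, so that
    singleton status is defined within the clustered set.
    """
    by_sample, stats = demultiplex_and_strip(reads, tagmap)
    filtered: dict[str, list[FilteredRead]] = {}
    for sample_id, sample_reads in by_sample.items():
        kept: list[FilteredRead] = []
        srec = stats.sample(sample_id)
        for read in sample_reads:
            trimmed = trim_to_length(read, config.trim_length)
            if trimmed is None:
                continue
            stats.length_pass += 1
            srec["length_pass"] += 1
            fr = expected_error_filter(
                trimmed, config.max_expected_errors, sample_id
            )
            if fr is None:
                continue
            stats.ee_pass += 1
            srec["ee_pass"] += 1
            kept.append(fr)
        filtered[sample_id] = kept
    return filtered, stats


def tally_uniques(stats: FilterStats, sample_id: str | None, uniques) -> None:
    """Record unique/singleton counts for a clustered set in the stats."""
    n_unique = len(uniques)
    n_single = sum(1 for u in uniques if u.abundance == 1)
    stats.unique += n_unique
    stats.singleton += n_single
    if sample_id is not None:
        srec = stats.sample(sample_id)
        srec["unique"] += n_unique
        srec["singleton"] += n_single


def write_derep(path, uniques: Sequence[UniqueSequence]) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tabundance\n")
        for u in uniques:
            fh.write(f"{u.sequence}\t{u.abundance}\n")


def read_derep(path) -> list[UniqueSequence]:
    uniques = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            seq, ab = line.rstrip("\n").split("\t")
            uniques.append(UniqueSequence(seq, int(ab)))
    return uniques


def write_filterstats(path, stats: FilterStats) -> None:
    """Write stage counts in the conventional pipeline-report layout."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "sample\traw\ttag_primer_pass\tlength_pass\tee_pass"
            "\tunique_incl_singletons\tsingletons\tunique_excl_singletons\n"
        )
        fh.write(
            f"ALL\t{stats.raw}\t{stats.tag_primer_pass}\t{stats.length_pass}"
            f"\t{stats.ee_pass}\t{stats.unique}\t{stats.singleton}"
            f"\t{stats.unique - stats.singleton}\n"
        )
        for sample_id in sorted(stats.per_sample):
            s = stats.per_sample[sample_id]
            fh.write(
                f"{sample_id}\t-\t{s['tag_primer_pass']}\t{s['length_pass']}"
                f"\t{s['ee_pass']}\t{s['unique']}\t{s['singleton']}"
                f"\t{s['unique'] - s['singleton']}\n"
            )
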