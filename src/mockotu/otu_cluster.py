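"""Greedy abundance-ordered centroid OTU clustering.

Sequences are clustered at integer divergence thresholds (1-10 percent of
aligned columns) against cluster centroids, in decreasing order of
abundance, the convention popularised by greedy amplicon clusterers: the
most abundant unique seeds the first OTU, and every subsequent unique
either joins the closest centroid within the threshold radius or seeds a
new OTU.

Because reads are trimmed to a fixed length before clustering, an internal
indel in one sequence shows up as an internal gap *plus* a terminal gap of
the same size against an indel-free sequence of equal length.  How those
gap columns enter the divergence denominator and numerator materially
changes cluster structure for length-variable markers such as 18S V4, so
the convention is explicit and configurable:

* ``ALL_GAPS_COUNTED`` (default): every gap column, terminal or internal,
  is a difference; divergence = (mismatch + all gap columns) / columns.
* ``INTERNAL_GAPS_ONLY``: terminal-gap columns are dropped from both the
  numerator and the denominator.

All merge decisions are made in exact integer arithmetic on column counts,
so threshold boundaries (e.g. 36 gap columns over 400 at a 9% threshold)
behave exactly; a divergence equal to the threshold merges.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _align
from .demux_filter import FilteredRead, UniqueSequence

__all__ = [
    "AlignmentResult",
    "DivergenceConvention",
    "OTUCluster",
    "ClusteringResult",
    "global_align",
    "divergence",
    "pair_divergence",
    "is_bimera",
    "greedy_cluster",
    "threshold_scan",
    "map_reads_to_otus",
    "validate_clustering",
    "write_clustering",
]


@dataclass(frozen=True)
class AlignmentResult:
    """Column tally of a pairwise global alignment with free end gaps."""

    total_columns: int
    match_columns: int
    mismatch_columns: int
    internal_gap_columns: int
    terminal_gap_columns: int

    def __post_init__(self) -> None:
        parts = (
            self.match_columns
            + self.mismatch_columns
            + self.internal_gap_columns
            + self.terminal_gap_columns
        )
        if parts != self.total_columns or min(
            self.match_columns,
            self.mismatch_columns,
            self.internal_gap_columns,
            self.terminal_gap_columns,
        ) < 0:
            raise ValueError("inconsistent alignment column counts")


class DivergenceConvention(enum.Enum):
    ALL_GAPS_COUNTED = "all-gaps"
    INTERNAL_GAPS_ONLY = "internal-gaps"


def global_align(a: str, b: str) -> AlignmentResult:
    """Globally align two sequences (terminal gaps free but recorded)."""
    _score, ops, _apos = _align.global_align_ops(a, b)
    match = int(np.count_nonzero(ops == _align.OP_MATCH))
    mismatch = int(np.count_nonzero(ops == _align.OP_MISMATCH))
    internal = int(
        np.count_nonzero(ops == _align.OP_GAP_IN_A)
        + np.count_nonzero(ops == _align.OP_GAP_IN_B)
    )
    terminal = len(ops) - match - mismatch - internal
    return AlignmentResult(len(ops), match, mismatch, internal, terminal)


def _div_fraction(
    aln: AlignmentResult, convention: DivergenceConvention
) -> tuple[int, int]:
    """Divergence as an exact (numerator, denominator) pair of columns."""
    if convention is DivergenceConvention.ALL_GAPS_COUNTED:
        num = (
            aln.mismatch_columns
            + aln.internal_gap_columns
            + aln.terminal_gap_columns
        )
        den = aln.total_columns
    else:
        num = aln.mismatch_columns + aln.internal_gap_columns
        den = aln.total_columns - aln.terminal_gap_columns
    return num, den


def divergence(aln: AlignmentResult, convention: DivergenceConvention) -> float:
    """Fractional divergence of an alignment under a gap convention."""
    num, den = _div_fraction(aln, convention)
    if den == 0:
        raise ValueError("divergence undefined: zero aligned columns")
    return num / den


def pair_divergence(
    a: str, b: str, convention: DivergenceConvention
) -> float:
    """Align two sequences and return their divergence."""
    return divergence(global_align(a, b), convention)


@dataclass
class OTUCluster:
    otu_id: str
    centroid: str
    members: list[tuple[UniqueSequence, float]] = field(default_factory=list)

    @property
    def total_abundance(self) -> int:
        return sum(u.abundance for u, _d in self.members)


@dataclass
class ClusteringResult:
    threshold: int  # integer percent
    convention: DivergenceConvention
    singleton_policy: str
    otus: list[OTUCluster]
    chimeras: list[UniqueSequence]
    n_input_uniques: int
    input_abundance: int

    @property
    def n_otus(self) -> int:
        return len(self.otus)


def _diff_profiles(candidate: str, centroid: str):
    """Per-crossover difference profiles of ``candidate`` vs ``centroid``.

    Returns (diff_prefix, bad_prefix) arrays of length len(candidate)+1.
    diff_prefix[c] counts mismatch/gap/overhang columns among candidate
    coordinates < c; bad_prefix[c] counts columns belonging to gap runs of
    length >= 2 in that region (which disqualify a chimera model there).
    Suffix counts follow as totals minus prefixes.
    """
    _score, ops, apos = _align.global_align_ops(candidate, centroid)
    L = len(candidate)
    diff = np.zeros(L + 1, dtype=np.int64)
    bad = np.zeros(L + 1, dtype=np.int64)
    # annotate gap runs >= 2 columns
    run_bad = np.zeros(len(ops), dtype=bool)
    k = 0
    while k < len(ops):
        if ops[k] in (_align.OP_GAP_IN_A, _align.OP_GAP_IN_B):
            j = k
            while j < len(ops) and ops[j] == ops[k]:
                j += 1
            if j - k >= 2:
                run_bad[k:j] = True
            k = j
        else:
            k += 1
    for k, op in enumerate(ops):
        if op == _align.OP_MATCH:
            continue
        if op == _align.OP_TERM_B:  # centroid overhang: no candidate bases
            continue
        pos = int(apos[k])  # candidate coordinate (or boundary for gaps in a)
        diff[pos + 1 :] += 1
        if run_bad[k]:
            bad[pos + 1 :] += 1
    return diff, bad


def is_bimera(
    candidate: str,
    centroids: Sequence[str],
    threshold: int,
    convention: DivergenceConvention = DivergenceConvention.ALL_GAPS_COUNTED,
    min_flank: int = 50,
) -> tuple[bool, tuple[int, int] | None]:
    """Screen a candidate as a two-parent chimera of existing centroids.

    Flags the candidate when some prefix matches one centroid and the
    complementary suffix matches another with at most one total mismatch,
    no gap runs of two or more columns in the used regions, a crossover at
    least ``min_flank`` nt from either end, while the candidate itself is
    more than ``threshold`` percent divergent from both parents.  Returns
    the flag and the (prefix, suffix) parent indices of the first model
    found (centroids scanned in order, crossovers left to right).
    """
    L = len(candidate)
    if len(centroids) < 2 or L < 2 * min_flank:
        return False, None
    profiles = []
    divergent = []
    for cen in centroids:
        aln = global_align(candidate, cen)
        num, den = _div_fraction(aln, convention)
        divergent.append(num * 100 > threshold * den)
        profiles.append(_diff_profiles(candidate, cen))
    for p1 in range(len(centroids)):
        if not divergent[p1]:
            continue
        d1, b1 = profiles[p1]
        for p2 in range(len(centroids)):
            if p2 == p1 or not divergent[p2]:
                continue
            d2, b2 = profiles[p2]
            d2_tot, b2_tot = d2[-1], b2[-1]
            for c in range(min_flank, L - min_flank + 1):
                if b1[c] or (b2_tot - b2[c]):
                    continue
                if d1[c] + (d2_tot - d2[c]) <= 1:
                    return True, (p1, p2)
    return False, None


def _sorted_uniques(uniques: Iterable[UniqueSequence]) -> list[UniqueSequence]:
    return sorted(uniques, key=lambda u: (-u.abundance, u.sequence))


def greedy_cluster(
    uniques: Iterable[UniqueSequence],
    threshold_percent: int,
    convention: DivergenceConvention = DivergenceConvention.ALL_GAPS_COUNTED,
    chimera_check: bool = False,
    singleton_policy: str = "include",
) -> ClusteringResult:
    """Cluster unique sequences greedily at an integer percent threshold.

    Uniques are processed in decreasing abundance (ties lexicographic by
    sequence).  Each is compared against every existing centroid; it joins
    the centroid of minimal divergence when that divergence is at most
    threshold/100 (ties broken toward the more abundant, then the earlier
    created centroid).  Otherwise it is either set aside as a putative
    chimera (when ``chimera_check`` is on and the bimera model fits) or it
    seeds a new OTU.
    """
    if not 1 <= int(threshold_percent) <= 100:
        raise ValueError("threshold must be an integer percent >= 1")
    ordered = _sorted_uniques(uniques)
    otus: list[OTUCluster] = []
    cen_abund: list[int] = []
    chimeras: list[UniqueSequence] = []
    t = int(threshold_percent)
    for u in ordered:
        best = None  # (num, den, -abundance, index)
        for idx, otu in enumerate(otus):
            aln = global_align(u.sequence, otu.centroid)
            num, den = _div_fraction(aln, convention)
            if den == 0:
                continue
            if best is None:
                better = True
            else:
                bn, bd, babund, bidx = best
                lhs = num * bd
                rhs = bn * den
                better = lhs < rhs or (
                    lhs == rhs and cen_abund[idx] > babund
                )
            if better:
                best = (num, den, cen_abund[idx], idx)
        if best is not None and best[0] * 100 <= t * best[1]:
            num, den, _ab, idx = best
            otus[idx].members.append((u, num / den))
        else:
            if chimera_check and len(otus) >= 2:
                flag, parents = is_bimera(
                    u.sequence, [o.centroid for o in otus], t, convention
                )
                if flag:
                    chimeras.append(u)
                    continue
            otu = OTUCluster(otu_id=f"otu{len(otus) + 1:03d}", centroid=u.sequence)
            otu.members.append((u, 0.0))
            otus.append(otu)
            cen_abund.append(u.abundance)
    return ClusteringResult(
        threshold=t,
        convention=convention,
        singleton_policy=singleton_policy,
        otus=otus,
        chimeras=chimeras,
        n_input_uniques=len(ordered),
        input_abundance=sum(u.abundance for u in ordered),
    )


def threshold_scan(
    uniques_by_policy: dict[str, Sequence[UniqueSequence]],
    thresholds: Iterable[int] = range(1, 11),
    convention: DivergenceConvention = DivergenceConvention.ALL_GAPS_COUNTED,
    chimera_check: bool = False,
) -> dict[tuple[int, str], ClusteringResult]:
    """Cluster each singleton policy's unique set at every threshold."""
    out: dict[tuple[int, str], ClusteringResult] = {}
    for policy, uniques in uniques_by_policy.items():
        for t in thresholds:
            out[(int(t), policy)] = greedy_cluster(
                uniques,
                int(t),
                convention=convention,
                chimera_check=chimera_check,
                singleton_policy=policy,
            )
    return out


def map_reads_to_otus(
    reads: Sequence[FilteredRead],
    result: ClusteringResult,
) -> tuple[dict[str, int], int, int]:
    """Assign filtered reads to OTUs via their unique sequence.

    Reads whose sequence belongs to a clustered unique go to that unique's
    OTU.  Reads whose unique was dropped (singleton exclusion) are mapped
    to the nearest centroid if within the clustering threshold, otherwise
    left unassigned.  Returns (otu_id -> read count, n_unassigned,
    n_chimera_reads); the three parts partition the input reads.
    """
    seq_to_otu: dict[str, str] = {}
    for otu in result.otus:
        for u, _d in otu.members:
            seq_to_otu[u.sequence] = otu.otu_id
    chimera_seqs = {u.sequence for u in result.chimeras}
    counts = {otu.otu_id: 0 for otu in result.otus}
    nearest_cache: dict[str, str | None] = {}
    unassigned = 0
    chimera_reads = 0
    for read in reads:
        seq = read.sequence
        if seq in seq_to_otu:
            counts[seq_to_otu[seq]] += 1
            continue
        if seq in chimera_seqs:
            chimera_reads += 1
            continue
        if seq not in nearest_cache:
            best = None
            for otu in result.otus:
                aln = global_align(seq, otu.centroid)
                num, den = _div_fraction(aln, result.convention)
                if den == 0:
                    continue
                if best is None or num * best[1] < best[0] * den:
                    best = (num, den, otu.otu_id)
            if best is not None and best[0] * 100 <= result.threshold * best[1]:
                nearest_cache[seq] = best[2]
            else:
                nearest_cache[seq] = None
        target = nearest_cache[seq]
        if target is None:
            unassigned += 1
        else:
            counts[target] += 1
    return counts, unassigned, chimera_reads


def validate_clustering(result: ClusteringResult) -> None:
    """Assert the membership and centroid-separation postconditions.

    Every member must lie within the threshold radius of its centroid, and
    every centroid must be more than the threshold divergent from all
    centroids created before it.  Raises AssertionError otherwise.
    """
    t = result.threshold
    conv = result.convention
    for otu in result.otus:
        for u, _d in otu.members:
            aln = global_align(u.sequence, otu.centroid)
            num, den = _div_fraction(aln, conv)
            assert num * 100 <= t * den, (
                f"member beyond threshold in {otu.otu_id}"
            )
    for i, otu in enumerate(result.otus):
        for prev in result.otus[:i]:
            aln = global_align(otu.centroid, prev.centroid)
            num, den = _div_fraction(aln, conv)
            assert num * 100 > t * den, (
                f"centroids {prev.otu_id}/{otu.otu_id} within threshold"
            )
    total = sum(o.total_abundance for o in result.otus) + sum(
        u.abundance for u in result.chimeras
    )
    assert total == result.input_abundance, "abundance not conserved"


def write_clustering(outdir, results: dict[tuple[int, str], ClusteringResult]) -> None:
    """Write otus.fasta / otumap.tsv / results.tsv / chimeras.tsv."""
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "results.tsv"), "w") as fh:
        fh.write("threshold\tpolicy\tn_otus\tn_chimeras\n")
        for (t, policy), res in sorted(results.items()):
            fh.write(f"{t}\t{policy}\t{res.n_otus}\t{len(res.chimeras)}\n")
    with open(os.path.join(outdir, "otus.fasta"), "w") as fa, open(
        os.path.join(outdir, "otumap.tsv"), "w"
    ) as om, open(os.path.join(outdir, "chimeras.tsv"), "w") as ch:
        om.write("threshold\tpolicy\totu_id\tsequence\tdivergence\n")
        ch.write("threshold\tpolicy\tsequence\tabundance\n")
        for (t, policy), res in sorted(results.items()):
            for otu in res.otus:
                fa.write(
                    f">{t}pct_{policy}_{otu.otu_id};size={otu.total_abundance}\n"
                    f"{otu.centroid}\n"
                )
                for u, d in otu.members:
                    om.write(
                        f"{t}\t{policy}\t{otu.otu_id}\t{u.sequence}\t{d:.6f}\n"
                    )
            for u in res.chimeras:
                ch.write(f"{t}\t{policy}\t{u.sequence}\t{u.abundance}\n")
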