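"""OTU-to-species correspondence metrics and reporting.

Quantifies how well OTU counts track known species composition in mock
communities: per-sample OTU counts and the fraction of samples yielding
exactly one OTU (the 1:1 correspondence percentage), the lowest divergence
threshold at which a sample collapses to a single OTU (with a ">10"
sentinel when even 10% leaves multiple OTUs), OTUs-versus-species-detected
curves across the threshold scan, and Pearson correlations between
population size, read depth and OTU count.

Percentages are rounded half-up to the nearest integer, matching the
reporting convention of mock-community benchmarks (e.g. 15/24 -> 63%).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats as _sps

from .demux_filter import UniqueSequence, apply_singleton_policy
from .otu_cluster import (
    ClusteringResult,
    DivergenceConvention,
    greedy_cluster,
    threshold_scan,
)
from .taxonomy_assign import ReferenceDB, assign_otus

__all__ = [
    "CorrespondenceSummary",
    "DetectionCurve",
    "CorrelationResult",
    "round_half_up_percent",
    "correspondence_summary",
    "min_single_otu_threshold",
    "detection_curve",
    "pearson",
    "population_correlations",
    "report",
]

SENTINEL_ABOVE_MAX = ">10"


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded half away from zero (15/24 -> 63, not 62)."""
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass(frozen=True)
class CorrespondenceSummary:
    per_sample: dict[str, int]
    single_otu: dict[str, bool]
    n_samples: int
    n_single: int
    percent_single: int


def correspondence_summary(
    otu_counts: Mapping[str, int]
) -> CorrespondenceSummary:
    """Flag samples with exactly one OTU and aggregate the percentage.

    A sample with zero OTUs (all of its uniques were, e.g., singletons
    under the exclude policy) counts as non-1:1.
    """
    if not otu_counts:
        raise ValueError("no per-sample OTU counts given")
    if any(c < 0 for c in otu_counts.values()):
        raise ValueError("OTU counts must be non-negative")
    flags = {s: c == 1 for s, c in otu_counts.items()}
    n_single = sum(flags.values())
    return CorrespondenceSummary(
        per_sample=dict(otu_counts),
        single_otu=flags,
        n_samples=len(otu_counts),
        n_single=n_single,
        percent_single=round_half_up_percent(n_single, len(otu_counts)),
    )


def min_single_otu_threshold(
    uniques: Sequence[UniqueSequence],
    convention: DivergenceConvention = DivergenceConvention.ALL_GAPS_COUNTED,
    policy: str = "include",
    thresholds: Iterable[int] = range(1, 11),
) -> int | str:
    """Smallest threshold yielding exactly one OTU, or the ">10" sentinel."""
    kept = apply_singleton_policy(list(uniques), policy)
    if not kept:
        raise ValueError("no sequences left to cluster for this sample")
    for t in thresholds:
        result = greedy_cluster(kept, int(t), convention=convention,
                                singleton_policy=policy)
        if result.n_otus == 1:
            return int(t)
    return SENTINEL_ABOVE_MAX


@dataclass(frozen=True)
class DetectionCurve:
    """(threshold, policy) -> (n_otus, n_species_detected)."""

    points: dict[tuple[int, str], tuple[int, int]]
    expected_species: int


def detection_curve(
    uniques: Sequence[UniqueSequence],
    db: ReferenceDB,
    expected_species: set[str],
    thresholds: Iterable[int] = range(1, 11),
    policies: Sequence[str] = ("exclude", "include"),
    convention: DivergenceConvention = DivergenceConvention.ALL_GAPS_COUNTED,
) -> DetectionCurve:
    """OTU counts and species detected across the threshold scan.

    A species is detected at a given threshold/policy when at least one
    OTU's best hit is positive for it.
    """
    by_policy = {
        p: apply_singleton_policy(list(uniques), p) for p in policies
    }
    results = threshold_scan(by_policy, thresholds, convention)
    points: dict[tuple[int, str], tuple[int, int]] = {}
    for (t, policy), res in results.items():
        hits = assign_otus(res, db)
        detected = {
            h.best_species
            for h in hits
            if h.positive and h.best_species in expected_species
        }
        points[(t, policy)] = (res.n_otus, len(detected))
    return DetectionCurve(points=points, expected_species=len(expected_species))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("correlation undefined for zero-variance input")
    res = _sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


def population_correlations(
    population_sizes: Sequence[float],
    read_counts: Sequence[float],
    otu_counts: Sequence[float],
) -> dict[str, CorrelationResult]:
    """r/p for size-vs-OTUs, size-vs-reads and reads-vs-OTUs."""
    if not (len(population_sizes) == len(read_counts) == len(otu_counts)):
        raise ValueError("input vectors must be aligned")
    return {
        "size_vs_otus": pearson(population_sizes, otu_counts),
        "size_vs_reads": pearson(population_sizes, read_counts),
        "reads_vs_otus": pearson(read_counts, otu_counts),
    }


def _plot_curve(path, curve: DetectionCurve) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    policies = sorted({p for _t, p in curve.points})
    thresholds = sorted({t for t, _p in curve.points})
    for policy in policies:
        otus = [curve.points[(t, policy)][0] for t in thresholds]
        det = [curve.points[(t, policy)][1] for t in thresholds]
        ax.plot(thresholds, otus, marker="o", label=f"OTUs ({policy})")
        ax.plot(thresholds, det, marker="s", linestyle="--",
                label=f"species detected ({policy})")
    ax.axhline(curve.expected_species, color="k", lw=1,
               label="expected species")
    ax.set_xlabel("divergence threshold (%)")
    ax.set_ylabel("count")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(
    outdir,
    summaries: Mapping[str, CorrespondenceSummary] | None = None,
    min_thresholds: Mapping[str, Mapping[str, int | str]] | None = None,
    curve: DetectionCurve | None = None,
    correlations: Mapping[str, Mapping[str, CorrelationResult]] | None = None,
) -> None:
    """Write summary.tsv / minthresholds.tsv / curve.tsv (+ plot).

    ``summaries`` maps a singleton policy to its correspondence summary;
    ``min_thresholds`` maps policy -> sample -> threshold or ">10".
    """
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "summary.tsv"), "w") as fh:
        fh.write("policy\tsample\tn_otus\tsingle_otu\n")
        for policy in sorted(summaries or {}):
            s = summaries[policy]
            for sample in sorted(s.per_sample):
                fh.write(
                    f"{policy}\t{sample}\t{s.per_sample[sample]}"
                    f"\t{int(s.single_otu[sample])}\n"
                )
            fh.write(
                f"{policy}\tAGGREGATE\t{s.n_single}/{s.n_samples}"
                f"\t{s.percent_single}\n"
            )
    with open(os.path.join(outdir, "minthresholds.tsv"), "w") as fh:
        fh.write("policy\tsample\tmin_single_otu_threshold\n")
        for policy in sorted(min_thresholds or {}):
            for sample in sorted(min_thresholds[policy]):
                fh.write(
                    f"{policy}\t{sample}\t{min_thresholds[policy][sample]}\n"
                )
    with open(os.path.join(outdir, "curve.tsv"), "w") as fh:
        fh.write("threshold\tpolicy\tn_otus\tn_species_detected"
                 "\texpected_species\n")
        if curve is not None:
            for (t, policy) in sorted(curve.points):
                n_otus, n_det = curve.points[(t, policy)]
                fh.write(f"{t}\t{policy}\t{n_otus}\t{n_det}"
                         f"\t{curve.expected_species}\n")
    if curve is not None:
        _plot_curve(os.path.join(outdir, "curve.png"), curve)
    with open(os.path.join(outdir, "correlations.tsv"), "w") as fh:
        fh.write("policy\tpair\tr\tp\tn\n")
        for policy in sorted(correlations or {}):
            for pair, c in sorted(correlations[policy].items()):
                fh.write(f"{policy}\t{pair}\t{c.r:.6f}\t{c.p:.6f}\t{c.n}\n")
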