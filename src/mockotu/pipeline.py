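"""End-to-end orchestration: simulate -> filter -> cluster -> assign -> evaluate.

A single seeded RunConfig drives the whole chain; every stage reads only
the previous stage's outputs from the run directory, and identical
config+seed yields byte-identical outputs.  Per-stage random streams are
forked from the run seed by fixed labels so stages are individually
reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import demux_filter as df
from . import evaluation as ev
from . import otu_cluster as oc
from . import synthetic_community as sc
from . import taxonomy_assign as tx

__all__ = [
    "RunConfig",
    "run_all",
    "standard_fixtures",
    "make_standard_fixtures",
    "DEFAULT_POPULATION_SIZES",
    "per_sample_otu_counts",
]

# stage labels -> offsets applied to the run seed when forking streams
_STAGE = {"references": 1, "variants": 2, "design": 3, "reads": 4}

# 24 populations over 13 species at low (~5) / medium (~10) / high (~30)
# individual counts, mirroring a mixed low/medium/high benchmark design.
DEFAULT_POPULATION_SIZES: tuple[tuple[str, int], ...] = (
    ("sp01", 5), ("sp01", 10), ("sp01", 30),
    ("sp02", 3),
    ("sp03", 5), ("sp03", 10), ("sp03", 17),
    ("sp04", 5),
    ("sp05", 10),
    ("sp06", 5),
    ("sp07", 10), ("sp07", 31),
    ("sp08", 5), ("sp08", 30),
    ("sp09", 9),
    ("sp10", 5), ("sp10", 8), ("sp10", 27),
    ("sp11", 5), ("sp11", 10), ("sp11", 28),
    ("sp12", 5), ("sp12", 10),
    ("sp13", 30),
)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 1
    design: str = "individuals"  # individuals | populations | untagged-...
    n_species: int = 20
    divergence_range: tuple[float, float] = (0.13, 0.30)
    population_sizes: tuple[tuple[str, int], ...] = DEFAULT_POPULATION_SIZES
    variant_plan: str = "single"  # single | calibrated
    reads_per_sample: int = 60
    pcr_substitution_rate: float = 0.0
    seq_substitution_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    chimera_fraction: float = 0.0
    trim_length: int = 400
    max_expected_errors: float = 0.5
    thresholds: tuple[int, ...] = tuple(range(1, 11))
    convention: oc.DivergenceConvention = oc.DivergenceConvention.ALL_GAPS_COUNTED
    policies: tuple[str, ...] = ("exclude", "include")
    chimera_check: bool = False
    report_threshold: int = 3

    def __post_init__(self) -> None:
        if self.design not in (
            "individuals",
            "populations",
            "untagged-individuals",
            "untagged-populations",
        ):
            raise ValueError(f"unknown design {self.design!r}")
        if not set(self.thresholds) <= set(range(1, 11)):
            raise ValueError("thresholds must lie within 1..10")

    def to_text(self) -> str:
        lines = [
            f"seed={self.seed}",
            f"design={self.design}",
            f"n_species={self.n_species}",
            f"divergence_range={self.divergence_range[0]},{self.divergence_range[1]}",
            f"variant_plan={self.variant_plan}",
            f"reads_per_sample={self.reads_per_sample}",
            f"pcr_substitution_rate={self.pcr_substitution_rate}",
            f"seq_substitution_rate={self.seq_substitution_rate}",
            f"homopolymer_indel_rate={self.homopolymer_indel_rate}",
            f"chimera_fraction={self.chimera_fraction}",
            f"trim_length={self.trim_length}",
            f"max_expected_errors={self.max_expected_errors}",
            f"thresholds={','.join(map(str, self.thresholds))}",
            f"convention={self.convention.value}",
            f"policies={','.join(self.policies)}",
            f"chimera_check={int(self.chimera_check)}",
            f"report_threshold={self.report_threshold}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _sep, value = line.partition("=")
            kv[key] = value
        conv = {c.value: c for c in oc.DivergenceConvention}
        lo, hi = kv.get("divergence_range", "0.13,0.30").split(",")
        return cls(
            seed=int(kv.get("seed", 1)),
            design=kv.get("design", "individuals"),
            n_species=int(kv.get("n_species", 20)),
            divergence_range=(float(lo), float(hi)),
            variant_plan=kv.get("variant_plan", "single"),
            reads_per_sample=int(kv.get("reads_per_sample", 60)),
            pcr_substitution_rate=float(kv.get("pcr_substitution_rate", 0.0)),
            seq_substitution_rate=float(kv.get("seq_substitution_rate", 0.0)),
            homopolymer_indel_rate=float(kv.get("homopolymer_indel_rate", 0.0)),
            chimera_fraction=float(kv.get("chimera_fraction", 0.0)),
            trim_length=int(kv.get("trim_length", 400)),
            max_expected_errors=float(kv.get("max_expected_errors", 0.5)),
            thresholds=tuple(
                int(t) for t in kv.get("thresholds", "1,2,3,4,5,6,7,8,9,10").split(",")
            ),
            convention=conv[kv.get("convention", "all-gaps")],
            policies=tuple(kv.get("policies", "exclude,include").split(",")),
            chimera_check=bool(int(kv.get("chimera_check", 0))),
            report_threshold=int(kv.get("report_threshold", 3)),
        )


def _calibrated_variants(
    template: sc.ReferenceTemplate, rng: np.random.Generator, seed: int
):
    """Within-genome variant plan calibrated to V-region rDNA surveys:
    1-6 length variants per individual averaging ~2.6, small substitution
    loads and 1-14 bp indels, dominant-copy-heavy frequencies."""
    n_variants = 1 + int(rng.binomial(5, 0.32))
    subs = int(rng.integers(1, 8))
    indels = tuple(
        int(rng.integers(1, 15)) for _ in range(n_variants - 1) if rng.random() < 0.5
    )
    weights = [2.0 ** (-k) for k in range(n_variants)]
    return sc.generate_intragenomic_variants(
        template,
        n_variants,
        substitutions_per_variant=subs,
        indel_length_choices=indels,
        frequency_weights=weights,
        seed=seed,
    )


def _build_inputs(config: RunConfig):
    """Templates, variants, design and genomes for a run config."""
    templates = sc.generate_reference_set(
        config.n_species,
        config.divergence_range,
        seed=config.seed + _STAGE["references"],
    )
    rng = np.random.default_rng(config.seed + _STAGE["variants"])
    variants_by_species = {}
    for k, t in enumerate(templates):
        if config.variant_plan == "single":
            variants_by_species[t.species_id] = sc.generate_intragenomic_variants(
                t, 1, seed=config.seed + _STAGE["variants"] + k
            )
        elif config.variant_plan == "calibrated":
            variants_by_species[t.species_id] = _calibrated_variants(
                t, rng, seed=config.seed + _STAGE["variants"] + k
            )
        else:
            raise ValueError(f"unknown variant plan {config.variant_plan!r}")
    design_seed = config.seed + _STAGE["design"]
    if config.design == "individuals":
        design = sc.assemble_individuals_community(templates, True, design_seed)
    elif config.design == "untagged-individuals":
        design = sc.assemble_individuals_community(templates, False, design_seed)
    else:
        sizes = [
            (s, n)
            for s, n in config.population_sizes
            if s in {t.species_id for t in templates}
        ]
        design = sc.assemble_populations_community(
            templates, sizes, config.design == "populations", design_seed
        )
    genomes = sc.default_genomes(design, variants_by_species)
    return templates, variants_by_species, design, genomes


def per_sample_otu_counts(
    result: oc.ClusteringResult,
    read_sample: dict[str, str],
    sample_ids: Sequence[str],
) -> dict[str, int]:
    """OTUs per sample from a pooled clustering (an OTU counts for every
    sample contributing at least one member read)."""
    counts = {s: 0 for s in sample_ids}
    for otu in result.otus:
        samples = set()
        for u, _d in otu.members:
            for rid in u.member_read_ids:
                samples.add(read_sample[rid])
        for s in samples:
            counts[s] += 1
    return counts


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline into ``outdir``; returns key results."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "run.cfg"), "w") as fh:
        fh.write(config.to_text())

    # --- simulate ---------------------------------------------------
    templates, variants_by_species, design, genomes = _build_inputs(config)
    sim_config = sc.SimulationConfig(
        seed=config.seed + _STAGE["reads"],
        reads_per_sample=config.reads_per_sample,
        pcr_substitution_rate=config.pcr_substitution_rate,
        seq_substitution_rate=config.seq_substitution_rate,
        homopolymer_indel_rate=config.homopolymer_indel_rate,
        chimera_fraction=config.chimera_fraction,
    )
    reads, truth = sc.simulate_reads(design, genomes, sim_config)
    simdir = os.path.join(outdir, "sim")
    sc.write_fixture(simdir, design, templates, variants_by_species, reads, truth)

    # --- filter -----------------------------------------------------
    raw = df.read_fastq(os.path.join(simdir, "reads.fastq"))
    tagmap = df.read_tagmap(os.path.join(simdir, "tagmap.tsv"))
    fconfig = df.FilterConfig(
        trim_length=config.trim_length,
        max_expected_errors=config.max_expected_errors,
    )
    filtered, stats = df.run_filter_chain(raw, tagmap, fconfig)

    per_sample_clustering = config.design == "populations"
    filterdir = os.path.join(outdir, "filter")
    os.makedirs(filterdir, exist_ok=True)

    clusterdir = os.path.join(outdir, "cluster")
    db = tx.read_reference_db(os.path.join(simdir, "refs.fasta"))
    read_sample = {
        r.read_id: r.sample_id for sample in filtered.values() for r in sample
    }

    summaries: dict[str, ev.CorrespondenceSummary] = {}
    min_thresholds: dict[str, dict[str, int | str]] = {}
    results_all: dict[tuple[int, str], oc.ClusteringResult] = {}
    hits_by_policy: dict[str, list[tx.TaxonomicHit]] = {}

    if per_sample_clustering:
        # each tagged population is clustered separately
        counts_by_policy: dict[str, dict[str, int]] = {
            p: {} for p in config.policies
        }
        for sample_id in sorted(filtered):
            uniques = df.dereplicate(filtered[sample_id])
            df.tally_uniques(stats, sample_id, uniques)
            df.write_derep(
                os.path.join(filterdir, f"derep_{sample_id}.tsv"), uniques
            )
            for policy in config.policies:
                kept = df.apply_singleton_policy(uniques, policy)
                mt: int | str = ev.SENTINEL_ABOVE_MAX
                for t in config.thresholds:
                    res = oc.greedy_cluster(
                        kept, t, config.convention,
                        chimera_check=config.chimera_check,
                        singleton_policy=policy,
                    )
                    results_all[(t, f"{policy}:{sample_id}")] = res
                    if t == config.report_threshold:
                        counts_by_policy[policy][sample_id] = res.n_otus
                    if res.n_otus == 1 and mt == ev.SENTINEL_ABOVE_MAX:
                        mt = t
                min_thresholds.setdefault(policy, {})[sample_id] = mt
        for policy in config.policies:
            summaries[policy] = ev.correspondence_summary(counts_by_policy[policy])
        curve = None
    else:
        # pooled clustering across all samples (tagged individuals pool
        # their filtered reads; untagged designs are one sample anyway)
        pooled = [r for sample_id in sorted(filtered) for r in filtered[sample_id]]
        uniques = df.dereplicate(pooled)
        df.tally_uniques(stats, None, uniques)
        df.write_derep(os.path.join(filterdir, "derep_pooled.tsv"), uniques)
        by_policy = {
            p: df.apply_singleton_policy(uniques, p) for p in config.policies
        }
        results_all = oc.threshold_scan(
            by_policy, config.thresholds, config.convention,
            chimera_check=config.chimera_check,
        )
        sample_ids = sorted(filtered)
        for policy in config.policies:
            res = results_all[(config.report_threshold, policy)]
            counts = per_sample_otu_counts(res, read_sample, sample_ids)
            summaries[policy] = ev.correspondence_summary(counts)
            hits_by_policy[policy] = tx.assign_otus(res, db)
            min_thresholds[policy] = {}
            for sample_id in sample_ids:
                sample_uniques = df.dereplicate(filtered[sample_id])
                try:
                    min_thresholds[policy][sample_id] = (
                        ev.min_single_otu_threshold(
                            sample_uniques, config.convention, policy,
                            config.thresholds,
                        )
                    )
                except ValueError:
                    min_thresholds[policy][sample_id] = ev.SENTINEL_ABOVE_MAX
        expected = {t.species_id for t in templates}
        curve = ev.detection_curve(
            uniques, db, expected, config.thresholds, config.policies,
            config.convention,
        )

    df.write_filterstats(os.path.join(filterdir, "filterstats.tsv"), stats)
    oc.write_clustering(clusterdir, results_all)
    assigndir = os.path.join(outdir, "assign")
    os.makedirs(assigndir, exist_ok=True)
    for policy, hits in hits_by_policy.items():
        tx.write_assignments(
            os.path.join(assigndir, f"assignments_{policy}.tsv"), hits
        )
    evaldir = os.path.join(outdir, "eval")
    ev.report(evaldir, summaries, min_thresholds, curve)
    return {
        "stats": stats,
        "summaries": summaries,
        "min_thresholds": min_thresholds,
        "curve": curve,
        "results": results_all,
        "design": design,
        "templates": templates,
    }


def standard_fixtures(seed: int = 11) -> dict:
    """The canonical in-memory test fixtures.

    (i)   a 36-nt-indel pair of 400-nt trimmed sequences;
    (ii)  a pair differing by 7 substitutions plus 4 small (1-6 nt) indels;
    (iii) a two-allele individual with a near-equal 47:43 read split;
    (iv)  a 20-species tagged-individuals community design;
    (v)   the 24-population design over 13 species at ~5/~10/~30.
    """
    rng = np.random.default_rng(seed)
    fixtures: dict = {}

    template = "".join(rng.choice(list("ACGT"), size=460))
    pos = 180
    deleted = template[:pos] + template[pos + 36 :]
    fixtures["indel36_pair"] = (template[:400], deleted[:400])

    t2 = sc.ReferenceTemplate("spX", "Decapoda", template, "fixture")
    variants = sc.generate_intragenomic_variants(
        t2, 2, substitutions_per_variant=7,
        indel_length_choices=(1, 2, 3, 6),
        frequency_weights=(0.5, 0.5), seed=seed + 1,
    )
    fixtures["subs_indels_pair"] = (variants[0].sequence, variants[1].sequence)

    allele_a = template[:400]
    allele_b = sc.apply_mutations(
        allele_a,
        [("sub", int(p), "ACGT"[(("ACGT".index(allele_a[int(p)])) + 1) % 4])
         for p in rng.choice(400, size=20, replace=False)],
    )
    fixtures["two_allele_uniques"] = [
        df.UniqueSequence(allele_a, 47),
        df.UniqueSequence(allele_b, 43),
    ]

    templates = sc.generate_reference_set(20, (0.13, 0.30), seed=seed + 2)
    fixtures["individuals_templates"] = templates
    fixtures["individuals_design"] = sc.assemble_individuals_community(
        templates, True, seed + 3
    )

    pop_templates = sc.generate_reference_set(13, (0.13, 0.30), seed=seed + 4)
    fixtures["population_design"] = sc.assemble_populations_community(
        pop_templates, list(DEFAULT_POPULATION_SIZES), True, seed + 5
    )
    return fixtures


def make_standard_fixtures(outdir, seed: int = 11) -> dict:
    """Write the canonical fixtures to disk; returns the in-memory set."""
    fixtures = standard_fixtures(seed)
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "indel36_pair.fasta"), "w") as fh:
        a, b = fixtures["indel36_pair"]
        fh.write(f">indel36_a\n{a}\n>indel36_b\n{b}\n")
    with open(os.path.join(outdir, "subs_indels_pair.fasta"), "w") as fh:
        a, b = fixtures["subs_indels_pair"]
        fh.write(f">subsindels_a\n{a}\n>subsindels_b\n{b}\n")
    df.write_derep(
        os.path.join(outdir, "two_allele_derep.tsv"),
        fixtures["two_allele_uniques"],
    )
    with open(os.path.join(outdir, "individuals_refs.fasta"), "w") as fh:
        for t in fixtures["individuals_templates"]:
            fh.write(f">{t.species_id}\n{t.sequence}\n")
    return fixtures
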