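"""Seeded mock-community amplicon simulator.

Emulates tagged mock zooplankton communities for 18S V4 metabarcoding
benchmarks: a set of reference species templates, intragenomic rDNA
variants within each genome (substitutions plus 1-36 bp indels among the
tandemly repeated gene copies), individuals carrying those variants, and
four community designs:

* tagged individuals  - one individual per species, one MID tag each;
* tagged populations  - ~5/~10/~30 conspecific individuals per sample,
  one MID per population, per-individual equal DNA weight (so a
  10-individual population carries twice the weight of a 5-individual one);
* untagged individuals / populations - the same members pooled into a
  single untagged PCR.

Reads are single-direction (forward) pyrosequencing-style amplicons:
[MID] + forward primer (degenerate positions resolved uniformly at random
per amplicon) + template insert, truncated to a fixed read length, with
per-base substitution errors, +/-1 nt slips in homopolymer runs >= 3, PCR
chimeras joined at a uniform crossover at least 50 nt from either end, and
a linearly decaying Phred profile.  Every read carries a truth record.

Coordinates are 0-based half-open; all sequences are stored 5'->3' on the
sense strand.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .demux_filter import IUPAC, RawRead
from .otu_cluster import DivergenceConvention, pair_divergence

__all__ = [
    "UNI18S",
    "UNI18SR",
    "ReferenceTemplate",
    "IntragenomicVariant",
    "IndividualGenome",
    "SampleDef",
    "CommunityDesign",
    "SimulationConfig",
    "TruthRecord",
    "apply_mutations",
    "generate_reference_set",
    "generate_intragenomic_variants",
    "generate_mids",
    "assemble_individuals_community",
    "assemble_populations_community",
    "default_genomes",
    "simulate_reads",
    "write_fixture",
]

UNI18S = "AGGGCAAKYCTGGTGCCAGC"
UNI18SR = "GRCGGTATCTRATCGYCTT"

TAXON_GROUPS = (
    "Cladocera", "Copepoda", "Rotifera", "Amphipoda", "Anostraca",
    "Cirripedia", "Decapoda", "Mollusca", "Tunicata",
)

_BASES = "ACGT"


@dataclass(frozen=True)
class ReferenceTemplate:
    species_id: str
    taxon_group: str
    sequence: str
    display_name: str

    def __post_init__(self) -> None:
        if set(self.sequence) - set(_BASES):
            raise ValueError("template sequence must be over A/C/G/T")
        if "_" in self.species_id:
            # individual ids are "<species>_<k>"; keep them parseable
            raise ValueError("species_id must not contain underscores")


@dataclass(frozen=True)
class IntragenomicVariant:
    variant_id: str
    species_id: str
    sequence: str
    copy_frequency: float
    mutation_record: tuple[tuple, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.copy_frequency <= 1:
            raise ValueError("copy_frequency must be in (0, 1]")


@dataclass(frozen=True)
class IndividualGenome:
    individual_id: str
    species_id: str
    rdna_copy_number: int
    variant_frequencies: dict[str, float]
    variant_sequences: dict[str, str]

    def __post_init__(self) -> None:
        if self.rdna_copy_number < 1:
            raise ValueError("rdna_copy_number must be >= 1")
        if abs(sum(self.variant_frequencies.values()) - 1.0) > 1e-9:
            raise ValueError("variant frequencies must sum to 1")


@dataclass(frozen=True)
class SampleDef:
    sample_id: str
    mid_tag: str | None
    forward_primer: str
    reverse_primer: str
    members: tuple[tuple[str, float], ...]  # (individual_id, weight)

    def __post_init__(self) -> None:
        if self.mid_tag is not None and len(self.mid_tag) != 10:
            raise ValueError("MID tags must be exactly 10 nt")
        if any(w <= 0 for _i, w in self.members):
            raise ValueError("member weights must be positive")

    @property
    def total_weight(self) -> float:
        return sum(w for _i, w in self.members)


@dataclass(frozen=True)
class CommunityDesign:
    samples: tuple[SampleDef, ...]

    def __post_init__(self) -> None:
        mids = [s.mid_tag for s in self.samples if s.mid_tag is not None]
        if len(set(mids)) != len(mids):
            raise ValueError("MID tags must be pairwise distinct")
        for i, a in enumerate(mids):
            for b in mids[i + 1 :]:
                if sum(x != y for x, y in zip(a, b)) < 3:
                    raise ValueError("MID pairwise Hamming distance must be >= 3")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    reads_per_sample: int = 150
    pcr_substitution_rate: float = 2e-4
    seq_substitution_rate: float = 1e-3
    homopolymer_indel_rate: float = 5e-3
    chimera_fraction: float = 0.01
    quality_model: tuple[float, float, int] = (38.0, 0.012, 28)
    read_length: int = 450

    def __post_init__(self) -> None:
        rates = (
            self.pcr_substitution_rate,
            self.seq_substitution_rate,
            self.homopolymer_indel_rate,
            self.chimera_fraction,
        )
        if any(not 0 <= r < 1 for r in rates):
            raise ValueError("rates must lie in [0, 1)")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    sample_id: str
    individual_id: str
    species_id: str
    variant_id: str
    is_chimera: bool = False
    chimera_parents: tuple[str, str] | None = None


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _substitute(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for pos in positions:
        old = chars[pos]
        chars[pos] = rng.choice([b for b in _BASES if b != old])
    return "".join(chars)


def generate_reference_set(
    n_species: int,
    pairwise_divergence_range: tuple[float, float] = (0.05, 0.30),
    length_range: tuple[int, int] = (440, 480),
    seed: int = 0,
    max_tries: int = 400,
) -> list[ReferenceTemplate]:
    """Generate species templates with controlled pairwise divergence.

    Templates descend from a common random ancestor by substitutions, with
    per-species length drawn from ``length_range``; every candidate is
    accepted only if its measured divergence to all previously accepted
    templates falls inside ``pairwise_divergence_range``.  Divergence is
    measured by the clustering aligner under the INTERNAL_GAPS_ONLY
    convention so that template length variation (a terminal-gap artifact
    of the shared ancestor construction) does not dominate the check.
    """
    lo, hi = pairwise_divergence_range
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not 0 < lo < hi < 0.5:
        raise ValueError("pairwise_divergence_range must lie within (0, 0.5)")
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, max(length_range))
    r_lo = lo * 0.55
    r_hi = max(hi * 0.5, r_lo * 1.2)
    accepted: list[ReferenceTemplate] = []
    for k in range(n_species):
        ok = False
        for _try in range(max_tries):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            rate = float(rng.uniform(r_lo, r_hi))
            n_subs = max(1, int(round(rate * length)))
            cand = _substitute(rng, ancestor[:length], n_subs)
            if all(
                lo
                <= pair_divergence(
                    cand, t.sequence, DivergenceConvention.INTERNAL_GAPS_ONLY
                )
                <= hi
                for t in accepted
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not satisfy pairwise_divergence_range "
                f"{pairwise_divergence_range} after {max_tries} tries "
                f"(species {k + 1} of {n_species})"
            )
        sid = f"sp{k + 1:02d}"
        accepted.append(
            ReferenceTemplate(
                species_id=sid,
                taxon_group=TAXON_GROUPS[k % len(TAXON_GROUPS)],
                sequence=cand,
                display_name=f"Species {k + 1:02d}",
            )
        )
    return accepted


def apply_mutations(template_sequence: str, record: Iterable[tuple]) -> str:
    """Replay an ordered mutation record against a template sequence."""
    seq = template_sequence
    for edit in record:
        kind = edit[0]
        if kind == "sub":
            _k, pos, base = edit
            seq = seq[:pos] + base + seq[pos + 1 :]
        elif kind == "ins":
            _k, pos, insert = edit
            seq = seq[:pos] + insert + seq[pos:]
        elif kind == "del":
            _k, pos, length = edit
            seq = seq[:pos] + seq[pos + length :]
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    return seq


def generate_intragenomic_variants(
    template: ReferenceTemplate,
    n_variants: int,
    substitutions_per_variant: int = 2,
    indel_length_choices: Sequence[int] = (),
    frequency_weights: Sequence[float] | None = None,
    seed: int = 0,
    position_range: tuple[int, int] | None = None,
) -> list[IntragenomicVariant]:
    """Generate within-genome rDNA variants of a species template.

    Variant 1 is always the unmodified template (the dominant copy); each
    further variant carries ``substitutions_per_variant`` substitutions
    plus one insertion-or-deletion per entry of ``indel_length_choices``
    (lengths 0-36 nt).  Edit sites are sampled on template coordinates
    with enforced separation and applied right to left, so edits never
    overlap and the edit distance between a variant and the template is
    exactly one per substitution plus the summed indel lengths.
    ``position_range`` optionally confines edit positions (half-open).
    Copy frequencies are ``frequency_weights`` normalised to sum to one
    (equal by default).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    indel_lengths = [int(L) for L in indel_length_choices if L > 0]
    if any(not 0 <= L <= 36 for L in indel_lengths):
        raise ValueError("indel lengths must lie in 0-36")
    if frequency_weights is None:
        weights = np.ones(n_variants)
    else:
        weights = np.asarray(list(frequency_weights), dtype=float)
        if len(weights) != n_variants or (weights <= 0).any():
            raise ValueError("need one positive weight per variant")
    freqs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    variants = [
        IntragenomicVariant(
            variant_id=f"{template.species_id}.v1",
            species_id=template.species_id,
            sequence=template.sequence,
            copy_frequency=float(freqs[0]),
            mutation_record=(),
        )
    ]
    n_edits = substitutions_per_variant + len(indel_lengths)
    max_indel = max(indel_lengths, default=0)
    sep = max_indel + 8
    lo, hi = (0, len(template.sequence)) if position_range is None else position_range
    hi = min(hi, len(template.sequence) - max_indel)
    # sample positions with pairwise separation >= sep by drawing from a
    # range compressed by (n-1)*(sep-1) and re-expanding
    span = hi - lo - max(n_edits - 1, 0) * (sep - 1)
    if n_edits > 0 and span < n_edits:
        raise ValueError(
            "requested edits exceed the available sequence length/region"
        )
    for v in range(2, n_variants + 1):
        if n_edits:
            drawn = np.sort(rng.choice(span, size=n_edits, replace=False))
            positions = drawn + lo + np.arange(n_edits) * (sep - 1)
        else:
            positions = np.empty(0, dtype=int)
        kinds: list[tuple] = [("sub",)] * substitutions_per_variant + [
            ("indel", L) for L in indel_lengths
        ]
        order = rng.permutation(n_edits)
        record: list[tuple] = []
        # apply right to left: earlier (leftward) coordinates stay valid
        for idx in range(n_edits - 1, -1, -1):
            pos = int(positions[idx])
            kind = kinds[order[idx]]
            if kind[0] == "sub":
                old = template.sequence[pos]
                base = str(rng.choice([b for b in _BASES if b != old]))
                record.append(("sub", pos, base))
            elif rng.random() < 0.5:
                record.append(("ins", pos, _random_seq(rng, kind[1])))
            else:
                record.append(("del", pos, kind[1]))
        seq = apply_mutations(template.sequence, record)
        variants.append(
            IntragenomicVariant(
                variant_id=f"{template.species_id}.v{v}",
                species_id=template.species_id,
                sequence=seq,
                copy_frequency=float(freqs[v - 1]),
                mutation_record=tuple(record),
            )
        )
    return variants


def generate_mids(n: int, rng: np.random.Generator, min_distance: int = 3) -> list[str]:
    """Random 10-nt MID tags with pairwise Hamming distance >= 3."""
    mids: list[str] = []
    tries = 0
    while len(mids) < n:
        tries += 1
        if tries > 200 * n:
            raise RuntimeError("could not generate enough distinct MID tags")
        cand = _random_seq(rng, 10)
        if all(
            sum(a != b for a, b in zip(cand, m)) >= min_distance for m in mids
        ):
            mids.append(cand)
    return mids


def assemble_individuals_community(
    templates: Sequence[ReferenceTemplate],
    tagged: bool = True,
    seed: int = 0,
) -> CommunityDesign:
    """One individual per species; one tagged sample each, or one pooled
    untagged sample containing every individual at equal weight."""
    if not templates:
        raise ValueError("at least one template is required")
    rng = np.random.default_rng(seed)
    if tagged:
        mids = generate_mids(len(templates), rng)
        samples = tuple(
            SampleDef(
                sample_id=f"ind_{t.species_id}",
                mid_tag=mid,
                forward_primer=UNI18S,
                reverse_primer=UNI18SR,
                members=((f"{t.species_id}_i1", 1.0),),
            )
            for t, mid in zip(templates, mids)
        )
    else:
        samples = (
            SampleDef(
                sample_id="pooled_individuals",
                mid_tag=None,
                forward_primer=UNI18S,
                reverse_primer=UNI18SR,
                members=tuple((f"{t.species_id}_i1", 1.0) for t in templates),
            ),
        )
    return CommunityDesign(samples=samples)


def assemble_populations_community(
    templates: Sequence[ReferenceTemplate],
    sizes: Sequence[tuple[str, int]],
    tagged: bool = True,
    seed: int = 0,
) -> CommunityDesign:
    """Populations of conspecific individuals, one sample per population.

    ``sizes`` lists (species_id, n_individuals) pairs; a species may appear
    several times (e.g. low/medium/high populations).  Per-individual
    weights are equal, so a larger population carries proportionally more
    weight.
    """
    by_id = {t.species_id: t for t in templates}
    if any(n < 1 for _s, n in sizes):
        raise ValueError("population sizes must be >= 1")
    rng = np.random.default_rng(seed)
    mids = generate_mids(len(sizes), rng) if tagged else [None] * len(sizes)
    samples = []
    members_all: list[tuple[str, float]] = []
    for p, (species_id, n) in enumerate(sizes, start=1):
        if species_id not in by_id:
            raise ValueError(f"unknown species {species_id!r}")
        members = tuple(
            (f"{species_id}_p{p:02d}_i{k + 1}", 1.0) for k in range(n)
        )
        members_all.extend(members)
        if tagged:
            samples.append(
                SampleDef(
                    sample_id=f"pop{p:02d}_{species_id}_{n}x",
                    mid_tag=mids[p - 1],
                    forward_primer=UNI18S,
                    reverse_primer=UNI18SR,
                    members=members,
                )
            )
    if not tagged:
        samples = [
            SampleDef(
                sample_id="pooled_populations",
                mid_tag=None,
                forward_primer=UNI18S,
                reverse_primer=UNI18SR,
                members=tuple(members_all),
            )
        ]
    return CommunityDesign(samples=tuple(samples))


def default_genomes(
    design: CommunityDesign,
    variants_by_species: dict[str, Sequence[IntragenomicVariant]],
    rdna_copy_number: int = 100,
) -> dict[str, IndividualGenome]:
    """Give every design member its species' variant set at copy frequency."""
    genomes: dict[str, IndividualGenome] = {}
    for sample in design.samples:
        for individual_id, _w in sample.members:
            species_id = individual_id.split("_")[0]
            variants = variants_by_species[species_id]
            genomes[individual_id] = IndividualGenome(
                individual_id=individual_id,
                species_id=species_id,
                rdna_copy_number=rdna_copy_number,
                variant_frequencies={
                    v.variant_id: v.copy_frequency for v in variants
                },
                variant_sequences={v.variant_id: v.sequence for v in variants},
            )
    return genomes


def _allocate_reads(design: CommunityDesign, reads_per_sample: int) -> list[int]:
    """Per-sample read counts proportional to total member weight.

    The total is fixed at reads_per_sample * n_samples exactly (largest
    remainder rounding), so read counts are conserved while larger
    populations receive proportionally more reads.  Equal-weight designs
    get exactly reads_per_sample per sample.
    """
    weights = np.array([s.total_weight for s in design.samples], dtype=float)
    total = reads_per_sample * len(design.samples)
    ideal = weights / weights.sum() * total
    counts = np.floor(ideal).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(ideal - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def _resolve_primer(primer: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in _BASES else str(rng.choice(list(IUPAC[c]))) for c in primer
    )


def _homopolymer_slips(
    seq: str, rng: np.random.Generator, rate: float
) -> str:
    """Lengthen or shorten homopolymer runs >= 3 by one base."""
    if rate <= 0:
        return seq
    out = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= 3 and rng.random() < rate:
            run = run + seq[i] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        i = j
    return "".join(out)


def _apply_substitutions(
    seq: str, rng: np.random.Generator, rate: float
) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for pos in hits:
        old = chars[pos]
        chars[pos] = str(rng.choice([b for b in _BASES if b != old]))
    return "".join(chars)


def _quality_string(
    length: int, rng: np.random.Generator, model: tuple[float, float, int]
) -> tuple[int, ...]:
    mean, decay, floor = model
    offset = rng.normal(0.0, 2.5)
    base = mean + offset - decay * np.arange(length)
    noisy = base + rng.normal(0.0, 1.5, size=length)
    return tuple(int(q) for q in np.clip(np.rint(noisy), floor, 40))


def simulate_reads(
    design: CommunityDesign,
    genomes: dict[str, IndividualGenome],
    config: SimulationConfig,
) -> tuple[list[RawRead], list[TruthRecord]]:
    """Simulate tagged amplicon reads with a truth record per read."""
    if not design.samples:
        raise ValueError("design has no samples")
    for sample in design.samples:
        for individual_id, _w in sample.members:
            if individual_id not in genomes:
                raise ValueError(f"no genome for member {individual_id!r}")
    counts = _allocate_reads(design, config.reads_per_sample)
    children = np.random.SeedSequence(config.seed).spawn(len(design.samples))
    reads: list[RawRead] = []
    truth: list[TruthRecord] = []
    for sample, n_reads, child in zip(design.samples, counts, children):
        rng = np.random.default_rng(child)
        # joint (individual, variant) distribution:
        # weight * rdna copy number * copy frequency
        choices: list[tuple[str, str, str]] = []
        probs: list[float] = []
        for individual_id, weight in sample.members:
            g = genomes[individual_id]
            for vid, freq in g.variant_frequencies.items():
                choices.append((individual_id, g.species_id, vid))
                probs.append(weight * g.rdna_copy_number * freq)
        p = np.asarray(probs)
        p = p / p.sum()
        seqs = {
            vid: genomes[iid].variant_sequences[vid]
            for iid, _sp, vid in choices
        }
        for r in range(n_reads):
            idx = int(rng.choice(len(choices), p=p))
            individual_id, species_id, variant_id = choices[idx]
            insert = seqs[variant_id]
            is_chimera = False
            parents = None
            if config.chimera_fraction > 0 and rng.random() < config.chimera_fraction:
                idx2 = int(rng.choice(len(choices), p=p))
                iid2, _sp2, vid2 = choices[idx2]
                other = seqs[vid2]
                lo, hi = 50, min(len(insert), len(other)) - 50
                if hi > lo:
                    cross = int(rng.integers(lo, hi + 1))
                    insert = insert[:cross] + other[cross:]
                    is_chimera = True
                    parents = (individual_id, iid2)
            insert = _apply_substitutions(
                insert, rng, config.pcr_substitution_rate
            )
            mid = sample.mid_tag or ""
            primer = _resolve_primer(sample.forward_primer, rng)
            full = mid + primer + insert
            full = _apply_substitutions(full, rng, config.seq_substitution_rate)
            full = _homopolymer_slips(full, rng, config.homopolymer_indel_rate)
            full = full[: config.read_length]
            read_id = f"{sample.sample_id}_r{r + 1:06d}"
            reads.append(
                RawRead(read_id, full, _quality_string(len(full), rng, config.quality_model))
            )
            truth.append(
                TruthRecord(
                    read_id=read_id,
                    sample_id=sample.sample_id,
                    individual_id=individual_id,
                    species_id=species_id,
                    variant_id=variant_id,
                    is_chimera=is_chimera,
                    chimera_parents=parents,
                )
            )
    return reads, truth


def write_fixture(
    outdir,
    design: CommunityDesign,
    templates: Sequence[ReferenceTemplate],
    variants_by_species: dict[str, Sequence[IntragenomicVariant]],
    reads: Sequence[RawRead],
    truth: Sequence[TruthRecord],
) -> None:
    """Write reads.fastq / refs.fasta / tagmap.tsv / truth.tsv / design.json."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "reads.fastq"), "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
    with open(os.path.join(outdir, "refs.fasta"), "w") as fh:
        for t in templates:
            # the dominant (v1) variant is the template itself
            fh.write(f">{t.species_id}\n{t.sequence}\n")
    with open(os.path.join(outdir, "tagmap.tsv"), "w") as fh:
        fh.write("sample_id\tmid\tfwd_primer\n")
        for s in design.samples:
            fh.write(f"{s.sample_id}\t{s.mid_tag or '-'}\t{s.forward_primer}\n")
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write(
            "read_id\tsample_id\tindividual_id\tspecies_id\tvariant_id"
            "\tis_chimera\tparent_a\tparent_b\n"
        )
        for t in truth:
            pa, pb = t.chimera_parents or ("-", "-")
            fh.write(
                f"{t.read_id}\t{t.sample_id}\t{t.individual_id}"
                f"\t{t.species_id}\t{t.variant_id}"
                f"\t{int(t.is_chimera)}\t{pa}\t{pb}\n"
            )
    payload = {
        "samples": [
            {
                "sample_id": s.sample_id,
                "mid": s.mid_tag,
                "fwd_primer": s.forward_primer,
                "rev_primer": s.reverse_primer,
                "members": [[i, w] for i, w in s.members],
            }
            for s in design.samples
        ],
        "variants": {
            sp: [
                {
                    "variant_id": v.variant_id,
                    "copy_frequency": v.copy_frequency,
                    "n_edits": len(v.mutation_record),
                }
                for v in vs
            ]
            for sp, vs in variants_by_species.items()
        },
    }
    with open(os.path.join(outdir, "design.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> list[TruthRecord]:
    """Re-load a truth table written by write_fixture."""
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            (rid, sid, iid, sp, vid, chim, pa, pb) = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    rid, sid, iid, sp, vid,
                    is_chimera=bool(int(chim)),
                    chimera_parents=None if pa == "-" else (pa, pb),
                )
            )
    return out
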