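"""Benchmark per-sample OTU tables from a 454 mock zooplankton experiment.

Transcribed 3%-threshold clustering outcomes for two tagged mock
zooplankton communities sequenced on a 454 GS-FLX platform: a tagged
individuals community (19 retained single specimens, one MID tag each)
and a tagged populations community (24 conspecific populations of roughly
5/10/30 individuals).  Per-sample OTU counts are given for both singleton
policies; population entries also carry the declared number of individuals
and the filtered reads contributing to OTUs.

These tables are inputs for the evaluation module: aggregating them
reproduces the benchmark's 1:1 correspondence percentages (84% and 74%
for individuals, 63% and 33% for populations) and the maximum of five
OTUs from any single population.

The rotifer entry (Brachionus calyciflorus) yielded no non-singleton
uniques, hence 0 OTUs under the exclude policy: the sample still counts,
as a non-1:1 outcome, in the aggregate percentage.
"""

from __future__ import annotations

__all__ = [
    "TAGGED_INDIVIDUALS_OTU_COUNTS",
    "TAGGED_POPULATIONS",
    "tagged_individuals_otu_counts",
    "tagged_populations_otu_counts",
]

# sample -> (n_otus singletons excluded, n_otus singletons included)
TAGGED_INDIVIDUALS_OTU_COUNTS: dict[str, tuple[int, int]] = {
    "Artemia salina": (1, 2),
    "Balanus crenatus": (1, 1),
    "Brachionus calyciflorus": (0, 1),
    "Cancer spp.": (1, 1),
    "Cercopagis pengoi": (1, 2),
    "Ciona intestinalis": (1, 2),
    "Corbicula fluminea": (2, 4),
    "Daphnia mendotae": (1, 1),
    "Diacyclops thomasi": (1, 1),
    "Echinogammarus ischnus": (1, 1),
    "Epischura lacustris": (1, 1),
    "Leptodiaptomus ashlandi": (1, 1),
    "Mesocyclops edax": (1, 1),
    "Microsetella norvegica": (1, 1),
    "Oikopleura labradoriensis": (1, 1),
    "Palaemonetes spp.": (2, 3),
    "Pleuroxus denticulatus": (1, 1),
    "Themisto libellula": (1, 1),
    "Senecella calanoides": (1, 1),
}

# population -> (n individuals, OTUs excl. singletons, OTUs incl. singletons,
#                reads in OTUs excl., reads in OTUs incl.)
TAGGED_POPULATIONS: dict[str, tuple[int, int, int, int, int]] = {
    "5x Corbicula fluminea": (5, 2, 3, 14860, 15211),
    "10x Corbicula fluminea": (10, 1, 3, 1465, 1739),
    "30x Corbicula fluminea": (30, 5, 5, 14999, 17436),
    "3x Neotrypaea californiensis": (3, 1, 1, 4186, 4793),
    "5x Balanus crenatus": (5, 2, 2, 2797, 3609),
    "10x Balanus crenatus": (10, 2, 2, 22387, 23805),
    "17x Balanus spp.": (17, 1, 1, 8888, 9765),
    "5x Crangonyx": (5, 1, 1, 2326, 2631),
    "10x Hyalella clade 8": (10, 3, 3, 2338, 2878),
    "5x Daphnia mendotae": (5, 1, 2, 3901, 4455),
    "10x Daphnia pulex": (10, 1, 1, 12825, 13394),
    "31x Daphnia pulex": (31, 1, 1, 30041, 31495),
    "5x Leptodiaptomus minutus": (5, 2, 4, 12108, 12918),
    "9x Leptodiaptomus sicilis": (9, 2, 3, 3707, 5088),
    "30x Leptodiaptomus minutus": (30, 1, 2, 38038, 39948),
    "5x Diacyclops thomasi": (5, 1, 1, 565, 860),
    "8x Diacyclops thomasi": (8, 1, 1, 1343, 1832),
    "27x Diacyclops thomasi": (27, 1, 1, 26959, 28075),
    "5x Leptodora kindtii": (5, 1, 2, 10915, 11434),
    "10x Leptodora kindtii": (10, 1, 3, 2807, 3535),
    "28x Leptodora kindtii": (28, 2, 4, 10323, 12455),
    "5x Limnoperna fortunei": (5, 1, 2, 3048, 3388),
    "10x Limnoperna fortunei": (10, 2, 3, 16014, 16671),
    "30x Limnoperna fortunei": (30, 1, 2, 3924, 4595),
}


def tagged_individuals_otu_counts(policy: str) -> dict[str, int]:
    """Per-individual OTU counts under a singleton policy."""
    idx = {"exclude": 0, "include": 1}[policy]
    return {s: v[idx] for s, v in TAGGED_INDIVIDUALS_OTU_COUNTS.items()}


def tagged_populations_otu_counts(policy: str) -> dict[str, int]:
    """Per-population OTU counts under a singleton policy."""
    idx = {"exclude": 1, "include": 2}[policy]
    return {s: v[idx] for s, v in TAGGED_POPULATIONS.items()}


def tagged_populations_sizes_and_reads(policy: str):
    """Aligned (sizes, read counts, OTU counts) vectors for correlations."""
    idx_otu = {"exclude": 1, "include": 2}[policy]
    idx_reads = {"exclude": 3, "include": 4}[policy]
    sizes, reads, otus = [], [], []
    for _name, row in TAGGED_POPULATIONS.items():
        sizes.append(row[0])
        reads.append(row[idx_reads])
        otus.append(row[idx_otu])
    return sizes, reads, otus
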