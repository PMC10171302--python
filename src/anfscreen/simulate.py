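"""Synthetic multi-genome collections with planted ANF genes.

The generator emulates the statistical structure of group-wise bacterial
pan-genome collections: each taxon group has, per ANF category, a
probability that a genome carries at least one gene of that category.
Carried genes are diverged copies of the catalog's reference proteins
(independent per-residue substitutions at a configurable rate, no indels,
so the expected identity to the reference is ~1 − mutation_rate), embedded
among decoy proteins drawn uniformly from the 20 residues and annotated
"hypothetical protein".  Planted genes carry the enzyme's name as product
(annotated regime) or "hypothetical protein" as well (unannotated regime,
detectable only by full-scan alignment).

Every run is fully determined by the seed; per-genome substreams are
derived by stable hashing of the genome id, so generation is independent of
genome insertion order.  A :class:`TruthRow` table records every planted
gene for recovery benchmarking.

:func:`emulate_study_groups` configures four groups — Bacillus_subtilis,
Lactobacillaceae, Pediococcus and Enterobacteriaceae — with group-specific
presence probabilities (e.g. phytase universal in the Bacillus-like group,
absent from the Lactobacillus- and Pediococcus-like groups, and present in
~61% of the Enterobacteriaceae-like group).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .catalog import ANFCatalog, default_catalog
from .io import GenomeRecord, ProteinRecord

__all__ = [
    "SyntheticConfig",
    "TruthRow",
    "generate_collection",
    "emulate_study_groups",
    "STUDY_GROUP_PRESENCE",
]

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    ``presence_prob`` maps ``(taxon_group, category_id)`` to the probability
    a genome of that group carries ≥1 gene of the category (missing keys
    mean 0).  ``copy_number`` maps ``category_id`` to ``(max_extra,
    p_extra)``: a carrying genome plants ``1 + Binomial(max_extra,
    p_extra)`` copies.  ``mutation_rate`` is the per-residue substitution
    probability (0–0.5, substitutions only).
    """

    n_genomes: dict[str, int]
    presence_prob: dict[tuple[str, str], float]
    copy_number: dict[str, tuple[int, float]] = field(default_factory=dict)
    mutation_rate: float = 0.05
    n_decoys: int = 25
    decoy_length_range: tuple[int, int] = (80, 400)
    annotated: bool = True
    seed: int = 0

    def validate(self, catalog: ANFCatalog) -> None:
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5]")
        for key, p in self.presence_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence_prob{key} = {p} outside [0, 1]")
        lo, hi = self.decoy_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid decoy_length_range")
        with_refs = {
            cat.category_id
            for cat in catalog.categories
            if any(enz.reference_proteins for enz in cat.enzymes)
        }
        for (group, category), p in self.presence_prob.items():
            if p > 0 and category not in set(catalog.category_ids):
                raise ValueError(f"unknown category {category!r} for group {group!r}")
            if p > 0 and category not in with_refs and not self.annotated:
                raise ValueError(
                    f"category {category!r} has no reference proteins; its "
                    "planted genes would be undetectable in the unannotated regime"
                )


@dataclass(frozen=True)
class TruthRow:
    """One planted gene: where it is, what it is, how diverged it is."""

    genome_id: str
    protein_id: str
    enzyme_id: str
    category_id: str
    n_mutations: int


def _genome_rng(seed: int, genome_id: str) -> np.random.Generator:
    # stable per-genome substream: insertion-order independent
    return np.random.default_rng([seed, zlib.crc32(genome_id.encode())])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate == 0.0:
        return seq, 0
    out = list(seq)
    n_mut = 0
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        choices = [c for c in AA if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
        n_mut += 1
    return "".join(out), n_mut


def generate_collection(
    config: SyntheticConfig, catalog: ANFCatalog | None = None
) -> tuple[list[GenomeRecord], list[TruthRow]]:
    """Generate genomes and the ground-truth table of planted genes.

    Identical configs (including seed) produce identical output; genomes
    appear in the order of ``config.n_genomes`` groups, ``group_000`` style
    ids within each group.
    """
    if catalog is None:
        catalog = default_catalog()
    config.validate(catalog)
    genomes: list[GenomeRecord] = []
    truth: list[TruthRow] = []
    for group, count in config.n_genomes.items():
        for i in range(count):
            genome_id = f"{group}_{i:03d}"
            rng = _genome_rng(config.seed, genome_id)
            proteins: list[ProteinRecord] = []
            counter = 0
            for cat in catalog.categories:
                p = config.presence_prob.get((group, cat.category_id), 0.0)
                if p <= 0.0 or rng.random() >= p:
                    continue
                max_extra, p_extra = config.copy_number.get(
                    cat.category_id, (0, 0.0)
                )
                n_copies = 1 + int(rng.binomial(max_extra, p_extra)) if max_extra else 1
                candidates = [
                    enz for enz in cat.enzymes if enz.reference_proteins
                ]
                for _ in range(n_copies):
                    if candidates:
                        enz = candidates[rng.integers(len(candidates))]
                        ref_id, ref_seq = enz.reference_proteins[
                            rng.integers(len(enz.reference_proteins))
                        ]
                        seq, n_mut = _mutate(ref_seq, config.mutation_rate, rng)
                    else:
                        enz = cat.enzymes[rng.integers(len(cat.enzymes))]
                        seq, n_mut = _random_seq(rng, 150, 300), 0
                    counter += 1
                    pid = f"{genome_id}_p{counter:04d}"
                    proteins.append(
                        ProteinRecord(
                            protein_id=pid,
                            genome_id=genome_id,
                            product=enz.name if config.annotated else
                            "hypothetical protein",
                            sequence=seq,
                        )
                    )
                    truth.append(
                        TruthRow(
                            genome_id=genome_id,
                            protein_id=pid,
                            enzyme_id=enz.enzyme_id,
                            category_id=cat.category_id,
                            n_mutations=n_mut,
                        )
                    )
            lo, hi = config.decoy_length_range
            for _ in range(config.n_decoys):
                counter += 1
                proteins.append(
                    ProteinRecord(
                        protein_id=f"{genome_id}_p{counter:04d}",
                        genome_id=genome_id,
                        product="hypothetical protein",
                        sequence=_random_seq(rng, lo, hi),
                    )
                )
            genomes.append(
                GenomeRecord(
                    genome_id=genome_id,
                    label=genome_id,
                    taxon_group=group,
                    proteins=tuple(proteins),
                )
            )
    return genomes, truth


def _random_seq(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AA[j] for j in rng.integers(0, len(AA), size=length))


# ---------------------------------------------------------------------------
# the four-group study layout

#: Per-group probability that a genome carries >=1 gene of each category.
#: Universal-presence and strict-absence entries follow the qualitative
#: group patterns of the study design; fractional entries are the group-wise
#: tallies (e.g. Enterobacteriaceae phytase 91/150 = 0.6067).
STUDY_GROUP_PRESENCE: dict[tuple[str, str], float] = {
    # Bacillus subtilis-like: phytase, PAD, trypsin, alpha-Gal in every genome
    ("Bacillus_subtilis", "phytate_degradation"): 1.0,
    ("Bacillus_subtilis", "phenolic_compounds"): 1.0,
    ("Bacillus_subtilis", "trypsin_protease"): 1.0,
    ("Bacillus_subtilis", "alpha_gos"): 1.0,
    # Lactobacillaceae-like: no phytase, seven other categories at the
    # observed genome fractions
    ("Lactobacillaceae", "myo_inositol"): 119 / 155,
    ("Lactobacillaceae", "tannin_degradation"): 17 / 155,
    ("Lactobacillaceae", "phenolic_compounds"): 73 / 150,
    ("Lactobacillaceae", "lectin_metabolism"): 26 / 150,
    ("Lactobacillaceae", "trypsin_protease"): 36 / 155,
    ("Lactobacillaceae", "saponin_degradation"): 31 / 151,
    ("Lactobacillaceae", "alpha_gos"): 95 / 155,
    # Pediococcus-like: indirect phytate metabolism only, trypsin universal
    ("Pediococcus", "myo_inositol"): 0.75,
    ("Pediococcus", "phenolic_compounds"): 7 / 9,
    ("Pediococcus", "trypsin_protease"): 1.0,
    ("Pediococcus", "alpha_gos"): 1 / 9,
    # Enterobacteriaceae-like: phytase in ~61%, UbiX universal
    ("Enterobacteriaceae", "phytate_degradation"): 91 / 150,
    ("Enterobacteriaceae", "tannin_degradation"): 9 / 150,
    ("Enterobacteriaceae", "phenolic_compounds"): 1.0,
    ("Enterobacteriaceae", "lectin_metabolism"): 8 / 150,
    ("Enterobacteriaceae", "trypsin_protease"): 15 / 150,
    ("Enterobacteriaceae", "saponin_degradation"): 4 / 150,
    ("Enterobacteriaceae", "alpha_gos"): 81 / 150,
}

#: Extra-copy distributions per category: (max_extra, p_extra).
DEFAULT_COPY_NUMBER: dict[str, tuple[int, float]] = {
    "phytate_degradation": (2, 0.18),
    "myo_inositol": (6, 0.20),
    "tannin_degradation": (2, 0.15),
    "phenolic_compounds": (2, 0.30),
    "lectin_metabolism": (1, 0.30),
    "trypsin_protease": (1, 0.20),
    "saponin_degradation": (3, 0.20),
    "alpha_gos": (6, 0.20),
}


def emulate_study_groups(
    scale: int | dict[str, int],
    seed: int = 0,
    mutation_rate: float = 0.05,
    annotated: bool = True,
    n_decoys: int = 25,
    catalog: ANFCatalog | None = None,
) -> tuple[list[GenomeRecord], list[TruthRow]]:
    """Four-group collection with the study's presence patterns.

    *scale* is either genomes per group (int, >=2) or a per-group mapping.
    """
    if isinstance(scale, int):
        if scale < 2:
            raise ValueError("scale must be >= 2")
        n_genomes = {
            g: scale
            for g in (
                "Bacillus_subtilis",
                "Lactobacillaceae",
                "Pediococcus",
                "Enterobacteriaceae",
            )
        }
    else:
        n_genomes = dict(scale)
    config = SyntheticConfig(
        n_genomes=n_genomes,
        presence_prob=dict(STUDY_GROUP_PRESENCE),
        copy_number=dict(DEFAULT_COPY_NUMBER),
        mutation_rate=mutation_rate,
        n_decoys=n_decoys,
        annotated=annotated,
        seed=seed,
    )
    return generate_collection(config, catalog)
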