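"""Synonymous-permutation null models.

Two randomizations generate the null against which native folding is
compared:

* **CDS-wide**: synonymous codons are permuted within each CDS.  This
  preserves the encoded protein, the CDS's codon multiset, and its
  nucleotide counts (hence GC) — only the *arrangement* of synonymous
  codons is destroyed.
* **Positional (vertical)**: synonymous codons are permuted between
  codons at the same position (relative to the CDS start) across all
  CDSs of a genome, preserving per-position genome-wide codon counts.

Both leave every protein sequence untouched, so any folding-energy
difference between native and randomized sequences is attributable to
codon arrangement alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .sequence_io import CodingSequence, GenomeDataset

__all__ = [
    "NullEnsemble",
    "synonymous_families",
    "shuffle_synonymous_within_cds",
    "shuffle_synonymous_positional",
    "build_null_ensemble",
    "build_genome_ensembles",
    "DEFAULT_N_RANDOMIZATIONS",
]

DEFAULT_N_RANDOMIZATIONS = 20

_FAMILY_CACHE: dict[int, dict[str, str]] = {}


def synonymous_families(genetic_code: int = 1) -> dict[str, str]:
    """Map codon -> family label (amino acid, or '*' for stops)."""
    fam = _FAMILY_CACHE.get(genetic_code)
    if fam is None:
        table = CodonTable.unambiguous_dna_by_id[genetic_code]
        fam = {codon: aa for codon, aa in table.forward_table.items()}
        for codon in table.stop_codons:
            fam[codon] = "*"
        _FAMILY_CACHE[genetic_code] = fam
    return fam


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.md5(text.encode()).digest()[:4], "little")


def _rng_for(seed: int, replicate: int, key: str) -> np.random.Generator:
    # replicate seeds derived from (master seed, replicate, id hash) so
    # ensembles do not depend on processing order
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(int(replicate), _stable_hash(key)))
    return np.random.Generator(np.random.PCG64(ss))


def shuffle_synonymous_within_cds(cds: CodingSequence, rng_seed: int,
                                  replicate: int = 0,
                                  pin_first_codon: bool = False) -> str:
    """Permute synonymous codons within one CDS (CDS-wide null).

    Each amino-acid family's codons are shuffled uniformly among that
    family's positions (Fisher-Yates via the seeded generator).  Stop
    codons form their own family.  With ``pin_first_codon`` the start
    codon keeps its position (off by default).
    """
    rng = _rng_for(rng_seed, replicate, cds.id)
    return _shuffle_codons(cds, rng, pin_first_codon)


def _shuffle_codons(cds: CodingSequence, rng: np.random.Generator,
                    pin_first_codon: bool) -> str:
    fam = synonymous_families(cds.genetic_code)
    codons = cds.codons
    first = 1 if pin_first_codon else 0
    positions_by_fam: dict[str, list[int]] = {}
    for i in range(first, len(codons)):
        positions_by_fam.setdefault(fam[codons[i]], []).append(i)
    out = list(codons)
    for positions in positions_by_fam.values():
        if len(positions) < 2:
            continue
        vals = [codons[i] for i in positions]
        perm = rng.permutation(len(vals))
        for slot, j in zip(positions, perm):
            out[slot] = vals[j]
    return "".join(out)


def shuffle_synonymous_positional(genome: GenomeDataset, rng_seed: int,
                                  replicate: int = 0) -> GenomeDataset:
    """Permute synonymous codons across CDSs at each codon position.

    For every codon position k (from the CDS start) and family a, the
    codons encoding a at position k across the genome are pooled and
    redealt; each CDS keeps its protein, and the genome keeps its
    per-position codon counts.
    """
    rng = _rng_for(rng_seed, replicate, genome.species_id)
    codon_lists = [c.codons for c in genome.cds_list]
    fams = [synonymous_families(c.genetic_code) for c in genome.cds_list]
    max_len = max((len(cl) for cl in codon_lists), default=0)
    new_lists = [list(cl) for cl in codon_lists]
    for k in range(max_len):
        pools: dict[str, list[int]] = {}  # family -> CDS indices with position k
        for p, cl in enumerate(codon_lists):
            if k < len(cl):
                pools.setdefault(fams[p][cl[k]], []).append(p)
        for members in pools.values():
            if len(members) < 2:
                continue
            vals = [codon_lists[p][k] for p in members]
            perm = rng.permutation(len(vals))
            for p, j in zip(members, perm):
                new_lists[p][k] = vals[j]
    new_cds = [CodingSequence(c.id, "".join(cl), c.genetic_code)
               for c, cl in zip(genome.cds_list, new_lists)]
    return GenomeDataset(genome.species_id, new_cds, genome.traits)


@dataclass
class NullEnsemble:
    """N randomized variants of one CDS under one null model."""

    cds_id: str
    variants: list[str]
    null_model: str  # 'cds_wide' or 'positional'
    seed: int

    def __len__(self) -> int:
        return len(self.variants)


def build_null_ensemble(cds: CodingSequence, n: int = DEFAULT_N_RANDOMIZATIONS,
                        rng_seed: int = 0,
                        pin_first_codon: bool = False) -> NullEnsemble:
    """N independent CDS-wide randomizations with derived replicate seeds.

    Bit-reproducible for a given (seed, cds id) regardless of the order
    CDSs are processed in.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    variants = [shuffle_synonymous_within_cds(cds, rng_seed, replicate=r,
                                              pin_first_codon=pin_first_codon)
                for r in range(n)]
    return NullEnsemble(cds.id, variants, "cds_wide", rng_seed)


def build_genome_ensembles(genome: GenomeDataset, null_model: str = "cds_wide",
                           n: int = DEFAULT_N_RANDOMIZATIONS, rng_seed: int = 0,
                           pin_first_codon: bool = False) -> dict[str, NullEnsemble]:
    """Per-CDS ensembles under either null model.

    For the positional model, replicate r is one genome-wide vertical
    shuffle; the ensemble for each CDS collects its copy from each
    shuffled genome.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if null_model == "cds_wide":
        return {c.id: build_null_ensemble(c, n, rng_seed, pin_first_codon)
                for c in genome.cds_list}
    if null_model == "positional":
        variant_lists: dict[str, list[str]] = {c.id: [] for c in genome.cds_list}
        for r in range(n):
            shuffled = shuffle_synonymous_positional(genome, rng_seed, replicate=r)
            for c in shuffled.cds_list:
                variant_lists[c.id].append(c.seq)
        return {cid: NullEnsemble(cid, vs, "positional", rng_seed)
                for cid, vs in variant_lists.items()}
    raise ValueError(f"unknown null model {null_model!r}")
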