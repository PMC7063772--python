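"""Synthetic trees, traits and genomes with known ground truth.

Real cohorts confound amino-acid content, codon-usage bias, GC-content
and codon *arrangement*.  The generator separates them: genomes are
sampled codon-by-codon with controllable GC and codon-usage skew, and
a folding-strength signal is then injected purely by *rearranging*
synonymous codons (hill-climbing over swaps), so composition is
provably identical before and after injection and any detected ΔLFE is
attributable to arrangement alone — exactly the quantity the null
models isolate.  Trees are Yule; continuous traits evolve by Brownian
motion on them; binary traits are painted on clades.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.optimize import brentq

from .folding import DEFAULT_STEP, DEFAULT_WINDOW, encode_seq, fold_energies_builtin
from .phylo_gls import brownian_covariance
from .randomization import synonymous_families
from .sequence_io import CodingSequence, GenomeDataset
from .traits_cub import SpeciesTraits

__all__ = [
    "SimulationConfig", "BiasRegion",
    "simulate_tree", "simulate_traits_bm", "paint_clade_trait",
    "generate_genome", "inject_folding_bias", "simulate_profile_cohort",
]


@dataclass
class BiasRegion:
    """One injected arrangement bias: nt range, direction, search effort."""

    anchor: str           # 'start' or 'end'
    start_nt: int         # inclusive, from the anchor
    end_nt: int           # exclusive, from the anchor
    direction: str        # 'stronger' (lower energy) or 'weaker'
    effort: int = 500     # hill-climb proposals per CDS


@dataclass
class SimulationConfig:
    n_species: int = 10
    n_cds: int = 100
    cds_length: int = 300            # nt, multiple of 3, incl. start + stop
    target_gc: float = 0.5           # per species, in [0.2, 0.8]
    cub_strength: float = 0.0        # 0 = uniform synonymous usage
    bias_spec: list[BiasRegion] = field(default_factory=list)
    bm_sigma2: float = 1.0
    yule_rate: float = 1.0
    genetic_code: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.cds_length % 3 or self.cds_length < 9:
            raise ValueError("cds_length must be a multiple of 3, >= 9")
        if not 0.0 <= self.cub_strength <= 1.0:
            raise ValueError("cub_strength must lie in [0, 1]")


# ----------------------------------------------------------------- tree

def simulate_tree(n_species: int, yule_rate: float = 1.0,
                  seed: int = 0) -> dendropy.Tree:
    """Ultrametric binary Yule (pure-birth) tree with labelled tips S001..."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    from dendropy.model import birthdeath
    rng = random.Random(int(seed))
    tree = birthdeath.birth_death_tree(
        birth_rate=yule_rate, death_rate=0.0, num_extant_tips=n_species,
        rng=rng)
    # the simulator stops at the n-th speciation, leaving the youngest
    # cherry with zero-length tip branches; run the clock forward by the
    # waiting time to the (unrealized) next event so every branch is
    # positive and the tree stays ultrametric
    extra = rng.expovariate(n_species * yule_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for i, leaf in enumerate(tree.leaf_node_iter(), 1):
        leaf.taxon.label = f"S{i:03d}"
    return tree


def simulate_traits_bm(tree: dendropy.Tree, root_value: float,
                       sigma2: float, seed: int = 0) -> pd.Series:
    """Brownian trait at the tips: N(root_value, sigma2 · V(tree))."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    cov = brownian_covariance(tree)
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        vals = np.full(len(cov.tip_ids), float(root_value))
    else:
        vals = rng.multivariate_normal(
            np.full(len(cov.tip_ids), float(root_value)), sigma2 * cov.V,
            method="cholesky" if _is_pd(cov.V) else "eigh")
    return pd.Series(vals, index=cov.tip_ids)


def _is_pd(V: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(V)
        return True
    except np.linalg.LinAlgError:
        return False


def paint_clade_trait(tree: dendropy.Tree, n_carriers: int,
                      seed: int = 0) -> pd.Series:
    """Binary trait on whole clades totalling ~``n_carriers`` tips.

    Clades are drawn at random (smallest first beyond the target is
    rejected), emulating traits like endosymbiosis that arise once per
    lineage rather than independently per species.
    """
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    rng = np.random.default_rng(seed)
    carriers: set[str] = set()
    internal = [nd for nd in tree.preorder_node_iter() if nd.child_nodes()]
    order = rng.permutation(len(internal))
    for idx in order:
        clade_tips = {l.taxon.label for l in internal[idx].leaf_iter()}
        if len(carriers | clade_tips) <= n_carriers:
            carriers |= clade_tips
        if len(carriers) >= n_carriers:
            break
    # top up with single tips if clades alone undershoot
    for t in rng.permutation(tips):
        if len(carriers) >= n_carriers:
            break
        carriers.add(str(t))
    return pd.Series([t in carriers for t in tips], index=tips)


# --------------------------------------------------------------- genome

_GC_COUNT = {b: (1 if b in "GC" else 0) for b in "ACGT"}


def _codon_gc(codon: str) -> int:
    return sum(_GC_COUNT[b] for b in codon)


def _family_tables(genetic_code: int):
    fam_of = synonymous_families(genetic_code)
    fams: dict[str, list[str]] = {}
    for codon, aa in fam_of.items():
        fams.setdefault(aa, []).append(codon)
    for v in fams.values():
        v.sort()
    return fams


def _codon_distributions(fams: dict[str, list[str]], aa_freqs: dict[str, float],
                         target_gc: float, cub_strength: float,
                         preferred: dict[str, str]):
    """Per-family codon probabilities hitting the GC target.

    Within each family, p(c) ∝ exp(beta·GC(c)) mixed with a point mass
    on the family's preferred codon (weight = cub_strength); beta is
    solved so the expected GC fraction of a sampled codon equals
    ``target_gc``.  Returns (distributions, achieved_gc).
    """
    aas = [a for a in fams if a != "*"]

    def expected_gc(beta: float) -> float:
        tot = 0.0
        for aa in aas:
            codons = fams[aa]
            w = np.exp(beta * np.array([_codon_gc(c) for c in codons]))
            w /= w.sum()
            p = (1 - cub_strength) * w
            p[codons.index(preferred[aa])] += cub_strength
            tot += aa_freqs[aa] * float(p @ [_codon_gc(c) / 3 for c in codons])
        return tot

    lo, hi = -30.0, 30.0
    glo, ghi = expected_gc(lo), expected_gc(hi)
    if not glo <= target_gc <= ghi:
        import warnings
        beta = lo if target_gc < glo else hi
        warnings.warn(
            f"target GC {target_gc:.2f} unreachable (range "
            f"{glo:.2f}-{ghi:.2f}); using best effort", stacklevel=2)
    else:
        beta = brentq(lambda b: expected_gc(b) - target_gc, lo, hi, xtol=1e-10)
    dists = {}
    for aa in aas:
        codons = fams[aa]
        w = np.exp(beta * np.array([_codon_gc(c) for c in codons]))
        w /= w.sum()
        p = (1 - cub_strength) * w
        p[codons.index(preferred[aa])] += cub_strength
        dists[aa] = (codons, p / p.sum())
    return dists, expected_gc(beta)


def generate_genome(config: SimulationConfig, species_id: str,
                    seed: int | None = None,
                    traits: SpeciesTraits | None = None) -> GenomeDataset:
    """Codon-sampled genome for one species.

    Each CDS starts with ATG, ends with a single stop codon, and draws
    interior amino acids from a uniform frequency vector; synonymous
    codons follow the GC-calibrated, optionally skewed distribution.
    Achieved GC lands within ~2% of the target for cohorts of 100+
    CDSs (amino-acid constraints permitting).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fams = _family_tables(config.genetic_code)
    aas = sorted(a for a in fams if a != "*")
    aa_freqs = {a: 1.0 / len(aas) for a in aas}
    preferred = {a: fams[a][int(rng.integers(len(fams[a])))] for a in aas}
    dists, _ = _codon_distributions(fams, aa_freqs, config.target_gc,
                                    config.cub_strength, preferred)
    stop = sorted(fams["*"])[0]
    n_interior = config.cds_length // 3 - 2
    aa_list = np.array(aas)
    aa_p = np.array([aa_freqs[a] for a in aas])
    cds_list = []
    for g in range(config.n_cds):
        draw = rng.choice(aa_list, size=n_interior, p=aa_p)
        codons = ["ATG"]
        for aa in draw:
            codons_aa, p = dists[aa]
            codons.append(codons_aa[int(rng.choice(len(codons_aa), p=p))])
        codons.append(stop)
        cds_list.append(CodingSequence(f"{species_id}_g{g + 1:04d}",
                                       "".join(codons), config.genetic_code))
    return GenomeDataset(species_id, cds_list, traits)


# ------------------------------------------------------- bias injection

def _region_window_starts(length: int, region: BiasRegion,
                          window: int = DEFAULT_WINDOW,
                          step: int = DEFAULT_STEP) -> np.ndarray:
    """Absolute start indices of grid windows lying inside the region."""
    if region.anchor == "start":
        a, b = region.start_nt, min(region.end_nt, length)
    elif region.anchor == "end":
        a, b = max(0, length - region.end_nt), length - region.start_nt
    else:
        raise ValueError(f"unknown anchor {region.anchor!r}")
    starts = np.arange(0, length - window + 1, step)
    return starts[(starts >= a) & (starts + window <= b)]


def inject_folding_bias(genome: GenomeDataset, bias_spec: list[BiasRegion],
                        seed: int = 0) -> GenomeDataset:
    """Rearrange synonymous codons to strengthen/weaken regional folding.

    Per CDS and region, hill-climbing proposes swaps of two synonymous
    codons (at least one inside the region) and accepts a move iff it
    moves the mean builtin window energy over the region's windows in
    the requested direction.  Protein, codon multiset and GC are exact
    invariants of every move.
    """
    rng = np.random.default_rng(seed)
    fam_of = synonymous_families(genome.cds_list[0].genetic_code
                                 if genome.cds_list else 1)
    new_cds = []
    for cds in genome.cds_list:
        codons = cds.codons
        n_cod = len(codons)
        fam = [fam_of[c] for c in codons]
        fam_positions: dict[str, list[int]] = {}
        for i, f in enumerate(fam):
            fam_positions.setdefault(f, []).append(i)
        codes = encode_seq(cds.seq)
        for region in bias_spec:
            w_starts = _region_window_starts(len(codes), region)
            if len(w_starts) == 0:
                continue
            sign = 1.0 if region.direction == "stronger" else -1.0
            energies = fold_energies_builtin(
                np.stack([codes[s:s + DEFAULT_WINDOW] for s in w_starts]))
            # codon positions whose bases fall inside some region window
            lo = int(w_starts.min())
            hi = int(w_starts.max()) + DEFAULT_WINDOW
            in_region = [i for i in range(n_cod)
                         if i * 3 < hi and i * 3 + 3 > lo]
            candidates = [i for i in in_region if len(fam_positions[fam[i]]) > 1]
            if not candidates:
                continue
            for _ in range(region.effort):
                p1 = candidates[int(rng.integers(len(candidates)))]
                others = fam_positions[fam[p1]]
                p2 = others[int(rng.integers(len(others)))]
                if p2 == p1 or codons[p1] == codons[p2]:
                    continue
                # windows touched by either codon
                touched = np.where(
                    ((w_starts < p1 * 3 + 3) & (w_starts + DEFAULT_WINDOW > p1 * 3))
                    | ((w_starts < p2 * 3 + 3) & (w_starts + DEFAULT_WINDOW > p2 * 3))
                )[0]
                if len(touched) == 0:
                    continue
                c1, c2 = codons[p1], codons[p2]
                codons[p1], codons[p2] = c2, c1
                codes[p1 * 3:p1 * 3 + 3] = encode_seq(c2)
                codes[p2 * 3:p2 * 3 + 3] = encode_seq(c1)
                new_e = fold_energies_builtin(
                    np.stack([codes[s:s + DEFAULT_WINDOW]
                              for s in w_starts[touched]]))
                delta = float(new_e.sum() - energies[touched].sum())
                if sign * delta < 0:      # improvement in requested direction
                    energies[touched] = new_e
                else:                      # revert
                    codons[p1], codons[p2] = c1, c2
                    codes[p1 * 3:p1 * 3 + 3] = encode_seq(c1)
                    codes[p2 * 3:p2 * 3 + 3] = encode_seq(c2)
        new_cds.append(CodingSequence(cds.id, "".join(codons), cds.genetic_code))
    return GenomeDataset(genome.species_id, new_cds, genome.traits)


# ------------------------------------------------- profile-level cohort

_TEMPLATE_OFFSETS = np.arange(0, 301, 10)


def _template_profile(anchor: str) -> np.ndarray:
    """Canonical strong-profile shape: positive ends, dip, negative mid."""
    x = _TEMPLATE_OFFSETS.astype(float)
    if anchor == "start":
        prof = (0.45 * np.exp(-x / 18.0)            # positive start
                - 0.75 * np.exp(-((x - 40) / 28.0) ** 2)  # transition peak
                - 0.5 / (1 + np.exp(-(x - 120) / 35.0)))  # negative mid plateau
    else:
        prof = (0.35 * np.exp(-x / 18.0)
                - 0.5 / (1 + np.exp(-(x - 120) / 40.0)))
    return prof


def simulate_profile_cohort(n_species: int = 60, seed: int = 0,
                            yule_rate: float = 1.0,
                            noise_sd: float = 0.04,
                            n_endosymbionts: int = 6):
    """Trait-linked cohort of ΔLFE profile vectors (no genomes).

    Emulates the association stage's inputs directly: each species gets
    Brownian-evolved GC and optimum temperature, clade-painted
    endosymbiosis, and a profile equal to the canonical shape scaled by
    an amplitude that the four weak-profile clauses suppress
    (endosymbionts ~0; low GC, high ENc' and hyperthermophily scaled
    down).  Returns (tree, traits dict, start matrix, end matrix).
    """
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_species, yule_rate, seed=seed)
    gc = simulate_traits_bm(tree, 50.0, 60.0, seed=seed + 1).clip(25, 75)
    temp = simulate_traits_bm(tree, 40.0, 150.0, seed=seed + 2).clip(4, 105)
    encp = simulate_traits_bm(tree, 50.0, 30.0, seed=seed + 3).clip(30, 61)
    endo = paint_clade_trait(tree, n_endosymbionts, seed=seed + 4)
    species = list(gc.index)
    traits = {}
    rows_start, rows_end = [], []
    for sp in species:
        t = SpeciesTraits(species_id=sp, gc_percent=float(gc[sp]),
                          enc_prime=float(encp[sp]),
                          opt_temp_c=float(temp[sp]),
                          endosymbiont=bool(endo[sp]))
        traits[sp] = t
        amp = 1.0
        if t.endosymbiont:
            amp *= 0.02
        if t.gc_percent < 38:
            amp *= 0.1
        if t.enc_prime > 56.5:
            amp *= 0.15
        if t.opt_temp_c > 58:
            amp *= 0.1
        amp *= rng.uniform(0.8, 1.2)
        rows_start.append(amp * _template_profile("start")
                          + rng.normal(0, noise_sd, len(_TEMPLATE_OFFSETS)))
        rows_end.append(amp * _template_profile("end")
                        + rng.normal(0, noise_sd, len(_TEMPLATE_OFFSETS)))
    mat_start = pd.DataFrame(rows_start, index=species,
                             columns=_TEMPLATE_OFFSETS)
    mat_end = pd.DataFrame(rows_end, index=species, columns=_TEMPLATE_OFFSETS)
    return tree, traits, mat_start, mat_end
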