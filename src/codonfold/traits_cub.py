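"""Species traits: genomic GC-content and codon-usage bias (ENc, ENc').

ENc is Wright's effective number of codons: 61 for perfectly uniform
synonymous usage, 20 when exactly one codon is used per amino acid.
ENc' is Novembre's composition-corrected variant, which replaces the
codon homozygosity with a chi-square deviation from the codon
frequencies *expected under the background nucleotide composition*, so
that bias attributable purely to GC-content does not register.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .randomization import synonymous_families
from .sequence_io import GenomeDataset

__all__ = ["SpeciesTraits", "gc_content", "enc", "enc_prime",
           "read_trait_table", "write_trait_table"]


@dataclass
class SpeciesTraits:
    species_id: str = ""
    gc_percent: float | None = None
    enc: float | None = None
    enc_prime: float | None = None
    opt_temp_c: float | None = None
    endosymbiont: bool | None = None
    taxon_path: list[str] = field(default_factory=list)
    growth_time_h: float | None = None
    genetic_code: int = 1


def gc_content(genome: GenomeDataset) -> float:
    """Percent G+C pooled over all kept CDSs (length-weighted)."""
    if not genome.cds_list:
        raise ValueError("empty genome")
    gc = total = 0
    for cds in genome.cds_list:
        gc += cds.seq.count("G") + cds.seq.count("C")
        total += len(cds.seq)
    return 100.0 * gc / total


def _pooled_codon_counts(genome: GenomeDataset) -> tuple[Counter, int]:
    counts: Counter = Counter()
    code = genome.cds_list[0].genetic_code
    for cds in genome.cds_list:
        counts.update(cds.codons)
    return counts, code


def _families(code: int) -> dict[str, list[str]]:
    fam_of = synonymous_families(code)
    fams: dict[str, list[str]] = defaultdict(list)
    for codon, aa in fam_of.items():
        if aa != "*":  # stop codons never enter ENc
            fams[aa].append(codon)
    return fams


def _nc_from_homozygosity(f_hat: dict[str, float], fams: dict[str, list[str]],
                          counts: Counter) -> float:
    # group families by degeneracy; average F within each class; the
    # generalized Wright sum is  sum_k  N_k / F_bar_k  (+ singletons)
    by_deg: dict[int, list[float]] = defaultdict(list)
    n_by_deg: Counter = Counter()
    for aa, codons in fams.items():
        m = len(codons)
        n_by_deg[m] += 1
        if m == 1:
            continue
        if aa in f_hat:
            by_deg[m].append(f_hat[aa])
    nc = float(n_by_deg[1])
    fbar = {m: np.mean(v) for m, v in by_deg.items() if v}
    # a degeneracy class with no estimable family borrows the mean of
    # the neighbouring classes (Wright's convention for 3-fold families)
    for m, n_fams in sorted(n_by_deg.items()):
        if m == 1:
            continue
        if m in fbar and fbar[m] > 0:
            nc += n_fams / fbar[m]
        else:
            neigh = [fbar[k] for k in (m - 1, m + 1) if k in fbar and fbar[k] > 0]
            if neigh:
                nc += n_fams / float(np.mean(neigh))
            else:
                nc += n_fams  # no information: count as unbiased singleton block
    total_sense = sum(len(c) for c in fams.values())
    return float(min(nc, min(61, total_sense)))


def enc(genome: GenomeDataset) -> float:
    """Wright's effective number of codons on pooled genome counts.

    F for each amino-acid family is the homozygosity estimator
    (n·Σp² − 1)/(n − 1); families observed fewer than 2 times are
    excluded from their degeneracy-class average.  Capped at 61.
    """
    counts, code = _pooled_codon_counts(genome)
    fams = _families(code)
    f_hat: dict[str, float] = {}
    for aa, codons in fams.items():
        if len(codons) < 2:
            continue
        n = sum(counts[c] for c in codons)
        if n < 2:
            continue
        p = np.array([counts[c] / n for c in codons])
        f = (n * float(np.sum(p ** 2)) - 1) / (n - 1)
        if f > 0:
            f_hat[aa] = f
    return _nc_from_homozygosity(f_hat, fams, counts)


def _background_codon_expectation(genome: GenomeDataset, codons: list[str],
                                  background: dict[str, float] | None
                                  ) -> np.ndarray:
    # expected relative frequencies within a family, from the pooled
    # mononucleotide composition of the CDS set (or a supplied one)
    if background is None:
        base_counts = Counter()
        for cds in genome.cds_list:
            base_counts.update(cds.seq)
        total = sum(base_counts[b] for b in "ACGT")
        background = {b: base_counts[b] / total for b in "ACGT"}
    e = np.array([background[c[0]] * background[c[1]] * background[c[2]]
                  for c in codons])
    return e / e.sum()


def enc_prime(genome: GenomeDataset,
              background: dict[str, float] | None = None) -> float:
    """Composition-corrected effective number of codons (ENc').

    Per family, the chi-square deviation of observed codon frequencies
    from the background-composition expectation replaces homozygosity:
    F' = (χ² + n − m) / (m·(n − 1)).  The background defaults to the
    nucleotide composition of the analysed CDS set itself; with a
    uniform background the statistic reduces exactly to Wright's F, so
    ENc' ≈ ENc on composition-balanced genomes.
    """
    counts, code = _pooled_codon_counts(genome)
    fams = _families(code)
    f_hat: dict[str, float] = {}
    for aa, codons in fams.items():
        m = len(codons)
        if m < 2:
            continue
        n = sum(counts[c] for c in codons)
        if n < 2:
            continue
        p = np.array([counts[c] / n for c in codons])
        e = _background_codon_expectation(genome, codons, background)
        chi2 = n * float(np.sum((p - e) ** 2 / e))
        f = (chi2 + n - m) / (m * (n - 1))
        if f > 0:
            f_hat[aa] = f
    return _nc_from_homozygosity(f_hat, fams, counts)


TRAIT_COLUMNS = ["species_id", "gc_percent", "enc_prime", "opt_temp_c",
                 "endosymbiont", "taxon_path", "genetic_code"]


def write_trait_table(traits: list[SpeciesTraits], path: str | Path) -> None:
    rows = []
    for t in traits:
        rows.append({
            "species_id": t.species_id,
            "gc_percent": t.gc_percent,
            "enc_prime": t.enc_prime,
            "opt_temp_c": t.opt_temp_c,
            "endosymbiont": ("NA" if t.endosymbiont is None
                             else int(t.endosymbiont)),
            "taxon_path": ";".join(t.taxon_path),
            "genetic_code": t.genetic_code,
        })
    pd.DataFrame(rows, columns=TRAIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_trait_table(path: str | Path) -> dict[str, SpeciesTraits]:
    df = pd.read_csv(path, sep="\t", dtype={"endosymbiont": str})
    out: dict[str, SpeciesTraits] = {}
    for _, row in df.iterrows():
        endo = row.get("endosymbiont")
        endo = (None if pd.isna(endo) or str(endo).upper() == "NA"
                else bool(int(float(endo))))
        taxon = row.get("taxon_path")
        taxon = [] if pd.isna(taxon) else str(taxon).split(";")
        def _num(key):
            v = row.get(key)
            return None if v is None or pd.isna(v) else float(v)
        out[row["species_id"]] = SpeciesTraits(
            species_id=row["species_id"],
            gc_percent=_num("gc_percent"),
            enc_prime=_num("enc_prime"),
            opt_temp_c=_num("opt_temp_c"),
            endosymbiont=endo,
            taxon_path=taxon,
            genetic_code=int(row.get("genetic_code", 1))
            if not pd.isna(row.get("genetic_code", 1)) else 1,
        )
    return out
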