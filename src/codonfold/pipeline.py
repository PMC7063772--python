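"""End-to-end orchestration: filter → null ensembles → fold → ΔLFE →
model rules, then the cross-species association stage.

Every stage's parameters are serialized into a run manifest so a rerun
with the same manifest is bit-identical for deterministic stages.  The
folding backend is wrapped in a content-addressed energy cache, since
randomized windows repeat (a warm cache changes nothing but runtime).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .dlfe import species_mean_dlfe
from .folding import BuiltinBackend, EnergyCache, RNAfoldBackend
from .model_rules import classify_model1, classify_model2
from .phylo_gls import (brownian_covariance, gls_fit, make_ultrametric, ols_fit,
                        prune_and_merge, range_robustness, taxon_scan)
from .profile_stats import (characteristic_profiles, pca_profiles,
                            profile_matrix, region_correlation,
                            weak_dlfe_classifier)
from .sequence_io import GenomeDataset, apply_cds_filters, read_fasta_cds, \
    write_rejection_report
from .traits_cub import SpeciesTraits, enc, enc_prime, gc_content, \
    read_trait_table, write_trait_table

log = logging.getLogger("codonfold")

__all__ = ["RunConfig", "run_profile", "run_association", "run_simulate"]


@dataclass
class RunConfig:
    cds_dir: str = "cds"
    traits_tsv: str = "traits.tsv"
    tree_newick: str | None = None
    out_dir: str = "results"
    null_model: str = "cds_wide"
    n_randomizations: int = 20
    seed: int = 0
    backend: str = "builtin"
    temperature_c: float = 37.0
    anchors: tuple[str, ...] = ("start", "end")
    max_span: int = 300
    min_cds_length: int = 150
    aggregate: str = "pooled"
    pin_first_codon: bool = False
    run_range_robustness: bool = False
    taxon_min_n: int = 9
    cluster_threshold_start: float = 0.8
    cluster_threshold_end: float = 1.3

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["anchors"] = list(self.anchors)
        d["version"] = __version__
        return d


def _make_backend(config: RunConfig):
    if config.backend == "builtin":
        base = BuiltinBackend(temperature=config.temperature_c)
    elif config.backend == "rnafold":
        base = RNAfoldBackend(temperature=config.temperature_c)
    else:
        raise ValueError(f"unknown backend {config.backend!r}")
    return EnergyCache(base)


def load_genomes(config: RunConfig) -> list[GenomeDataset]:
    traits = (read_trait_table(config.traits_tsv)
              if Path(config.traits_tsv).exists() else {})
    genomes = []
    for fasta in sorted(Path(config.cds_dir).glob("*.fasta")):
        sp = fasta.stem
        t = traits.get(sp)
        if t is None:
            log.warning("species %s missing from trait table", sp)
            t = SpeciesTraits(species_id=sp)
        cds = read_fasta_cds(fasta, genetic_code=t.genetic_code)
        kept, rejected = apply_cds_filters(cds, min_len=config.min_cds_length)
        out = Path(config.out_dir) / "rejections"
        out.mkdir(parents=True, exist_ok=True)
        write_rejection_report(rejected, out / f"{sp}.tsv")
        if not kept:
            log.warning("species %s: no CDS passed filtering; skipped", sp)
            continue
        genomes.append(GenomeDataset(sp, kept, t))
    return genomes


def _classification_record(cls) -> dict:
    return {"model": cls.model, "peak_position": cls.peak_position,
            **{k: bool(v) for k, v in cls.elements.items()}}


def run_profile(config: RunConfig) -> dict:
    """Profile stage: per-species ΔLFE TSVs + model classifications.

    Returns {species_id: {anchor: DLFEResult}, ...} keyed structures
    for in-process use; files land under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "profiles").mkdir(exist_ok=True)
    backend = _make_backend(config)
    genomes = load_genomes(config)
    if not genomes:
        raise FileNotFoundError(f"no usable species FASTAs in {config.cds_dir}")
    results: dict[str, dict] = {}
    class_rows = []
    for genome in genomes:
        per_anchor = {}
        frames = []
        for anchor in config.anchors:
            res = species_mean_dlfe(
                genome, null_model=config.null_model,
                n_randomizations=config.n_randomizations, anchor=anchor,
                seed=config.seed, backend=backend, max_span=config.max_span,
                aggregate=config.aggregate,
                pin_first_codon=config.pin_first_codon)
            per_anchor[anchor] = res
            frames.append(res.to_frame())
        pd.concat(frames).to_csv(out / "profiles" / f"{genome.species_id}.tsv",
                                 sep="\t", index=False, float_format="%.10g")
        results[genome.species_id] = per_anchor
        if "start" in per_anchor and "end" in per_anchor:
            row = {"species_id": genome.species_id}
            try:
                m1 = classify_model1(per_anchor["start"], per_anchor["end"])
                m2 = classify_model2(per_anchor["start"], per_anchor["end"])
                for m in (m1, m2):
                    rec = _classification_record(m)
                    row.update({f"{m.model}_{k}": v for k, v in rec.items()
                                if k != "model"})
            except ValueError as exc:
                row["error"] = str(exc)
            class_rows.append(row)
    if class_rows:
        pd.DataFrame(class_rows).to_csv(out / "model_classifications.tsv",
                                        sep="\t", index=False)
    for anchor in config.anchors:
        mat = profile_matrix([results[s][anchor] for s in results],
                             max_span=config.max_span)
        mat.to_csv(out / f"dlfe_matrix_{anchor}.tsv", sep="\t",
                   float_format="%.10g")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"stage": "profile", **config.manifest()}, fh, indent=2,
                  sort_keys=True)
    return results


TRAIT_PREDICTORS = ("gc_percent", "enc_prime", "opt_temp_c")


def run_association(config: RunConfig) -> dict:
    """Association stage: GLS/OLS tables, scans, PCA, clusters, classifier."""
    out = Path(config.out_dir)
    matrices = {}
    for anchor in config.anchors:
        path = out / f"dlfe_matrix_{anchor}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"{path} (run the profile stage first)")
        mat = pd.read_csv(path, sep="\t", index_col=0)
        mat.columns = mat.columns.astype(int)
        matrices[anchor] = mat
    mat_start = matrices["start"]
    traits = read_trait_table(config.traits_tsv)

    reports: dict = {}
    trait_df = pd.DataFrame({
        sp: {"gc_percent": t.gc_percent, "enc_prime": t.enc_prime,
             "opt_temp_c": t.opt_temp_c,
             "endosymbiont": (np.nan if t.endosymbiont is None
                              else float(t.endosymbiont))}
        for sp, t in traits.items()}).T

    if config.tree_newick:
        tree = dendropy.Tree.get(path=config.tree_newick, schema="newick")
        tips = {l.taxon.label for l in tree.leaf_node_iter()}
        common = sorted(set(mat_start.index) & tips)
        missing = sorted(set(mat_start.index) - tips)
        if missing:
            log.warning("%d species absent from tree: %s", len(missing), missing)
        tree = make_ultrametric(prune_and_merge(tree, set(common)))
        cov = brownian_covariance(tree)
        region_cols = [c for c in mat_start.columns if 100 <= c <= 300]
        region_mean = mat_start[region_cols].mean(axis=1)
        rows = []
        for name in TRAIT_PREDICTORS + ("endosymbiont",):
            tr = trait_df[name] if name in trait_df else pd.Series(dtype=float)
            ids = [s for s in common if s in tr.index and pd.notna(tr[s])
                   and pd.notna(region_mean.get(s))]
            if len(ids) < 3 or tr.loc[ids].nunique() < 2:
                continue
            discrete = name == "endosymbiont"
            y = region_mean.loc[ids].to_numpy()
            x = tr.loc[ids].to_numpy()
            g = gls_fit(y, x, cov.subset(ids), discrete=discrete)
            o = ols_fit(y, x, discrete=discrete)
            rows.append({"trait": name, "n": g.n,
                         "gls_slope": g.slope, "gls_r2": g.r2,
                         "gls_p": g.p_value, "ols_slope": o.slope,
                         "ols_r2": o.r2, "ols_p": o.p_value})
        gls_table = pd.DataFrame(rows)
        gls_table.to_csv(out / "gls_regressions.tsv", sep="\t", index=False,
                         float_format="%.10g")
        reports["gls"] = gls_table
        if config.run_range_robustness and "gc_percent" in trait_df:
            rr = range_robustness(mat_start, trait_df["gc_percent"], cov)
            rr.to_csv(out / "range_robustness.tsv", sep="\t", index=False,
                      float_format="%.10g")
            reports["range_robustness"] = rr
        taxon_paths = {sp: t.taxon_path for sp, t in traits.items()
                       if t.taxon_path}
        if taxon_paths and "gc_percent" in trait_df:
            scan = taxon_scan(mat_start, trait_df["gc_percent"], cov,
                              taxon_paths, min_n=config.taxon_min_n)
            scan.to_csv(out / "taxon_scan.tsv", sep="\t", index=False,
                        float_format="%.10g")
            reports["taxon_scan"] = scan

    corr = region_correlation(mat_start, end_matrix=matrices.get("end"))
    corr.to_csv(out / "region_correlations.tsv", sep="\t", index=False,
                float_format="%.10g")
    reports["region_correlations"] = corr

    if len(mat_start) >= 3:
        pca = pca_profiles(mat_start.dropna(axis=1), bootstrap=0)
        pca.coordinates.to_csv(out / "pca_coordinates.tsv", sep="\t",
                               float_format="%.10g")
        reports["pca"] = pca

    for anchor, threshold in (("start", config.cluster_threshold_start),
                              ("end", config.cluster_threshold_end)):
        if anchor in matrices:
            cen, members = characteristic_profiles(
                matrices[anchor].dropna(axis=1), dist_threshold=threshold)
            members.rename("cluster").to_csv(
                out / f"cluster_membership_{anchor}.tsv", sep="\t")
            reports[f"clusters_{anchor}"] = (cen, members)

    clf = weak_dlfe_classifier(mat_start, traits)
    with open(out / "classifier_report.json", "w") as fh:
        json.dump({"precision": clf.precision, "recall": clf.recall,
                   "n_weak_observed": int(clf.table.observed_weak.sum()),
                   "n_weak_predicted": int(clf.table.predicted_weak.sum()),
                   "n_species": int(len(clf.table))}, fh, indent=2,
                  sort_keys=True)
    reports["classifier"] = clf
    with open(out / "manifest_association.json", "w") as fh:
        json.dump({"stage": "association", **config.manifest()}, fh, indent=2,
                  sort_keys=True)
    return reports


def run_simulate(out_dir: str, n_species: int = 5, n_cds: int = 50,
                 cds_length: int = 300, seed: int = 0,
                 bias_spec=None) -> None:
    """Write a synthetic cohort in the pipeline's input layout."""
    from .synthetic_data import (SimulationConfig, generate_genome,
                                 inject_folding_bias, simulate_traits_bm,
                                 simulate_tree)
    out = Path(out_dir)
    (out / "cds").mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(n_species, seed=seed)
    tree.write(path=str(out / "tree.nwk"), schema="newick")
    gc_trait = simulate_traits_bm(tree, 50.0, 40.0, seed=seed + 1).clip(25, 75)
    traits = []
    truth = {}
    for i, sp in enumerate(gc_trait.index):
        cfg = SimulationConfig(n_species=1, n_cds=n_cds, cds_length=cds_length,
                               target_gc=float(gc_trait[sp]) / 100, seed=seed)
        genome = generate_genome(cfg, sp, seed=seed * 1000 + i)
        if bias_spec:
            genome = inject_folding_bias(genome, bias_spec, seed=seed * 1000 + i)
            truth[sp] = [dataclasses.asdict(b) for b in bias_spec]
        else:
            truth[sp] = []
        with open(out / "cds" / f"{sp}.fasta", "w") as fh:
            for cds in genome.cds_list:
                fh.write(f">{cds.id}\n{cds.seq}\n")
        traits.append(SpeciesTraits(
            species_id=sp, gc_percent=gc_content(genome), enc=enc(genome),
            enc_prime=enc_prime(genome), opt_temp_c=37.0, endosymbiont=False,
            taxon_path=["SyntheticRoot", f"Clade{(i % 2) + 1}"]))
    write_trait_table(traits, out / "traits.tsv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
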