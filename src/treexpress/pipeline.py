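"""End-to-end orchestration: regions → trees → expression → association.

Two entry points:

* :func:`run_association_study` — the statistical core, from normalized
  gene × pair tables and a normalized expression table to the Bonferroni-
  corrected region × tissue results.
* :func:`run_full_analysis` — the file pipeline: genomes (FASTA) +
  annotations (GTF) + expression (TSV) + global tree (Newick/TSV) in,
  results bundle out, with a manifest recording parameters, input
  checksums and per-stage gene accounting.

:func:`run_simulated_study` wires the synthetic generator straight into
the statistical core without the file round-trip; the calibration
experiments and the acceptance script use it.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .species import SpeciesSet
from .trees import PairDistanceVector
from . import regions as regions_mod
from .regions import (GenomeStore, build_region_sets, filter_undefined,
                      parse_annotations, summarize_region_lengths,
                      REGION_TYPES)
from .genomic_trees import (build_tree_table, load_global_tree,
                            normalize_by_global, DropRecord)
from .expression import (ExpressionTable, quantile_normalize,
                         tissue_enriched_genes, expression_tree_table,
                         tissue_divergence, EnrichedGeneSet)
from .association import (AssociationResult, CorrelationSample, Density,
                          NullDistribution, bonferroni, bootstrap_null,
                          compare_distributions, correlation_distribution,
                          rank_signature_genes, results_table)

#: The default 48-cell family: three promoter windows plus the three
#: transcript regions, crossed with the tissues passing the size filter.
DEFAULT_ANALYSIS_REGIONS = (
    "promoter_w1", "promoter_w2", "promoter_w3", "utr5", "cds", "utr3",
)


@dataclass
class StudyParams:
    """Analysis parameters; defaults are the published values."""

    fold_threshold: float = 5.0
    size_threshold: int = 100
    iterations: int = 1000
    bins: int = 40
    seed: int = 0
    saturation: str = "drop"
    saturation_cap: float = 5.0
    regions: Tuple[str, ...] = DEFAULT_ANALYSIS_REGIONS
    family_size: Optional[int] = None
    promoter_length: int = 1500
    window_length: int = 500
    keep_null_values: bool = False


@dataclass
class StudyResult:
    table: pd.DataFrame
    results: List[AssociationResult]
    samples: Dict[Tuple[str, str], CorrelationSample]
    nulls: Dict[str, NullDistribution]
    enriched: Dict[str, EnrichedGeneSet]
    family_size: int

    def significant(self, alpha: float = 0.05, test: str = "ks"
                    ) -> List[Tuple[str, str]]:
        col = "ks_p_bonf" if test == "ks" else "kw_p_bonf"
        hits = self.table[self.table[col] < alpha]
        return list(zip(hits["region"], hits["tissue"]))


def run_association_study(
    genomic_tables: Mapping[str, pd.DataFrame],
    expr: ExpressionTable,
    species_set: SpeciesSet,
    params: Optional[StudyParams] = None,
) -> StudyResult:
    """Correlate genomic vs expression trees per region × tissue cell.

    ``genomic_tables`` maps region → gene × pair table of (normalized)
    JC distances; ``expr`` must be quantile-normalized.  Only tissues
    with strictly more than ``size_threshold`` enriched genes enter the
    analysis.  Genes dropped for zero variance are excluded from both
    observed and permuted computations, keeping sample sizes matched.
    """
    params = params or StudyParams()
    if not expr.normalized:
        raise ValueError("expression table must be quantile-normalized")

    enriched: Dict[str, EnrichedGeneSet] = {}
    for tissue in expr.tissues:
        enriched[tissue] = tissue_enriched_genes(
            expr, tissue, params.fold_threshold, params.size_threshold
        )
    passing = [t for t in expr.tissues if enriched[t].passed_size_filter]

    results: List[AssociationResult] = []
    samples: Dict[Tuple[str, str], CorrelationSample] = {}
    nulls: Dict[str, NullDistribution] = {}
    study_regions = [r for r in params.regions if r in genomic_tables]
    for r_idx, region in enumerate(study_regions):
        gtable = genomic_tables[region]
        cells: Dict[str, Tuple[pd.DataFrame, pd.DataFrame]] = {}
        region_samples: Dict[str, CorrelationSample] = {}
        for tissue in passing:
            genes = sorted(enriched[tissue].genes & set(gtable.index))
            etable = expression_tree_table(expr, genes, tissue, species_set)
            sample, _dens = correlation_distribution(
                region, tissue, genes, gtable, etable, params.bins
            )
            region_samples[tissue] = sample
            cells[tissue] = (gtable.loc[sample.genes],
                             etable.loc[sample.genes])
        null = bootstrap_null(
            region, cells, params.iterations, params.seed, params.bins,
            region_idx=r_idx, tissue_order=passing,
        )
        for tissue in passing:
            res = compare_distributions(region_samples[tissue], null)
            results.append(res)
            samples[(region, tissue)] = region_samples[tissue]
        if not params.keep_null_values:
            null = NullDistribution(null.region, np.empty(0), null.density,
                                    null.iterations, null.seed,
                                    null.n_per_tissue)
        nulls[region] = null

    family = params.family_size if params.family_size is not None else len(results)
    bonferroni(results, family)
    return StudyResult(results_table(results), results, samples, nulls,
                       enriched, family)


# ---------------------------------------------------------------------------
# simulation-backed study (no file round-trip)


def run_simulated_study(config, params: Optional[StudyParams] = None):
    """Generate a synthetic world and run the full analysis in memory.

    Returns (StudyResult, ground_truth, context) where context carries
    the simulation, the normalized trees and the normalized expression
    table for further inspection.
    """
    from .simulate import simulate_regions, simulate_expression

    params = params or StudyParams(seed=getattr(config, "seed", 0))
    sim = simulate_regions(config)
    region_sets = sim.region_sets(params.regions)
    global_tree = sim.global_tree()
    tables: Dict[str, pd.DataFrame] = {}
    drops: Dict[str, List[DropRecord]] = {}
    counts: Dict[str, Dict[str, int]] = {}
    for region, sets in region_sets.items():
        kept = filter_undefined(sets, sim.species_set)
        table, dropped = build_tree_table(
            kept, sim.species_set, params.saturation, params.saturation_cap
        )
        tables[region] = normalize_by_global(table, global_tree)
        drops[region] = dropped
        counts[region] = {"extracted": len(sets), "after_n_filter": len(kept),
                          "with_tree": len(table)}
    raw_expr, ground_truth = simulate_expression(config, sim)
    expr = quantile_normalize(raw_expr)
    study = run_association_study(tables, expr, sim.species_set, params)
    context = {"sim": sim, "genomic_tables": tables, "expression": expr,
               "drops": drops, "counts": counts}
    return study, ground_truth, context


# ---------------------------------------------------------------------------
# file pipeline


@dataclass
class RunConfig:
    """Paths and parameters for a file-based run."""

    species: Tuple[str, ...]
    genomes: Dict[str, str]
    annotations: Dict[str, str]
    expression: str
    global_tree: str
    out: str
    orthologs: Optional[str] = None
    annotation_format: str = "gtf"
    extract_regions: Tuple[str, ...] = REGION_TYPES
    params: StudyParams = field(default_factory=StudyParams)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = StudyParams(**raw.get("params", {}))
        inputs = raw["inputs"]
        return cls(
            species=tuple(raw["species"]),
            genomes=dict(inputs["genomes"]),
            annotations=dict(inputs["annotations"]),
            expression=inputs["expression"],
            global_tree=inputs["global_tree"],
            orthologs=inputs.get("orthologs"),
            annotation_format=inputs.get("annotation_format", "gtf"),
            extract_regions=tuple(raw.get("extract_regions", REGION_TYPES)),
            out=raw["out"],
            params=params,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _apply_orthologs(genes: Dict[str, "regions_mod.GeneModel"],
                     mapping: Mapping[str, str]) -> Dict[str, object]:
    return {mapping[gid]: g for gid, g in genes.items() if gid in mapping}


def run_full_analysis(config: RunConfig) -> StudyResult:
    """Execute the whole pipeline from files and write the results bundle."""
    params = config.params
    species_set = SpeciesSet(tuple(config.species))
    for sp in species_set.labels:
        if sp not in config.genomes or sp not in config.annotations:
            raise ValueError(f"species {sp!r} missing a genome or annotation")
    os.makedirs(config.out, exist_ok=True)
    cache_dir = os.path.join(config.out, "cache")
    os.makedirs(cache_dir, exist_ok=True)

    checksums = {
        "expression": _sha256(config.expression),
        "global_tree": _sha256(config.global_tree),
        **{f"genome:{sp}": _sha256(config.genomes[sp]) for sp in species_set.labels},
        **{f"annotation:{sp}": _sha256(config.annotations[sp])
           for sp in species_set.labels},
    }
    if config.orthologs:
        checksums["orthologs"] = _sha256(config.orthologs)

    # ---- stage 1+2: regions and genomic trees (content-addressed cache)
    tree_key = hashlib.sha256(json.dumps({
        "checksums": checksums, "regions": config.extract_regions,
        "promoter": params.promoter_length, "window": params.window_length,
        "saturation": [params.saturation, params.saturation_cap],
        "fmt": config.annotation_format,
    }, sort_keys=True).encode()).hexdigest()[:16]

    tables: Dict[str, pd.DataFrame] = {}
    counts: Dict[str, Dict[str, int]] = {}
    lengths_path = os.path.join(config.out, "region_lengths.tsv")
    cached = all(
        os.path.exists(os.path.join(cache_dir, f"trees_{tree_key}_{r}.tsv"))
        for r in config.extract_regions
    ) and os.path.exists(os.path.join(cache_dir, f"counts_{tree_key}.json"))
    if cached:
        for region in config.extract_regions:
            tables[region] = pd.read_csv(
                os.path.join(cache_dir, f"trees_{tree_key}_{region}.tsv"),
                sep="\t", index_col=0, float_precision="round_trip",
            )
        with open(os.path.join(cache_dir, f"counts_{tree_key}.json")) as fh:
            counts = json.load(fh)
    else:
        ortho_map: Optional[Dict[str, Dict[str, str]]] = None
        if config.orthologs:
            odf = pd.read_csv(config.orthologs, sep="\t", index_col=0)
            ortho_map = {
                sp: {str(v): str(g) for g, v in odf[sp].items()}
                for sp in species_set.labels
            }
        genes_by_species = {}
        for sp in species_set.labels:
            models = parse_annotations(config.annotations[sp], sp,
                                       config.annotation_format)
            gmap = {g.gene_id: g for g in models}
            if ortho_map is not None:
                gmap = _apply_orthologs(gmap, ortho_map[sp])
            genes_by_species[sp] = gmap
        genomes = {sp: GenomeStore(config.genomes[sp])
                   for sp in species_set.labels}
        region_sets = build_region_sets(
            genes_by_species, genomes, species_set, config.extract_regions,
            params.promoter_length, params.window_length,
        )
        all_sets = [rs for sets in region_sets.values() for rs in sets]
        summarize_region_lengths(all_sets).to_csv(lengths_path, sep="\t",
                                                  index=False)
        global_tree = load_global_tree(config.global_tree, species_set)
        for region, sets in region_sets.items():
            kept = filter_undefined(sets, species_set)
            table, dropped = build_tree_table(
                kept, species_set, params.saturation, params.saturation_cap
            )
            tables[region] = normalize_by_global(table, global_tree)
            counts[region] = {
                "extracted": len(sets),
                "after_n_filter": len(kept),
                "with_tree": len(table),
                "dropped_saturation_or_empty": len(dropped),
            }
            tables[region].to_csv(
                os.path.join(cache_dir, f"trees_{tree_key}_{region}.tsv"),
                sep="\t",
            )
        with open(os.path.join(cache_dir, f"counts_{tree_key}.json"), "w") as fh:
            json.dump(counts, fh, sort_keys=True, indent=1)

    # ---- stage 3: expression
    raw = ExpressionTable.read_tsv(config.expression)
    missing = set(species_set.labels) - set(raw.species)
    if missing:
        raise ValueError(f"expression table missing species {sorted(missing)}")
    expr = quantile_normalize(raw)
    divergence = pd.DataFrame(
        {t: tissue_divergence(expr, t, species_set).values
         for t in expr.tissues},
        index=list(species_set.pair_labels),
    )
    divergence.to_csv(os.path.join(config.out, "tissue_divergence.tsv"),
                      sep="\t", index_label="pair")

    # ---- stage 4: association
    study = run_association_study(tables, expr, species_set, params)
    _write_bundle(study, config, counts, checksums)
    return study


def _write_bundle(study: StudyResult, config: RunConfig,
                  counts: Mapping[str, Mapping[str, int]],
                  checksums: Mapping[str, str]) -> None:
    out = config.out
    study.table.to_csv(os.path.join(out, "association_results.tsv"),
                       sep="\t", index=False)
    cells_dir = os.path.join(out, "cells")
    os.makedirs(cells_dir, exist_ok=True)
    for (region, tissue), sample in study.samples.items():
        pd.DataFrame({"gene_id": sample.genes, "r": sample.values}).to_csv(
            os.path.join(cells_dir, f"{region}__{tissue}.tsv"),
            sep="\t", index=False,
        )
        rank_signature_genes(sample, 50).to_csv(
            os.path.join(cells_dir, f"{region}__{tissue}.top50.tsv"),
            sep="\t", index=False,
        )
    dens_rows = []
    for region, null in study.nulls.items():
        mids = 0.5 * (null.density.edges[:-1] + null.density.edges[1:])
        for m, d in zip(mids, null.density.density):
            dens_rows.append((region, m, d))
    pd.DataFrame(dens_rows, columns=["region", "bin_mid", "null_density"]) \
        .to_csv(os.path.join(out, "null_densities.tsv"), sep="\t", index=False)
    enriched_rows = [
        (t, len(s.genes), s.passed_size_filter)
        for t, s in study.enriched.items()
    ]
    pd.DataFrame(enriched_rows,
                 columns=["tissue", "n_enriched", "passed_size_filter"]) \
        .to_csv(os.path.join(out, "enriched_sets.tsv"), sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": config.params.seed,
        "params": asdict(config.params),
        "input_checksums": dict(checksums),
        "per_region_counts": {k: dict(v) for k, v in counts.items()},
        "family_size": study.family_size,
        "n_cells": len(study.results),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
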