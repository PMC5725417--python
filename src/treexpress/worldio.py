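"""Write a synthetic world to disk in the real pipeline's input formats.

Produces, per species, a genome FASTA and an Ensembl-dialect GTF in
which the simulated region sequences are embedded at known coordinates
(upstream → promoter → 5'UTR → CDS → 3'UTR, with random spacers and
introns), plus the expression TSV, the global normalizing tree
(Newick) and a ground-truth manifest.  A share of genes sits on the
minus strand, some genes carry a two-exon CDS, and some carry a second
identical transcript variant, so the extraction stage is exercised on
the layouts it must handle.  Byte-identical for equal seeds.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Tuple

import numpy as np

from .regions import reverse_complement
from .simulate import (SimulatedRegions, SyntheticConfig, matrix_row_to_seq,
                       simulate_expression, simulate_regions)

_SPACER = 700
_INTRON = 120
_ALPH = "ACGT"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPH[i] for i in rng.integers(0, 4, n))


def _gene_sequences(sim: SimulatedRegions, sp: str, i: int) -> Dict[str, str]:
    out = {}
    for region in ("upstream_far", "promoter_w1", "promoter_w2",
                   "promoter_w3", "utr5", "cds", "utr3"):
        out[region] = matrix_row_to_seq(
            sim.sequences[region][sp][i], int(sim.lengths[region][sp][i])
        )
    return out


def write_world(config: SyntheticConfig, outdir: str) -> Dict[str, object]:
    """Simulate and write a complete input bundle; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    sim = simulate_regions(config)
    expr, ground_truth = simulate_expression(config, sim)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(4,))
    )

    paths: Dict[str, object] = {"genomes": {}, "annotations": {}}
    n = len(sim.gene_ids)
    strands = ["-" if i % 7 == 3 else "+" for i in range(n)]
    split_cds = [i % 3 == 0 for i in range(n)]
    two_tx = [i % 5 == 0 for i in range(n)]
    introns = [_random_seq(rng, _INTRON) if split_cds[i] else "" for i in range(n)]
    spacers = [_random_seq(rng, _SPACER) for _ in range(n + 1)]

    for sp in sim.species_set.labels:
        chrom_parts: List[str] = []
        gtf_lines: List[str] = []
        offset = 0
        for i, gid in enumerate(sim.gene_ids):
            chrom_parts.append(spacers[i])
            offset += len(spacers[i])
            seqs = _gene_sequences(sim, sp, i)
            pieces = [seqs["upstream_far"], seqs["promoter_w1"],
                      seqs["promoter_w2"], seqs["promoter_w3"], seqs["utr5"]]
            tss_rel = sum(len(p) for p in pieces[:4])
            utr5_len = len(seqs["utr5"])
            cds_seq = seqs["cds"]
            cds_rel: List[Tuple[int, int]] = []
            pos = tss_rel + utr5_len
            if split_cds[i]:
                half = len(cds_seq) // 2
                pieces.append(cds_seq[:half])
                cds_rel.append((pos, pos + half))
                pieces.append(introns[i])
                pos += half + _INTRON
                pieces.append(cds_seq[half:])
                cds_rel.append((pos, pos + len(cds_seq) - half))
                pos += len(cds_seq) - half
            else:
                pieces.append(cds_seq)
                cds_rel.append((pos, pos + len(cds_seq)))
                pos += len(cds_seq)
            pieces.append(seqs["utr3"])
            end_rel = pos + len(seqs["utr3"])
            S = "".join(pieces)
            assert len(S) == end_rel

            if split_cds[i]:
                exon_rel = [(tss_rel, cds_rel[0][1]), (cds_rel[1][0], end_rel)]
            else:
                exon_rel = [(tss_rel, end_rel)]

            strand = strands[i]
            if strand == "+":
                chrom_parts.append(S)
                to_genomic = lambda a, b, o=offset: (o + a, o + b)
            else:
                chrom_parts.append(reverse_complement(S))
                to_genomic = lambda a, b, o=offset, L=len(S): (o + L - b, o + L - a)

            tx_span = to_genomic(tss_rel, end_rel)
            feats: List[Tuple[str, int, int, str]] = []
            n_tx = 2 if two_tx[i] else 1
            feats.append(("gene", tx_span[0], tx_span[1],
                          f'gene_id "{gid}";'))
            for k in range(1, n_tx + 1):
                tid = f"{gid}.t{k}"
                attr = f'gene_id "{gid}"; transcript_id "{tid}";'
                feats.append(("transcript", tx_span[0], tx_span[1], attr))
                for a, b in exon_rel:
                    ga, gb = to_genomic(a, b)
                    feats.append(("exon", ga, gb, attr))
                for a, b in cds_rel:
                    ga, gb = to_genomic(a, b)
                    feats.append(("CDS", ga, gb, attr))
            for ftype, ga, gb, attr in feats:
                gtf_lines.append(
                    f"chr1\tsynthetic\t{ftype}\t{ga + 1}\t{gb}\t.\t{strand}\t.\t{attr}"
                )
            offset += len(S)
        chrom_parts.append(spacers[n])
        chrom = "".join(chrom_parts)

        fasta_path = os.path.join(outdir, f"{sp}.fa")
        with open(fasta_path, "w") as fh:
            fh.write(">chr1\n")
            for j in range(0, len(chrom), 60):
                fh.write(chrom[j:j + 60] + "\n")
        gtf_path = os.path.join(outdir, f"{sp}.gtf")
        with open(gtf_path, "w") as fh:
            fh.write("\n".join(gtf_lines) + "\n")
        paths["genomes"][sp] = fasta_path
        paths["annotations"][sp] = gtf_path

    expr_path = os.path.join(outdir, "expression.tsv")
    expr.write_tsv(expr_path)
    tree_path = os.path.join(outdir, "global_tree.nwk")
    with open(tree_path, "w") as fh:
        fh.write(config.species_tree.strip() + "\n")
    truth_path = os.path.join(outdir, "ground_truth.json")
    with open(truth_path, "w") as fh:
        json.dump(ground_truth, fh, sort_keys=True, indent=1)

    paths.update(expression=expr_path, global_tree=tree_path,
                 ground_truth=truth_path, species=list(sim.species_set.labels))
    return paths
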