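"""Functional genomic region definitions and extraction.

Per gene, the analysis considers eight region types anchored on the
gene's transcription geometry:

* ``promoter_full`` — 1500 bp immediately 5' of the TSS,
* ``promoter_w1`` / ``promoter_w2`` / ``promoter_w3`` — the three
  consecutive 500 bp windows of the promoter, w1 being the farthest
  from the TSS (−1500..−1000) and w3 abutting it (−500..0),
* ``upstream_far`` — the 1500 bp upstream of the promoter (−3000..−1500),
  a negative-control region,
* ``utr5`` — the region between TSS and translation start,
* ``cds`` — the union of coding (CDS) intervals,
* ``utr3`` — the region between translation end and transcription end.

All coordinates are handled 0-based half-open internally (GTF input is
converted on read).  Regions are defined in transcription direction:
"upstream" means 5' of the TSS on the coding strand, and minus-strand
sequences are reverse-complemented so every output reads 5'→3'.
Regions of the same type from multiple transcript variants are unified
(interval union); discontiguous fragments are concatenated in
transcription order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .species import SpeciesSet

REGION_TYPES = (
    "upstream_far",
    "promoter_full",
    "promoter_w1",
    "promoter_w2",
    "promoter_w3",
    "utr5",
    "cds",
    "utr3",
)

PROMOTER_LENGTH = 1500
WINDOW_LENGTH = 500
UPSTREAM_FAR_SPAN = (3000, 1500)  # distances from TSS: [−3000, −1500)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AnnotationParseError(ValueError):
    """A malformed annotation record; the message names the line."""


class EmptyRegionError(ValueError):
    """Requested a transcript-derived region of a gene with no coding
    transcript."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# gene models


@dataclass
class Transcript:
    transcript_id: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for a, b in self.exons:
            if b <= a:
                raise ValueError(
                    f"degenerate exon interval ({a}, {b}) in {self.transcript_id}"
                )

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    """One gene on one species' genome, with all transcript variants."""

    gene_id: str
    species: str
    chrom: str
    strand: str
    transcripts: List[Transcript]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def tss(self) -> int:
        """Transcription start as a half-open boundary coordinate.

        On '+' this is the leftmost transcript start; on '−' it is the
        rightmost transcript end (the first transcribed base is the one
        immediately left of it).
        """
        return self.start if self.strand == "+" else self.end

    @property
    def coding_transcripts(self) -> List[Transcript]:
        return [t for t in self.transcripts if t.coding]


# ---------------------------------------------------------------------------
# genome access


class GenomeStore:
    """Uniform fetch interface over a FASTA file or an in-memory dict.

    Sequences are uppercased on fetch; out-of-bounds requests are
    clipped to the chromosome (callers detect truncation by length).
    """

    def __init__(self, source) -> None:
        if isinstance(source, (str, os.PathLike)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source), as_raw=True,
                                        sequence_always_upper=True)
            self._dict = None
        elif isinstance(source, Mapping):
            self._fasta = None
            self._dict = {k: v.upper() for k, v in source.items()}
        else:
            raise TypeError("GenomeStore wants a FASTA path or a dict")

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(0, start)
        end = min(self.length(chrom), end)
        if end <= start:
            return ""
        if self._dict is not None:
            return self._dict[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()


# ---------------------------------------------------------------------------
# annotation parsing


def _validate_gtf_lines(lines: Iterable[str]) -> None:
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.rstrip("\n").split("\t")) < 9:
            raise AnnotationParseError(
                f"malformed GTF record at line {i}: expected 9 tab-separated "
                f"fields, got {len(line.split(chr(9)))}"
            )


def parse_annotations(source, species: str, fmt: str = "gtf") -> List[GeneModel]:
    """Parse a GTF (Ensembl dialect) or BED12 stream into gene models.

    Every transcript variant is retained.  Transcripts without a CDS are
    kept but flagged non-coding (``Transcript.coding`` False) and are
    excluded from utr5/cds/utr3 derivation downstream.
    """
    if fmt == "gtf":
        return _parse_gtf(source, species)
    if fmt == "bed12":
        return _parse_bed12(source, species)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if not text or "\n" in text or "\t" in text:
        return text
    with open(text) as fh:
        return fh.read()


def _parse_gtf(source, species: str) -> List[GeneModel]:
    import gffutils

    text = _read_text(source)
    lines = text.splitlines(keepends=True)
    _validate_gtf_lines(lines)
    if not any(l.strip() and not l.startswith("#") for l in lines):
        return []
    try:
        db = gffutils.create_db(
            text,
            ":memory:",
            from_string=True,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils internal errors
        raise AnnotationParseError(f"failed to parse GTF: {exc}") from exc

    genes: List[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        transcripts: List[Transcript] = []
        for t in db.children(g, featuretype=("transcript", "mRNA"),
                             order_by="start"):
            exons = [(f.start - 1, f.end)
                     for f in db.children(t, featuretype="exon",
                                          order_by="start")]
            cds = [(f.start - 1, f.end)
                   for f in db.children(t, featuretype="CDS",
                                        order_by="start")]
            if not exons:
                exons = [(t.start - 1, t.end)]
            transcripts.append(Transcript(t.id, exons, cds))
        if not transcripts:
            continue
        genes.append(GeneModel(g.id, species, g.seqid, g.strand, transcripts))
    return genes


def _parse_bed12(source, species: str) -> List[GeneModel]:
    text = _read_text(source)
    by_gene: Dict[Tuple[str, str, str], List[Transcript]] = {}
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise AnnotationParseError(
                f"malformed BED12 record at line {i}: expected 12 fields"
            )
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        strand = fields[5]
        thick_start, thick_end = int(fields[6]), int(fields[7])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        cds: List[Tuple[int, int]] = []
        if thick_end > thick_start:
            for a, b in exons:
                lo, hi = max(a, thick_start), min(b, thick_end)
                if hi > lo:
                    cds.append((lo, hi))
        gene_id = name.split(".")[0]
        by_gene.setdefault((gene_id, chrom, strand), []).append(
            Transcript(name, exons, cds)
        )
    return [
        GeneModel(gene_id, species, chrom, strand, txs)
        for (gene_id, chrom, strand), txs in by_gene.items()
    ]


# ---------------------------------------------------------------------------
# region extraction


@dataclass
class RegionExtract:
    sequence: str
    truncated: bool = False


def _union_intervals(ivs: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for a, b in sorted(iv for iv in ivs if iv[1] > iv[0]):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _fetch_fragments(gene: GeneModel, genome: GenomeStore,
                     ivs: Sequence[Tuple[int, int]]) -> Tuple[str, bool]:
    """Fetch merged intervals and concatenate in transcription order."""
    merged = _union_intervals(ivs)
    truncated = False
    frags = []
    for a, b in merged:
        seq = genome.fetch(gene.chrom, a, b)
        if len(seq) < b - a:
            truncated = True
        frags.append(seq)
    if gene.strand == "-":
        frags = [reverse_complement(f) for f in reversed(frags)]
    return "".join(frags), truncated


def _upstream_window(gene: GeneModel, genome: GenomeStore,
                     far: int, near: int) -> RegionExtract:
    """The window [−far, −near) relative to the TSS, on the coding strand."""
    t = gene.tss
    if gene.strand == "+":
        a, b = t - far, t - near
    else:
        a, b = t + near, t + far
    seq = genome.fetch(gene.chrom, a, b)
    truncated = len(seq) < (far - near)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return RegionExtract(seq, truncated)


def _transcript_region_intervals(gene: GeneModel, region: str
                                 ) -> List[Tuple[int, int]]:
    coding = gene.coding_transcripts
    if not coding:
        raise EmptyRegionError(
            f"gene {gene.gene_id} has no coding transcript; "
            f"region {region} undefined"
        )
    ivs: List[Tuple[int, int]] = []
    for t in coding:
        cds_start, cds_end = t.cds[0][0], t.cds[-1][1]
        if region == "cds":
            ivs.extend(t.cds)
        elif region == "utr5":
            if gene.strand == "+":
                ivs.append((t.start, cds_start))
            else:
                ivs.append((cds_end, t.end))
        elif region == "utr3":
            if gene.strand == "+":
                ivs.append((cds_end, t.end))
            else:
                ivs.append((t.start, cds_start))
        else:  # pragma: no cover
            raise ValueError(region)
    return ivs


def extract_region(gene: GeneModel, genome: GenomeStore, region: str,
                   promoter_length: int = PROMOTER_LENGTH,
                   window_length: int = WINDOW_LENGTH) -> RegionExtract:
    """Extract one region's sequence (5'→3') for one gene.

    Chromosome-edge truncation returns the truncated sequence with the
    flag set.  utr5/cds/utr3 are the interval union over all coding
    transcript variants.
    """
    if region not in REGION_TYPES:
        raise ValueError(f"unknown region {region!r}")
    w = window_length
    if region == "promoter_full":
        return _upstream_window(gene, genome, promoter_length, 0)
    if region == "promoter_w1":
        return _upstream_window(gene, genome, promoter_length, promoter_length - w)
    if region == "promoter_w2":
        return _upstream_window(gene, genome, promoter_length - w,
                                promoter_length - 2 * w)
    if region == "promoter_w3":
        return _upstream_window(gene, genome, w, 0)
    if region == "upstream_far":
        return _upstream_window(gene, genome, *UPSTREAM_FAR_SPAN)
    ivs = _transcript_region_intervals(gene, region)
    seq, truncated = _fetch_fragments(gene, genome, ivs)
    return RegionExtract(seq, truncated)


# ---------------------------------------------------------------------------
# multi-species region sets


@dataclass
class RegionSequenceSet:
    """For one (ortholog) gene and one region type, the sequence per species."""

    gene_id: str
    region: str
    sequences: Dict[str, str]
    truncated: Dict[str, bool] = field(default_factory=dict)

    @property
    def contains_undefined(self) -> Dict[str, bool]:
        return {sp: ("N" in seq) for sp, seq in self.sequences.items()}

    @property
    def any_undefined(self) -> bool:
        return any(self.contains_undefined.values())


def build_region_sets(
    genes_by_species: Mapping[str, Mapping[str, GeneModel]],
    genomes: Mapping[str, GenomeStore],
    species_set: SpeciesSet,
    regions: Sequence[str] = REGION_TYPES,
    promoter_length: int = PROMOTER_LENGTH,
    window_length: int = WINDOW_LENGTH,
) -> Dict[str, List[RegionSequenceSet]]:
    """Extract every requested region for genes shared by all species.

    ``genes_by_species`` maps species → {ortholog group id → GeneModel};
    orthology is an input (shared group ids), never inferred here.
    Genes lacking a model in any species are skipped; genes whose
    transcript-derived region is undefined or empty in any species are
    skipped for that region only.
    """
    shared = set(genes_by_species[species_set.labels[0]])
    for sp in species_set.labels[1:]:
        shared &= set(genes_by_species[sp])
    out: Dict[str, List[RegionSequenceSet]] = {r: [] for r in regions}
    for gid in sorted(shared):
        for region in regions:
            seqs: Dict[str, str] = {}
            trunc: Dict[str, bool] = {}
            ok = True
            for sp in species_set.labels:
                try:
                    ext = extract_region(
                        genes_by_species[sp][gid], genomes[sp], region,
                        promoter_length, window_length,
                    )
                except EmptyRegionError:
                    ok = False
                    break
                if not ext.sequence:
                    ok = False
                    break
                seqs[sp] = ext.sequence
                trunc[sp] = ext.truncated
            if ok:
                out[region].append(RegionSequenceSet(gid, region, seqs, trunc))
    return out


def filter_undefined(region_sets: Sequence[RegionSequenceSet],
                     species_set: Optional[SpeciesSet] = None
                     ) -> List[RegionSequenceSet]:
    """Drop any gene×region whose sequence contains 'N' in any species.

    Filtering is per region type, independently: the caller passes one
    region's sets at a time (or a mixed list; membership is decided per
    set).  Idempotent and order-independent.
    """
    if species_set is not None:
        for rs in region_sets:
            missing = set(species_set.labels) - set(rs.sequences)
            if missing:
                raise ValueError(
                    f"{rs.gene_id}/{rs.region} missing species {sorted(missing)}"
                )
    return [rs for rs in region_sets if not rs.any_undefined]


def summarize_region_lengths(
    region_sets: Iterable[RegionSequenceSet],
) -> pd.DataFrame:
    """Per-species, per-region length summary (count, mean, median)."""
    rows = []
    for rs in region_sets:
        for sp, seq in rs.sequences.items():
            rows.append((rs.region, sp, len(seq)))
    if not rows:
        raise ValueError("no region sets to summarize")
    df = pd.DataFrame(rows, columns=["region", "species", "length"])
    out = (
        df.groupby(["region", "species"])["length"]
        .agg(n="count", mean="mean", median="median")
        .reset_index()
    )
    return out
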