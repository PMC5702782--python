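"""Intergenic region extraction and classification.

The prediction unit of this package is a whole genomic region, not an
individual motif hit.  Intergenic gaps are split into two classes based on
the orientation of the flanking genes:

* **other intergenic** — upstream of at least one adjacent gene; the search
  space for transcription targets;
* **convergent intergenic** — downstream of both adjacent genes (the genes
  point toward the gap from either side); regulator binding is not expected
  there, which makes these gaps a natural empirical background.

Putative negatives are sampled from deep inside ORFs, excluding a margin at
both ends where functional promoter elements are sometimes located.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Gene",
    "GenomicRegion",
    "OTHER",
    "CONVERGENT",
    "ORF_INTERIOR",
    "classify_intergenic",
    "sample_orf_interior",
    "load_positive_set",
    "read_gff3_genes",
    "read_genome_fasta",
    "write_genome_fasta",
    "write_gff3",
    "write_regions_bed",
    "write_regions_fasta",
    "read_bed_intervals",
]

OTHER = "other_intergenic"
CONVERGENT = "convergent_intergenic"
ORF_INTERIOR = "orf_interior"


@dataclass(frozen=True)
class Gene:
    """A gene interval; coordinates are 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene interval {self.gene_id}: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class GenomicRegion:
    """A sequence interval with a class label and provenance coordinates."""

    region_id: str
    seq: str
    chrom: str
    start: int
    end: int
    region_class: str
    #: strands of the genes flanking an intergenic gap, (left, right);
    #: ``None`` on a side with no flanking gene (chromosome end).
    flank_info: tuple[Optional[str], Optional[str]] = (None, None)

    def __post_init__(self):
        if self.end - self.start != len(self.seq) or not self.seq:
            raise ValueError(
                f"region {self.region_id}: coordinates [{self.start},{self.end}) "
                f"do not match sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _region_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


@dataclass(frozen=True)
class _Cluster:
    start: int
    end: int
    left_strand: str   # strand of the member gene reaching the left edge
    right_strand: str  # strand of the member gene reaching the right edge


def _merge_genes(genes: Sequence[Gene]) -> list[_Cluster]:
    """Union-merge overlapping/adjacent-on-overlap gene intervals.

    For classification only the gene *touching* each cluster edge matters,
    so each cluster records the strand of its leftmost-starting and
    rightmost-ending members.
    """
    out: list[_Cluster] = []
    for g in sorted(genes, key=lambda g: (g.start, g.end)):
        if out and g.start < out[-1].end:
            prev = out[-1]
            if g.end > prev.end:
                out[-1] = _Cluster(prev.start, g.end, prev.left_strand, g.strand)
        else:
            out.append(_Cluster(g.start, g.end, g.strand, g.strand))
    return out


def _gap_class(left: Optional[str], right: Optional[str]) -> str:
    """Strand-pair rule.  A gap is upstream of its right neighbor iff that
    gene is '+', upstream of its left neighbor iff that gene is '-'.
    Convergent (downstream of both) therefore means ('+', '-')."""
    if left is None:  # gap before the first gene
        return OTHER if right == "+" else CONVERGENT
    if right is None:  # gap after the last gene
        return OTHER if left == "-" else CONVERGENT
    return CONVERGENT if (left == "+" and right == "-") else OTHER


def classify_intergenic(
    genes: Sequence[Gene],
    genome: dict[str, str],
    min_length: int = 1,
    circular: bool = False,
) -> list[GenomicRegion]:
    """Extract and classify every intergenic gap of length >= ``min_length``.

    Overlapping gene annotations are union-merged first.  In circular mode
    the gap spanning the origin joins the last and first genes (its sequence
    wraps around); otherwise chromosome-end gaps are classified from their
    single flanking gene.
    """
    regions: list[GenomicRegion] = []
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        if g.end > len(genome[g.chrom]):
            raise ValueError(
                f"gene {g.gene_id} extends past the end of {g.chrom} "
                f"({g.end} > {len(genome[g.chrom])})"
            )
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom in sorted(by_chrom):
        seq = genome[chrom]
        L = len(seq)
        clusters = _merge_genes(by_chrom[chrom])

        def add(start: int, end: int, left: Optional[str], right: Optional[str]):
            if end - start >= max(min_length, 1):
                regions.append(
                    GenomicRegion(
                        region_id=_region_id(chrom, start, end),
                        seq=seq[start:end],
                        chrom=chrom,
                        start=start,
                        end=end,
                        region_class=_gap_class(left, right),
                        flank_info=(left, right),
                    )
                )

        for prev, nxt in zip(clusters, clusters[1:]):
            add(prev.end, nxt.start, prev.right_strand, nxt.left_strand)

        first, last = clusters[0], clusters[-1]
        if circular:
            # wrap-around gap: [last.end, L) + [0, first.start)
            wrap_len = (L - last.end) + first.start
            if wrap_len >= max(min_length, 1):
                wseq = seq[last.end :] + seq[: first.start]
                regions.append(
                    GenomicRegion(
                        region_id=f"{chrom}:{last.end}-{first.start}(wrap)",
                        seq=wseq,
                        chrom=chrom,
                        start=last.end,
                        end=last.end + wrap_len,
                        region_class=_gap_class(
                            last.right_strand, first.left_strand
                        ),
                        flank_info=(last.right_strand, first.left_strand),
                    )
                )
        else:
            add(0, first.start, None, first.left_strand)
            add(last.end, L, last.right_strand, None)
    return regions


def sample_orf_interior(
    genes: Sequence[Gene],
    genome: dict[str, str],
    target_lengths: Sequence[int],
    margin: int = 50,
    rng_seed: Union[int, np.random.Generator, None] = 0,
) -> list[GenomicRegion]:
    """Sample ORF-interior putative-negative regions, one per requested
    length, each fully inside ``[orf.start + margin, orf.end - margin)`` and
    drawn uniformly over all eligible (ORF, offset) placements."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    genes = sorted(genes, key=lambda g: (g.chrom, g.start))
    out: list[GenomicRegion] = []
    for L in target_lengths:
        placements = np.array(
            [max(0, (g.end - g.start) - 2 * margin - L + 1) for g in genes]
        )
        total = int(placements.sum())
        if total == 0:
            raise ValueError(
                f"no ORF can host an interior region of length {L} with "
                f"margin {margin}"
            )
        gi = rng.choice(len(genes), p=placements / total)
        off = int(rng.integers(placements[gi]))
        g = genes[gi]
        start = g.start + margin + off
        end = start + L
        out.append(
            GenomicRegion(
                region_id=_region_id(g.chrom, start, end),
                seq=genome[g.chrom][start:end],
                chrom=g.chrom,
                start=start,
                end=end,
                region_class=ORF_INTERIOR,
            )
        )
    return out


def load_positive_set(
    regions: Sequence[GenomicRegion],
    evidence: Union[Iterable[str], Iterable[tuple]],
) -> list[GenomicRegion]:
    """Select the positive regions from ``regions`` by id, or by overlap
    with ``(chrom, start, end)`` intervals (e.g. from a BED file).  The
    returned subset preserves the order of ``regions``."""
    evidence = list(evidence)
    if not evidence:
        return []
    if all(isinstance(e, str) for e in evidence):
        ids = set(evidence)
        known = {r.region_id for r in regions}
        missing = ids - known
        if missing:
            raise ValueError(f"evidence id(s) not found: {sorted(missing)[:5]}")
        return [r for r in regions if r.region_id in ids]
    hits = []
    for r in regions:
        for chrom, start, end, *_ in evidence:
            if chrom == r.chrom and start < r.end and end > r.start:
                hits.append(r)
                break
    return hits


# ---------------------------------------------------------------------------
# File I/O


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gff3_genes(path, feature_type: str = "gene") -> list[Gene]:
    """Read gene features from GFF3 (1-based inclusive -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for i, feat in enumerate(db.features_of_type(feature_type)):
        gid = feat.attributes.get("ID", [f"{feature_type}_{i + 1}"])[0]
        strand = feat.strand if feat.strand in "+-" else "+"
        genes.append(
            Gene(
                gene_id=gid,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=strand,
            )
        )
    if not genes:
        raise ValueError(f"no {feature_type!r} features in {path}")
    return genes


def write_gff3(genes: Sequence[Gene], path, source: str = "regionks") -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    source,
                    "gene",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_regions_bed(regions: Sequence[GenomicRegion], path) -> None:
    """BED6; the name field carries ``region_id|region_class``."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}|{r.region_class}\t0\t.\n"
            )


def write_regions_fasta(regions: Sequence[GenomicRegion], path) -> None:
    records = [
        SeqRecord(Seq(r.seq), id=r.region_id, description=r.region_class)
        for r in regions
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed_intervals(path) -> list[tuple]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append((f[0], int(f[1]), int(f[2])) + tuple(f[3:4]))
    return out
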