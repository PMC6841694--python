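"""Read-to-gene assignment producing the six per-gene count types.

For every aligned read (or fragment) the counter evaluates, independently:

* ``n_ust``   — unstranded count over the full exon union; a read touching
  exons of several genes increments each of them.
* ``n_ustno`` — unstranded count restricted to reads that touch exons of
  exactly one gene (union-mode unambiguous assignment).
* ``n_st``    — like ``n_ust`` among genes matching the read's inferred
  transcriptional strand (stranded libraries only).
* ``n_stno``  — reads counted in ``n_ustno`` whose inferred strand matches
  the gene; by construction ``n_stno <= n_ustno`` and both tally reads over
  the identical unique region, which is what makes the
  log2(N_ustno/N_stno) comparison meaningful.
* ``n_jctn``  — reads with a CIGAR-N gap exactly matching an annotated
  splice junction of the gene (and counted in its ``n_ust``).
* ``n_intr``  — reads overlapping the gene's introns and no gene's exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pysam

from .gene_models import GenomeDatabase
from .intervals import Interval, merge

log = logging.getLogger(__name__)

STRAND_COLUMNS = ("n_st", "n_stno")
COUNT_COLUMNS = ("n_st", "n_stno", "n_ust", "n_ustno", "n_jctn", "n_intr")


@dataclass
class CountRecord:
    gene_id: str
    n_st: int = 0
    n_stno: int = 0
    n_ust: int = 0
    n_ustno: int = 0
    n_jctn: int = 0
    n_intr: int = 0


@dataclass(frozen=True)
class LibraryConfig:
    """Library protocol and filtering settings.

    strandedness 'R' is the dUTP convention: the first mate aligns opposite
    to the transcribed strand. 'U' disables the stranded count types.
    """

    strandedness: str = "U"
    mapq_min: int = 10
    count_unit: str = "read"  # or "fragment"
    keep_duplicates: bool = False

    def __post_init__(self) -> None:
        if self.strandedness not in {"U", "F", "R"}:
            raise ValueError(f"strandedness must be U, F or R, got {self.strandedness!r}")
        if self.count_unit not in {"read", "fragment"}:
            raise ValueError(f"count_unit must be read or fragment")


@dataclass
class ReadAlignment:
    """Alignment geometry extracted from one read or pooled mate pair."""

    query_name: str
    chrom: str
    blocks: list[Interval]
    gaps: list[Interval]
    alignment_strand: str
    is_read2: bool = False


@dataclass
class CountDiagnostics:
    processed: int = 0
    counted: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    duplicate: int = 0
    low_mapq: int = 0
    missing_chrom: int = 0
    ambiguous: int = 0
    no_feature: int = 0
    mate_chrom_mismatch: int = 0

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def infer_read_gene_strand(alignment_strand: str, is_read2: bool, lib: LibraryConfig) -> str:
    """Strand of the transcript a read came from, or 'unknown' for lib U."""
    if lib.strandedness == "U":
        return "unknown"
    strand = alignment_strand
    if is_read2:
        strand = "-" if strand == "+" else "+"
    if lib.strandedness == "R":
        strand = "-" if strand == "+" else "+"
    return strand


def blocks_and_gaps(read: pysam.AlignedSegment) -> tuple[list[Interval], list[Interval]]:
    """Aligned reference blocks (split at N) and the N gaps between them."""
    blocks: list[Interval] = []
    gaps: list[Interval] = []
    pos = read.reference_start
    start = pos
    for op, ln in read.cigartuples:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += ln
        elif op == 3:  # N
            if pos > start:
                blocks.append((start, pos))
            gaps.append((pos, pos + ln))
            pos += ln
            start = pos
        # I, S, H, P do not consume reference
    if pos > start:
        blocks.append((start, pos))
    return blocks, gaps


def assign_read(
    aln: ReadAlignment,
    db: GenomeDatabase,
    lib: LibraryConfig,
    counts: dict[str, CountRecord],
    diag: CountDiagnostics,
) -> None:
    """Apply one read's increments to ``counts`` (union-mode semantics)."""
    etree = db.exon_index.get(aln.chrom)
    if etree is None:
        diag.missing_chrom += 1
        return

    exon_hits: set[tuple[str, str]] = set()
    for s, e in aln.blocks:
        for hit in etree.overlap(s, e):
            exon_hits.add(hit.data)

    read_strand = infer_read_gene_strand(aln.alignment_strand, aln.is_read2, lib)

    touched = False
    if exon_hits:
        touched = True
        for gid, gstrand in exon_hits:
            counts[gid].n_ust += 1
            if read_strand == gstrand:
                counts[gid].n_st += 1
        if len(exon_hits) == 1:
            ((gid, gstrand),) = exon_hits
            counts[gid].n_ustno += 1
            if read_strand == gstrand:
                counts[gid].n_stno += 1
        else:
            diag.ambiguous += 1
        if aln.gaps:
            jct_genes: set[str] = set()
            for gs, ge in aln.gaps:
                jct_genes |= db.junction_index.get((aln.chrom, gs, ge), frozenset())
            hit_gids = {gid for gid, _ in exon_hits}
            for gid in jct_genes & hit_gids:
                counts[gid].n_jctn += 1
    else:
        # intronic reads: only reads touching no gene's exons anywhere
        itree = db.intron_index.get(aln.chrom)
        intron_hits: set[tuple[str, str]] = set()
        if itree is not None:
            for s, e in aln.blocks:
                for hit in itree.overlap(s, e):
                    intron_hits.add(hit.data)
        if intron_hits:
            touched = True
            for gid, _ in intron_hits:
                counts[gid].n_intr += 1
    if touched:
        diag.counted += 1
    else:
        diag.no_feature += 1


def _passes_filters(read: pysam.AlignedSegment, lib: LibraryConfig, diag: CountDiagnostics) -> bool:
    if read.is_unmapped:
        diag.unmapped += 1
        return False
    if read.is_secondary:
        diag.secondary += 1
        return False
    if read.is_supplementary:
        diag.supplementary += 1
        return False
    if read.is_duplicate and not lib.keep_duplicates:
        diag.duplicate += 1
        return False
    if read.mapping_quality < lib.mapq_min:
        diag.low_mapq += 1
        return False
    return True


def count_bam(
    bam_path: str | Path,
    db: GenomeDatabase,
    lib: LibraryConfig,
) -> tuple[dict[str, CountRecord], CountDiagnostics]:
    """Count all reads of a coordinate-sorted, indexed BAM.

    With ``count_unit='fragment'`` both mates of a pair are pooled and the
    fragment counted once; single-end reads and orphan mates count alone.
    """
    bam_path = Path(bam_path)
    if not bam_path.exists():
        raise FileNotFoundError(bam_path)
    counts = {gid: CountRecord(gene_id=gid) for gid in db.genes}
    diag = CountDiagnostics()
    pending: dict[str, ReadAlignment] = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path} is not indexed (samtools index)")
        for read in bam.fetch(until_eof=True):
            diag.processed += 1
            if not _passes_filters(read, lib, diag):
                continue
            blocks, gaps = blocks_and_gaps(read)
            aln = ReadAlignment(
                query_name=read.query_name,
                chrom=read.reference_name,
                blocks=blocks,
                gaps=gaps,
                alignment_strand="-" if read.is_reverse else "+",
                is_read2=read.is_paired and read.is_read2,
            )
            if lib.count_unit == "fragment" and read.is_paired:
                mate = pending.pop(read.query_name, None)
                if mate is None:
                    pending[read.query_name] = aln
                    continue
                if mate.chrom != aln.chrom:
                    diag.mate_chrom_mismatch += 1
                    continue
                first = mate if not mate.is_read2 else aln
                aln = ReadAlignment(
                    query_name=read.query_name,
                    chrom=aln.chrom,
                    blocks=merge(mate.blocks + aln.blocks),
                    gaps=sorted(set(mate.gaps) | set(aln.gaps)),
                    alignment_strand=first.alignment_strand,
                    is_read2=False,
                )
            assign_read(aln, db, lib, counts, diag)
        # orphan mates (mate unmapped/filtered) are counted as single reads
        for aln in pending.values():
            first_strand = aln.alignment_strand
            if aln.is_read2:
                first_strand = "-" if first_strand == "+" else "+"
            assign_read(
                ReadAlignment(
                    aln.query_name, aln.chrom, aln.blocks, aln.gaps, first_strand
                ),
                db,
                lib,
                counts,
                diag,
            )
    if lib.strandedness in {"F", "R"}:
        tot_st = sum(c.n_st for c in counts.values())
        tot_ust = sum(c.n_ust for c in counts.values())
        if tot_ust > 0 and tot_st < 0.25 * tot_ust:
            log.warning(
                "stranded counts are much lower than unstranded (%d vs %d); "
                "check the --strand setting",
                tot_st,
                tot_ust,
            )
    return counts, diag


def compute_tpm(
    counts: dict[str, CountRecord],
    db: GenomeDatabase,
    which: str = "n_ustno",
) -> dict[str, float]:
    """Transcripts-per-million from one count type.

    Length normalization uses the unique-region length for the *no count
    types and the full exonic length otherwise; genes with zero usable
    length get TPM 0 and do not enter the denominator.
    """
    if which not in COUNT_COLUMNS:
        raise ValueError(f"unknown count type {which!r}")
    use_nonoverlap = which.endswith("no")
    rates: dict[str, float] = {}
    for gid, rec in counts.items():
        g = db.genes[gid]
        length = g.nonoverlap_len if use_nonoverlap else g.exonic_len
        rates[gid] = getattr(rec, which) / (length / 1000.0) if length > 0 else 0.0
    denom = sum(rates.values())
    if denom == 0:
        return {gid: 0.0 for gid in rates}
    return {gid: r / denom * 1e6 for gid, r in rates.items()}


def write_counts_tsv(
    counts: dict[str, CountRecord],
    lib: LibraryConfig,
    out_path: str | Path,
) -> None:
    """Six-column count table; stranded columns are NA for lib U."""
    with open(out_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(COUNT_COLUMNS) + "\n")
        for gid in sorted(counts):
            rec = counts[gid]
            vals = []
            for col in COUNT_COLUMNS:
                if lib.strandedness == "U" and col in STRAND_COLUMNS:
                    vals.append("NA")
                else:
                    vals.append(str(getattr(rec, col)))
            fh.write(gid + "\t" + "\t".join(vals) + "\n")


def write_diagnostics_tsv(diag: CountDiagnostics, out_path: str | Path) -> None:
    with open(out_path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in diag.as_dict().items():
            fh.write(f"{k}\t{v}\n")
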