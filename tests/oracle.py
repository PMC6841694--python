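"""Independent brute-force oracles used to cross-check the implementation.

The read-counting oracle classifies every BAM read by exhaustive per-base
membership tests against position sets rebuilt from the raw isoform exon
chains — it shares no interval arithmetic, indexing, or assignment code
with the package's counter. The junction-placement oracle instantiates
every read placement on a transcript and tests boundary spanning per base.
"""

from __future__ import annotations

from collections import defaultdict

import pysam


def gene_position_sets(db):
    """Per-gene exon/intron position sets recomputed from isoform chains."""
    exon_pos: dict[str, set[int]] = {}
    intron_pos: dict[str, set[int]] = {}
    junctions: dict[str, set[tuple[int, int]]] = {}
    for gid, g in db.genes.items():
        pos: set[int] = set()
        jset: set[tuple[int, int]] = set()
        for _tid, exons in g.isoforms:
            for s, e in exons:
                pos.update(range(s, e))
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                jset.add((e1, s2))
        exon_pos[gid] = pos
        junctions[gid] = jset
        span = range(min(pos), max(pos) + 1)
        intron_pos[gid] = set(span) - pos
    return exon_pos, intron_pos, junctions


def brute_force_counts(bam_path, db, strandedness="U"):
    """Six count types per gene via per-base membership, mapq >= 10 filter."""
    exon_pos, intron_pos, junctions = gene_position_sets(db)
    by_chrom_exon = defaultdict(dict)
    by_chrom_intron = defaultdict(dict)
    for gid, g in db.genes.items():
        by_chrom_exon[g.chrom][gid] = exon_pos[gid]
        by_chrom_intron[g.chrom][gid] = intron_pos[gid]
    counts = {
        gid: dict(n_st=0, n_stno=0, n_ust=0, n_ustno=0, n_jctn=0, n_intr=0)
        for gid in db.genes
    }
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < 10
            ):
                continue
            chrom = read.reference_name
            covered = set()
            gaps = []
            pos = read.reference_start
            start = pos
            for op, ln in read.cigartuples:
                if op in (0, 2, 7, 8):
                    pos += ln
                elif op == 3:
                    covered.update(range(start, pos))
                    gaps.append((pos, pos + ln))
                    pos += ln
                    start = pos
            covered.update(range(start, pos))

            hit = [
                gid
                for gid, ps in by_chrom_exon.get(chrom, {}).items()
                if covered & ps
            ]
            if strandedness == "U":
                read_strand = None
            else:
                s = "-" if read.is_reverse else "+"
                if read.is_paired and read.is_read2:
                    s = "-" if s == "+" else "+"
                if strandedness == "R":
                    s = "-" if s == "+" else "+"
                read_strand = s
            if hit:
                for gid in hit:
                    counts[gid]["n_ust"] += 1
                    if read_strand == db.genes[gid].strand:
                        counts[gid]["n_st"] += 1
                    if any(gap in junctions[gid] for gap in gaps):
                        counts[gid]["n_jctn"] += 1
                if len(hit) == 1:
                    gid = hit[0]
                    counts[gid]["n_ustno"] += 1
                    if read_strand == db.genes[gid].strand:
                        counts[gid]["n_stno"] += 1
            else:
                for gid, ps in by_chrom_intron.get(chrom, {}).items():
                    if covered & ps:
                        counts[gid]["n_intr"] += 1
    return counts


def brute_force_junction_probability(exon_chain, read_length, min_overhang):
    """Enumerate every single-end placement on one molecule, test per base.

    Transcript positions are labelled by exon index; a placement spans a
    junction when it covers bases of two exons with at least min_overhang
    bases on each side of some boundary.
    """
    labels = []
    for idx, (s, e) in enumerate(exon_chain):
        labels.extend([idx] * (e - s))
    L = len(labels)
    starts = range(L - read_length + 1) if L >= read_length else [0]
    eff = min(read_length, L)
    total = 0
    junction = 0
    for s in starts:
        window = labels[s : s + eff]
        total += 1
        spans = False
        for b in range(1, eff):
            if window[b] != window[b - 1]:
                if b >= min_overhang and eff - b >= min_overhang:
                    spans = True
        if spans:
            junction += 1
    return total, junction
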