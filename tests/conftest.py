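import pysam
import pytest

from strandbias.gene_models import build_database


def make_gtf(path, genes):
    """Write a minimal Gencode-dialect GTF.

    genes: list of dicts with gene_id, strand, chrom (default 'c1') and
    transcripts: {tid: [(start, end), ...]} in 0-based half-open coords.
    """
    with open(path, "w") as fh:
        for g in genes:
            chrom = g.get("chrom", "c1")
            attrs = (
                f'gene_id "{g["gene_id"]}"; gene_name "{g["gene_id"]}"; '
                f'gene_type "{g.get("biotype", "protein_coding")}";'
            )
            for tid, exons in g["transcripts"].items():
                tattrs = attrs + f' transcript_id "{tid}";'
                for s, e in exons:
                    fh.write(
                        f"{chrom}\ttest\texon\t{s + 1}\t{e}\t.\t{g['strand']}\t.\t{tattrs}\n"
                    )
    return path


def make_bam(path, reads, chrom="c1", chrom_len=100_000):
    """Write a sorted+indexed BAM from (name, pos, cigar, reverse[, mapq]) tuples."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
    reads = sorted(reads, key=lambda r: r[1])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in reads:
            name, pos, cigar, reverse = r[:4]
            mapq = r[4] if len(r) > 4 else 60
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = cigar
            a.mapping_quality = mapq
            a.is_reverse = reverse
            bam.write(a)
    pysam.index(str(path))
    return path


TOY_GENES = [
    {
        "gene_id": "A",
        "strand": "+",
        "transcripts": {"A.t1": [(100, 200), (300, 400), (500, 600)]},
    },
    {"gene_id": "B", "strand": "-", "transcripts": {"B.t1": [(150, 250)]}},
    {"gene_id": "C", "strand": "+", "transcripts": {"C.t1": [(1000, 1100)]}},
]

# hand-placed reads over the toy annotation; lib R => aligned-reverse reads
# come from the + strand. See test_counting for the per-read bookkeeping.
TOY_READS = [
    ("r1", 100, "40M", True),
    ("r2", 160, "20M", True),
    ("r3", 160, "20M", False),
    ("r4", 205, "40M", True),
    ("r5", 205, "40M", False),
    ("r6", 180, "20M100N30M", True),
    ("r7", 380, "20M100N30M", True),
    ("r8", 260, "30M", False),
    ("r9", 420, "30M", True),
    ("r10", 1000, "50M", False),
    ("r11", 1020, "50M", True),
    ("r12", 1000, "50M", False, 5),  # below the mapq threshold
]


@pytest.fixture(scope="session")
def toy_db(tmp_path_factory):
    gtf = make_gtf(tmp_path_factory.mktemp("toy") / "toy.gtf", TOY_GENES)
    return build_database(gtf)


@pytest.fixture(scope="session")
def toy_bam(tmp_path_factory):
    return make_bam(tmp_path_factory.mktemp("toybam") / "toy.bam", TOY_READS)
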