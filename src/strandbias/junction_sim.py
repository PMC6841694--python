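"""Expected splice-junction-read probability per gene, by exact enumeration.

For a gene whose locus is genuinely transcribed, a predictable fraction of
its reads spans an annotated exon-exon junction. That fraction depends only
on the gene's isoform structure and the read configuration, under two
assumptions: isoforms are present at equal molar abundance, and coverage is
uniform along each transcript. Both are realized exactly by enumerating
every read placement on every isoform and pooling the placements — each
molecule contributes reads in proportion to its number of placements, which
is equal-molar weighting under uniform fragmentation.

Reads that arrived by carry-over from the opposite strand ignore the
exon-intron structure, so their junction fraction is near zero; the gap
between observed and expected junction fractions is the strongest predictor
of strand bias.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gene_models import GeneModel
from .counting import CountRecord
from .intervals import Interval

DEFAULT_MIN_OVERHANG = 8  # mirrors a spliced aligner's minimum junction overhang


@dataclass(frozen=True)
class ReadConfiguration:
    read_length: int = 50
    paired: bool = False
    fragment_length: int | None = None
    # optional empirical fragment-length distribution: [(length, weight), ...]
    fragment_dist: tuple[tuple[int, float], ...] | None = None
    min_overhang: int = DEFAULT_MIN_OVERHANG

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        if self.paired and self.fragment_length is None and self.fragment_dist is None:
            raise ValueError("paired reads require fragment_length or fragment_dist")


@dataclass(frozen=True)
class JunctionExpectation:
    gene_id: str
    p_expected: float
    n_positions_total: float
    n_positions_junction: float


def _isoform_boundaries(exons: tuple[Interval, ...]) -> tuple[int, list[int]]:
    """Transcript length and internal exon-boundary offsets in transcript bp."""
    length = 0
    boundaries = []
    for s, e in exons:
        length += e - s
        boundaries.append(length)
    return length, boundaries[:-1]


def _count_se(length: int, boundaries: list[int], rl: int, oh: int) -> tuple[int, int]:
    """Single-end placements (total, junction-spanning) on one molecule."""
    if length < rl:
        # molecule shorter than the read: one placement covering it whole
        spans = any(b >= oh and length - b >= oh for b in boundaries)
        return 1, int(spans)
    total = length - rl + 1
    # a start s spans boundary b iff  b-oh >= s >= b-rl+oh ; union the ranges
    ranges = []
    for b in boundaries:
        lo = max(0, b - rl + oh)
        hi = min(length - rl, b - oh)
        if lo <= hi:
            ranges.append((lo, hi))
    junction = 0
    ranges.sort()
    cur_lo, cur_hi = None, None
    for lo, hi in ranges:
        if cur_lo is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi + 1:
            cur_hi = max(cur_hi, hi)
        else:
            junction += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    if cur_lo is not None:
        junction += cur_hi - cur_lo + 1
    return total, junction


def _mate_spans(s: int, frag: int, rl: int) -> list[Interval]:
    """Aligned spans of the two mates of a fragment starting at s."""
    rl = min(rl, frag)
    return [(s, s + rl), (s + frag - rl, s + frag)]


def _count_pe(
    length: int, boundaries: list[int], rl: int, frag: int, oh: int
) -> tuple[int, int]:
    """Paired-end placements for one fragment length on one molecule."""
    frag = min(frag, length)
    total = length - frag + 1
    junction = 0
    for s in range(total):
        spans = _mate_spans(s, frag, rl)
        hit = False
        for ms, me in spans:
            for b in boundaries:
                if b - ms >= oh and me - b >= oh:
                    hit = True
                    break
            if hit:
                break
        junction += int(hit)
    return total, junction


def simulate_junction_probability(
    gene: GeneModel, cfg: ReadConfiguration
) -> JunctionExpectation:
    """Expected probability that one of the gene's reads spans a junction.

    Placements are pooled over isoforms; paired-end fragments span a
    junction if either mate covers an internal boundary with at least
    ``min_overhang`` aligned bases on both sides (a junction inside the
    mate overlap is counted once).
    """
    total = 0.0
    junction = 0.0
    for _tid, exons in gene.isoforms:
        length, boundaries = _isoform_boundaries(exons)
        if not cfg.paired:
            t, j = _count_se(length, boundaries, cfg.read_length, cfg.min_overhang)
            total += t
            junction += j
        else:
            dist = cfg.fragment_dist or ((cfg.fragment_length, 1.0),)
            wsum = sum(w for _, w in dist)
            for frag, w in dist:
                t, j = _count_pe(
                    length, boundaries, cfg.read_length, frag, cfg.min_overhang
                )
                total += w / wsum * t
                junction += w / wsum * j
    p = junction / total if total > 0 else 0.0
    return JunctionExpectation(
        gene_id=gene.gene_id,
        p_expected=p,
        n_positions_total=total,
        n_positions_junction=junction,
    )


def simulate_all(
    genes: dict[str, GeneModel], cfg: ReadConfiguration
) -> dict[str, JunctionExpectation]:
    return {gid: simulate_junction_probability(g, cfg) for gid, g in genes.items()}


def observed_junction_frequency(counts: CountRecord) -> float:
    """Observed junction reads as a fraction of the unstranded count."""
    if counts.n_ust == 0:
        return 0.0
    return counts.n_jctn / counts.n_ust


def write_expectations_tsv(
    expectations: dict[str, JunctionExpectation], out_path
) -> None:
    with open(out_path, "w") as fh:
        fh.write("gene_id\tp_expected\tn_positions_total\tn_positions_junction\n")
        for gid in sorted(expectations):
            ex = expectations[gid]
            fh.write(
                f"{gid}\t{ex.p_expected:.10g}\t{ex.n_positions_total:.10g}"
                f"\t{ex.n_positions_junction:.10g}\n"
            )
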