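"""Gene models from a GTF: exon unions, unique regions, introns, junctions.

The *build* step of the pipeline. Each gene is represented by the union of
its transcripts' exons ("exon union" counting model); the portion of that
union not shared with any other gene's exon union (on either strand) is the
gene's unique region, over which the stranded/unstranded count comparison is
defined. Annotated splice junctions are collected from consecutive exons of
every transcript. The result is persisted as a JSON database directory that
the count and analyze steps reload.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .intervals import (
    GenomicInterval,
    Interval,
    merge,
    span_distance,
    subtract,
    total_length,
)

log = logging.getLogger(__name__)

DB_FORMAT_VERSION = 1
NEIGHBOR_MAX_DISTANCE = 2000

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """Immutable per-gene model derived from all of the gene's transcripts."""

    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    span: GenomicInterval
    exon_union: tuple[Interval, ...]
    nonoverlap_exonic: tuple[Interval, ...]
    introns: tuple[Interval, ...]
    junctions: frozenset[tuple[int, int]]
    isoforms: tuple[tuple[str, tuple[Interval, ...]], ...]

    @property
    def exonic_len(self) -> int:
        return total_length(self.exon_union)

    @property
    def nonoverlap_len(self) -> int:
        return total_length(self.nonoverlap_exonic)

    @property
    def intron_len(self) -> int:
        return total_length(self.introns)

    @property
    def overlap_fraction(self) -> float:
        return 1.0 - self.nonoverlap_len / self.exonic_len

    @property
    def monoexonic(self) -> bool:
        return not self.junctions


@dataclass
class GenomeDatabase:
    genes: dict[str, GeneModel]
    neighbors: dict[str, tuple[str, ...]]
    exon_index: dict[str, IntervalTree] = field(repr=False, default_factory=dict)
    intron_index: dict[str, IntervalTree] = field(repr=False, default_factory=dict)
    junction_index: dict[tuple[str, int, int], frozenset[str]] = field(
        repr=False, default_factory=dict
    )

    def save(self, dbdir: str | Path) -> None:
        """Write the database as a plain-text JSON directory.

        Serialization is canonical (sorted keys, sorted lists) so rebuilding
        from the same GTF produces byte-identical files.
        """
        dbdir = Path(dbdir)
        dbdir.mkdir(parents=True, exist_ok=True)
        payload = {
            "format_version": DB_FORMAT_VERSION,
            "genes": {
                gid: _gene_to_json(g) for gid, g in sorted(self.genes.items())
            },
            "neighbors": {
                gid: sorted(ns) for gid, ns in sorted(self.neighbors.items())
            },
        }
        with open(dbdir / "genes.json", "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1, separators=(",", ": "))
            fh.write("\n")

    @classmethod
    def load(cls, dbdir: str | Path) -> "GenomeDatabase":
        path = Path(dbdir) / "genes.json"
        if not path.exists():
            raise FileNotFoundError(f"no database at {dbdir}")
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != DB_FORMAT_VERSION:
            raise ValueError(
                f"unsupported database format {payload.get('format_version')}"
            )
        genes = {gid: _gene_from_json(gid, d) for gid, d in payload["genes"].items()}
        neighbors = {gid: tuple(ns) for gid, ns in payload["neighbors"].items()}
        db = cls(genes=genes, neighbors=neighbors)
        db._build_indices()
        return db

    def _build_indices(self) -> None:
        self.exon_index = {}
        self.intron_index = {}
        jidx: dict[tuple[str, int, int], set[str]] = {}
        for gid, g in self.genes.items():
            etree = self.exon_index.setdefault(g.chrom, IntervalTree())
            for s, e in g.exon_union:
                etree.addi(s, e, (gid, g.strand))
            itree = self.intron_index.setdefault(g.chrom, IntervalTree())
            for s, e in g.introns:
                itree.addi(s, e, (gid, g.strand))
            for d, a in g.junctions:
                jidx.setdefault((g.chrom, d, a), set()).add(gid)
        self.junction_index = {k: frozenset(v) for k, v in jidx.items()}


def _gene_to_json(g: GeneModel) -> dict:
    return {
        "gene_name": g.gene_name,
        "biotype": g.biotype,
        "chrom": g.chrom,
        "strand": g.strand,
        "span": [g.span.start, g.span.end],
        "exon_union": [list(iv) for iv in g.exon_union],
        "nonoverlap_exonic": [list(iv) for iv in g.nonoverlap_exonic],
        "introns": [list(iv) for iv in g.introns],
        "junctions": sorted([d, a] for d, a in g.junctions),
        "isoforms": [
            {"transcript_id": tid, "exons": [list(iv) for iv in exons]}
            for tid, exons in sorted(g.isoforms)
        ],
    }


def _gene_from_json(gid: str, d: dict) -> GeneModel:
    return GeneModel(
        gene_id=gid,
        gene_name=d["gene_name"],
        biotype=d["biotype"],
        chrom=d["chrom"],
        strand=d["strand"],
        span=GenomicInterval(d["chrom"], d["span"][0], d["span"][1], d["strand"]),
        exon_union=tuple((s, e) for s, e in d["exon_union"]),
        nonoverlap_exonic=tuple((s, e) for s, e in d["nonoverlap_exonic"]),
        introns=tuple((s, e) for s, e in d["introns"]),
        junctions=frozenset((d_, a) for d_, a in d["junctions"]),
        isoforms=tuple(
            (iso["transcript_id"], tuple((s, e) for s, e in iso["exons"]))
            for iso in d["isoforms"]
        ),
    )


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf_exons(
    gtf_path: str | Path,
    attribute_keys: dict[str, str] | None = None,
    transcript_tag: str | None = None,
):
    """Yield exon records from a Gencode-dialect GTF.

    attribute_keys maps logical names (gene_id, transcript_id, gene_name,
    gene_type) to the attribute keys used in the file. With transcript_tag
    set, only exons of transcripts carrying that ``tag`` value are kept
    (e.g. ``"basic"`` to drop rare isoform models).
    """
    keys = {
        "gene_id": "gene_id",
        "transcript_id": "transcript_id",
        "gene_name": "gene_name",
        "gene_type": "gene_type",
    }
    if attribute_keys:
        keys.update(attribute_keys)
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            attrd = _parse_attributes(attrs)
            for req in ("gene_id", "transcript_id"):
                if keys[req] not in attrd:
                    raise GtfParseError(
                        f"{gtf_path}:{lineno}: exon record missing required "
                        f"attribute {keys[req]!r}"
                    )
            if transcript_tag is not None:
                tags = [v for k, v in _ATTR_RE.findall(attrs) if k == "tag"]
                if transcript_tag not in tags:
                    continue
            if strand not in {"+", "-"}:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: exon with invalid strand {strand!r}"
                )
            yield {
                "lineno": lineno,
                "chrom": chrom,
                "start": int(start) - 1,  # GTF 1-based inclusive -> 0-based half-open
                "end": int(end),
                "strand": strand,
                "gene_id": attrd[keys["gene_id"]],
                "transcript_id": attrd[keys["transcript_id"]],
                "gene_name": attrd.get(keys["gene_name"], attrd[keys["gene_id"]]),
                "biotype": attrd.get(keys["gene_type"], ""),
            }


def build_database(
    gtf_path: str | Path,
    attribute_keys: dict[str, str] | None = None,
    transcript_tag: str | None = None,
    neighbor_max_distance: int = NEIGHBOR_MAX_DISTANCE,
) -> GenomeDatabase:
    """Build a :class:`GenomeDatabase` from a GTF annotation.

    Genes spanning multiple chromosomes or with mixed exon strands are
    rejected. Transcripts with internally overlapping exons are merged with
    a warning.
    """
    raw: dict[str, dict] = {}
    n_exons = 0
    for rec in parse_gtf_exons(gtf_path, attribute_keys, transcript_tag):
        n_exons += 1
        g = raw.setdefault(
            rec["gene_id"],
            {
                "chrom": rec["chrom"],
                "strand": rec["strand"],
                "gene_name": rec["gene_name"],
                "biotype": rec["biotype"],
                "transcripts": {},
            },
        )
        if rec["chrom"] != g["chrom"]:
            raise GtfParseError(
                f"gene {rec['gene_id']} has exons on multiple chromosomes "
                f"({g['chrom']}, {rec['chrom']})"
            )
        if rec["strand"] != g["strand"]:
            raise GtfParseError(
                f"gene {rec['gene_id']} has exons on mixed strands"
            )
        g["transcripts"].setdefault(rec["transcript_id"], []).append(
            (rec["start"], rec["end"])
        )
    if n_exons == 0:
        raise GtfParseError(f"{gtf_path}: no exon records found")

    genes: dict[str, GeneModel] = {}
    for gid, g in raw.items():
        isoforms = []
        junctions: set[tuple[int, int]] = set()
        all_exons: list[Interval] = []
        for tid, exons in g["transcripts"].items():
            merged = merge(exons)
            if len(merged) < len(exons):
                log.warning(
                    "transcript %s of gene %s has overlapping exons; merged",
                    tid,
                    gid,
                )
            isoforms.append((tid, tuple(merged)))
            for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
                junctions.add((e1, s2))
            all_exons.extend(merged)
        exon_union = merge(all_exons)
        span = GenomicInterval(
            g["chrom"], exon_union[0][0], exon_union[-1][1], g["strand"]
        )
        genes[gid] = GeneModel(
            gene_id=gid,
            gene_name=g["gene_name"],
            biotype=g["biotype"],
            chrom=g["chrom"],
            strand=g["strand"],
            span=span,
            exon_union=tuple(exon_union),
            nonoverlap_exonic=(),  # filled below
            introns=tuple(subtract([(span.start, span.end)], exon_union)),
            junctions=frozenset(junctions),
            isoforms=tuple(sorted(isoforms)),
        )

    # unique (non-overlapping) exonic regions: subtract every other gene's
    # exon union, irrespective of strand, so stranded and unstranded counts
    # in this region are directly comparable
    exon_trees: dict[str, IntervalTree] = {}
    for gid, gm in genes.items():
        tree = exon_trees.setdefault(gm.chrom, IntervalTree())
        for s, e in gm.exon_union:
            tree.addi(s, e, gid)
    finalized: dict[str, GeneModel] = {}
    for gid, gm in genes.items():
        others: list[Interval] = []
        tree = exon_trees[gm.chrom]
        for s, e in gm.exon_union:
            for hit in tree.overlap(s, e):
                if hit.data != gid:
                    others.append((hit.begin, hit.end))
        nonoverlap = subtract(gm.exon_union, others)
        finalized[gid] = GeneModel(
            **{
                **gm.__dict__,
                "nonoverlap_exonic": tuple(nonoverlap),
            }
        )

    neighbors = _compute_neighbors(finalized, neighbor_max_distance)
    db = GenomeDatabase(genes=finalized, neighbors=neighbors)
    db._build_indices()
    return db


def _compute_neighbors(
    genes: dict[str, GeneModel], max_distance: int
) -> dict[str, tuple[str, ...]]:
    neighbors: dict[str, set[str]] = {gid: set() for gid in genes}
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in genes.values():
        by_chrom.setdefault(gm.chrom, []).append(gm)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.span.start, g.span.end, g.gene_id))
        for i, a in enumerate(chrom_genes):
            for b in chrom_genes[i + 1 :]:
                if b.span.start - a.span.end > max_distance:
                    break
                d = span_distance(
                    (a.span.start, a.span.end), (b.span.start, b.span.end)
                )
                if d <= max_distance:
                    neighbors[a.gene_id].add(b.gene_id)
                    neighbors[b.gene_id].add(a.gene_id)
    return {gid: tuple(sorted(ns)) for gid, ns in neighbors.items()}


def compute_overlap_fraction(gene: GeneModel, db: GenomeDatabase) -> float:
    """Fraction of the gene's exonic span shared with other genes' exons."""
    del db  # precomputed at build time; kept for interface symmetry
    return gene.overlap_fraction


def find_neighbors(
    gene: GeneModel, db: GenomeDatabase, max_distance: int = NEIGHBOR_MAX_DISTANCE
) -> list[str]:
    """Gene ids (either strand) whose span lies within max_distance bp."""
    if max_distance == NEIGHBOR_MAX_DISTANCE:
        return list(db.neighbors.get(gene.gene_id, ()))
    out = []
    for other in db.genes.values():
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
            continue
        d = span_distance(
            (gene.span.start, gene.span.end), (other.span.start, other.span.end)
        )
        if d <= max_distance:
            out.append(other.gene_id)
    return sorted(out)
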