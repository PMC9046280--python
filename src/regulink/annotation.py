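"""Gene models and HOMER-style categorical annotation of peaks.

Each peak is classified by its *center* into exactly one of five categories —
promoter, TTS, exon, intron, intergenic — with priority promoter > TTS >
exon > intron > intergenic, so the categories always partition a peak set.
The promoter window is strand-aware (default 1 kb upstream to 100 bp
downstream of the TSS); the TTS window extends 100 bp to each side of the
transcript end. Peaks falling in introns or intergenic space are flagged as
putative enhancers.

Gene models come from GTF (1-based inclusive on disk, converted to 0-based
half-open in memory). Models are gene-level: when a gene's exon rows extend
beyond its stated span the most extreme span is kept.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import DataFormatError, UsageError
from .intervals import GenomicInterval

__all__ = [
    "GeneModel",
    "AnnotationConfig",
    "AnnotatedPeak",
    "GeneIndex",
    "load_gene_models",
    "write_gtf",
    "annotate_peak",
    "annotate_peaks",
    "genomic_distribution",
    "write_annotation_tsv",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "exon", "intron", "TTS", "intergenic")
ENHANCER_CATEGORIES = frozenset({"intron", "intergenic"})


@dataclass(frozen=True)
class GeneModel:
    """One gene's strand-aware span and exon structure (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataFormatError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if not (0 <= self.tx_start < self.tx_end):
            raise DataFormatError(
                f"gene {self.gene_id}: invalid span "
                f"[{self.tx_start}, {self.tx_end})"
            )
        prev_end = self.tx_start
        for (s, e) in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise DataFormatError(
                    f"gene {self.gene_id}: exons must be sorted, "
                    "non-overlapping and contained in the transcript span"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        """Transcription end site."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    def signed_tss_distance(self, pos: int) -> int:
        """Signed distance from the TSS; positive downstream in gene orientation."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


@dataclass(frozen=True)
class AnnotationConfig:
    """Promoter / TTS window sizes in bp (HOMER-default-like)."""

    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    tts_window: int = 100

    def __post_init__(self) -> None:
        if min(self.promoter_upstream, self.promoter_downstream, self.tts_window) < 0:
            raise UsageError("annotation window sizes must be >= 0")


@dataclass(frozen=True)
class AnnotatedPeak:
    interval: GenomicInterval
    category: str
    nearest_gene: str | None
    tss_distance: int | None
    is_enhancer: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise UsageError(f"unknown category {self.category!r}")
        object.__setattr__(
            self, "is_enhancer", self.category in ENHANCER_CATEGORIES
        )


class GeneIndex:
    """Per-chromosome interval trees over promoter/TTS/exon/gene-body windows.

    Promoter and TTS windows are closed on both ends in position terms, so a
    window [lo, hi] is stored half-open as [lo, hi + 1).
    """

    def __init__(self, genes: Iterable[GeneModel], cfg: AnnotationConfig):
        self.cfg = cfg
        self.genes = sorted(genes, key=lambda g: g.gene_id)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise DataFormatError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        self._promoter: dict[str, IntervalTree] = {}
        self._tts: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        self._body: dict[str, IntervalTree] = {}
        tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
        self._by_id: dict[str, GeneModel] = {}
        for g in self.genes:
            self._by_id[g.gene_id] = g
            if g.strand == "+":
                plo, phi = g.tss - cfg.promoter_upstream, g.tss + cfg.promoter_downstream
            else:
                plo, phi = g.tss - cfg.promoter_downstream, g.tss + cfg.promoter_upstream
            self._promoter.setdefault(g.chrom, IntervalTree()).addi(
                max(0, plo), phi + 1, g.gene_id
            )
            self._tts.setdefault(g.chrom, IntervalTree()).addi(
                max(0, g.tes - cfg.tts_window), g.tes + cfg.tts_window + 1, g.gene_id
            )
            for (s, e) in g.exons:
                self._exon.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
            self._body.setdefault(g.chrom, IntervalTree()).addi(
                g.tx_start, g.tx_end, g.gene_id
            )
            tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        self._tss_sorted = {
            chrom: sorted(entries) for chrom, entries in tss_by_chrom.items()
        }

    def _hit(self, trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
        tree = trees.get(chrom)
        return bool(tree is not None and tree.overlap(pos, pos + 1))

    def category_at(self, chrom: str, pos: int) -> str:
        if self._hit(self._promoter, chrom, pos):
            return "promoter"
        if self._hit(self._tts, chrom, pos):
            return "TTS"
        if self._hit(self._exon, chrom, pos):
            return "exon"
        if self._hit(self._body, chrom, pos):
            return "intron"
        return "intergenic"

    def nearest_gene(self, chrom: str, pos: int) -> GeneModel | None:
        """Gene whose TSS is closest to ``pos`` (ties: smallest gene_id)."""
        entries = self._tss_sorted.get(chrom)
        if not entries:
            return None
        idx = bisect_left(entries, (pos,))
        best: tuple[int, str] | None = None
        for j in (idx - 1, idx, idx + 1):
            if 0 <= j < len(entries):
                tss, gid = entries[j]
                cand = (abs(pos - tss), gid)
                if best is None or cand < best:
                    best = cand
        assert best is not None
        # ties at the same |pos - tss| can only occur at TSS = pos +/- dist;
        # take the lexicographically smallest gene_id among them
        dist = best[0]
        for tss in (pos - dist, pos + dist):
            j = bisect_left(entries, (tss,))
            while j < len(entries) and entries[j][0] == tss:
                if (dist, entries[j][1]) < best:
                    best = (dist, entries[j][1])
                j += 1
        return self._by_id[best[1]]


def annotate_peak(
    peak: GenomicInterval,
    index: GeneIndex,
    cfg: AnnotationConfig | None = None,
) -> AnnotatedPeak:
    """Classify one peak by its center and attach the nearest gene."""
    if cfg is not None and cfg != index.cfg:
        index = GeneIndex(index.genes, cfg)
    c = peak.center
    category = index.category_at(peak.chrom, c)
    gene = index.nearest_gene(peak.chrom, c)
    return AnnotatedPeak(
        interval=peak,
        category=category,
        nearest_gene=gene.gene_id if gene else None,
        tss_distance=gene.signed_tss_distance(c) if gene else None,
    )


def annotate_peaks(
    peaks: Iterable[GenomicInterval],
    genes: Iterable[GeneModel] | GeneIndex,
    cfg: AnnotationConfig | None = None,
) -> list[AnnotatedPeak]:
    if not isinstance(genes, GeneIndex):
        genes = GeneIndex(genes, cfg or AnnotationConfig())
    return [annotate_peak(p, genes) for p in peaks]


def genomic_distribution(annotated: Sequence[AnnotatedPeak]) -> dict[str, float]:
    """Fraction of peaks per category; fractions sum to 1."""
    if not annotated:
        raise UsageError("cannot compute a genomic distribution of zero peaks")
    n = len(annotated)
    return {
        cat: sum(1 for a in annotated if a.category == cat) / n
        for cat in CATEGORIES
    }


# ---------------------------------------------------------------------------
# GTF I/O (gene/exon features, gene_id attribute)
# ---------------------------------------------------------------------------

def _parse_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_gene_models(path) -> list[GeneModel]:
    """Read gene models from GTF (gene and exon features).

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Genes lacking exon rows get a single exon spanning the transcript; when
    exon rows extend beyond the stated gene span, the extreme span is kept.
    """
    spans: dict[str, list] = {}  # gene_id -> [chrom, strand, start, end, exons, has_gene_row]
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise DataFormatError(
                    f"{path}:{lineno}: GTF line has {len(fields)} fields, expected 9"
                )
            chrom, _, feature, start_s, end_s, _, strand, _, attr_s = fields
            if feature not in ("gene", "exon", "transcript"):
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError as exc:
                raise DataFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise DataFormatError(f"{path}:{lineno}: invalid span {start_s}-{end_s}")
            if strand not in ("+", "-"):
                raise DataFormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            gene_id = _parse_attributes(attr_s).get("gene_id")
            if not gene_id:
                raise DataFormatError(f"{path}:{lineno}: missing gene_id attribute")
            rec = spans.get(gene_id)
            if rec is None:
                rec = [chrom, strand, start, end, [], False]
                spans[gene_id] = rec
                order.append(gene_id)
            if rec[0] != chrom or rec[1] != strand:
                raise DataFormatError(
                    f"{path}:{lineno}: gene {gene_id} spans multiple "
                    "chromosomes or strands"
                )
            if feature == "gene":
                if rec[5]:
                    raise DataFormatError(
                        f"{path}:{lineno}: duplicate gene feature for {gene_id!r}"
                    )
                rec[5] = True
            rec[2] = min(rec[2], start)
            rec[3] = max(rec[3], end)
            if feature == "exon":
                rec[4].append((start, end))
    if not spans:
        logger.warning("GTF file %s contains no gene models", path)
    models = []
    for gene_id in order:
        chrom, strand, start, end, exons, _ = spans[gene_id]
        exons = _merge_exons(exons) if exons else [(start, end)]
        models.append(GeneModel(gene_id, chrom, strand, start, end, tuple(exons)))
    return models


def _merge_exons(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    exons = sorted(exons)
    merged = [list(exons[0])]
    for s, e in exons[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def write_gtf(path, genes: Iterable[GeneModel], source: str = "regulink") -> None:
    """Write gene models as GTF (gene + exon rows, 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                "\t".join(
                    (g.chrom, source, "gene", str(g.tx_start + 1), str(g.tx_end),
                     ".", g.strand, ".", attrs)
                )
                + "\n"
            )
            for s, e in g.exons:
                fh.write(
                    "\t".join(
                        (g.chrom, source, "exon", str(s + 1), str(e),
                         ".", g.strand, ".", attrs)
                    )
                    + "\n"
                )


def write_annotation_tsv(path, annotated: Sequence[AnnotatedPeak]) -> None:
    rows = [
        {
            "chrom": a.interval.chrom,
            "start": a.interval.start,
            "end": a.interval.end,
            "name": a.interval.name or ".",
            "category": a.category,
            "nearest_gene": a.nearest_gene or ".",
            "tss_distance": a.tss_distance if a.tss_distance is not None else ".",
            "is_enhancer": str(a.is_enhancer).lower(),
        }
        for a in annotated
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
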