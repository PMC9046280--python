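"""ATAC–RNA integration: peak-to-gene linking and activation/repression calls.

A peak is linked to every gene whose TSS lies within ``max_dist`` (default
50 kb, inclusive) of the peak center. A gene is *activated* when it is linked
to at least one newly accessible ("gained") peak and its expression log2 fold
change strictly exceeds the up threshold (+1 by default); *repressed* when it
is linked to at least one closed ("lost") peak and its log2FC falls strictly
below the down threshold (-1). Genes qualifying for both calls at once are
reported as unchanged with a conflict flag rather than silently resolved.

Gained/lost peak sets are the unique regions of a two-condition partition
(set-theoretic accessibility change, not differential signal testing).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotation import AnnotatedPeak, GeneModel
from .errors import UsageError
from .intervals import GenomicInterval, PeakSet

__all__ = [
    "PeakGeneLink",
    "GeneClassification",
    "link_peaks_to_genes",
    "classify_genes",
    "enhancer_expression_classes",
    "write_classification_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIST = 50_000


@dataclass(frozen=True)
class PeakGeneLink:
    peak: GenomicInterval
    gene_id: str
    distance: int  # |peak center - TSS| in bp


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    label: str  # activated | repressed | unchanged
    log2fc: float
    n_gained_links: int
    n_lost_links: int
    min_distance: int | None
    conflict: bool = False


class _TssIndex:
    def __init__(self, genes: Iterable[GeneModel]):
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        self._sorted = {c: sorted(v) for c, v in by_chrom.items()}

    def within(self, chrom: str, pos: int, max_dist: int) -> list[tuple[int, str]]:
        entries = self._sorted.get(chrom, [])
        lo = bisect_left(entries, (pos - max_dist,))
        hi = bisect_right(entries, (pos + max_dist, "￿"))
        return [(abs(pos - tss), gid) for tss, gid in entries[lo:hi]]


def link_peaks_to_genes(
    peaks: PeakSet | Sequence[GenomicInterval],
    genes: Iterable[GeneModel],
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[PeakGeneLink]:
    """One link per (peak, gene) pair with |peak center - TSS| <= max_dist.

    A peak may link to several genes and a gene to several peaks. Links are
    ordered by peak (chrom, start, end), then gene_id.
    """
    if max_dist < 0:
        raise UsageError(f"max_dist must be >= 0, got {max_dist}")
    index = _TssIndex(genes)
    links = []
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    for peak in ordered:
        for dist, gid in sorted(
            index.within(peak.chrom, peak.center, max_dist),
            key=lambda t: (t[1], t[0]),
        ):
            links.append(PeakGeneLink(peak=peak, gene_id=gid, distance=dist))
    return links


def classify_genes(
    gained: PeakSet | Sequence[GenomicInterval],
    lost: PeakSet | Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    log2fc: pd.Series,
    up_thresh: float = 1.0,
    down_thresh: float = -1.0,
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[GeneClassification]:
    """Call genes activated / repressed / unchanged from accessibility change.

    activated: >= 1 gained-peak link and log2FC > up_thresh (strict);
    repressed: >= 1 lost-peak link and log2FC < down_thresh (strict).
    A gene satisfying both rules is reported unchanged with ``conflict=True``.
    Genes in the fold-change table but absent from the gene models are
    skipped with a warning.
    """
    known = {g.gene_id for g in genes}
    unknown = [g for g in log2fc.index if g not in known]
    if unknown:
        logger.warning(
            "%d genes in the log2FC table are absent from the gene models "
            "and were skipped (first: %s)", len(unknown), unknown[0],
        )
    gained_links: dict[str, list[int]] = {}
    for link in link_peaks_to_genes(gained, genes, max_dist):
        gained_links.setdefault(link.gene_id, []).append(link.distance)
    lost_links: dict[str, list[int]] = {}
    for link in link_peaks_to_genes(lost, genes, max_dist):
        lost_links.setdefault(link.gene_id, []).append(link.distance)

    out = []
    for gene_id in log2fc.index:
        if gene_id not in known:
            continue
        fc = float(log2fc[gene_id])
        n_gained = len(gained_links.get(gene_id, ()))
        n_lost = len(lost_links.get(gene_id, ()))
        act = n_gained > 0 and fc > up_thresh
        rep = n_lost > 0 and fc < down_thresh
        if act and rep:
            label, conflict = "unchanged", True
            logger.warning(
                "gene %s has both gained and lost support; left unchanged",
                gene_id,
            )
        elif act:
            label, conflict = "activated", False
        elif rep:
            label, conflict = "repressed", False
        else:
            label, conflict = "unchanged", False
        dists = gained_links.get(gene_id, []) + lost_links.get(gene_id, [])
        out.append(
            GeneClassification(
                gene_id=gene_id, label=label, log2fc=fc,
                n_gained_links=n_gained, n_lost_links=n_lost,
                min_distance=min(dists) if dists else None, conflict=conflict,
            )
        )
    return out


def enhancer_expression_classes(
    cistrome: Sequence[AnnotatedPeak],
    genes: Sequence[GeneModel],
    log2fc: pd.Series,
    up_thresh: float = 1.0,
    down_thresh: float = -1.0,
    max_dist: int = DEFAULT_MAX_DIST,
) -> dict:
    """Project enhancer-bound peaks onto expression change.

    Restricts the annotated cistrome to enhancer peaks (intronic/intergenic),
    links them to genes, and splits linked genes into ``enhancer_up`` (log2FC
    strictly above ``up_thresh``) and ``enhancer_down`` (strictly below
    ``down_thresh``). Also reports the up/down percentages among linked genes
    with known fold change.
    """
    enhancer_peaks = [a.interval for a in cistrome if a.is_enhancer]
    links = link_peaks_to_genes(enhancer_peaks, genes, max_dist)
    linked_genes = sorted({l.gene_id for l in links})
    up, down = set(), set()
    n_with_fc = 0
    for gid in linked_genes:
        if gid not in log2fc.index:
            continue
        n_with_fc += 1
        fc = float(log2fc[gid])
        if fc > up_thresh:
            up.add(gid)
        elif fc < down_thresh:
            down.add(gid)
    return {
        "enhancer_up": up,
        "enhancer_down": down,
        "n_linked_genes": len(linked_genes),
        "pct_up": 100.0 * len(up) / n_with_fc if n_with_fc else 0.0,
        "pct_down": 100.0 * len(down) / n_with_fc if n_with_fc else 0.0,
    }


def write_classification_tsv(path, classes: Sequence[GeneClassification]) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "class": c.label,
            "log2fc": c.log2fc,
            "n_gained_links": c.n_gained_links,
            "n_lost_links": c.n_lost_links,
            "min_distance": c.min_distance if c.min_distance is not None else ".",
            "conflict": str(c.conflict).lower(),
        }
        for c in classes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
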