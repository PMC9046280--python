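"""Motif scanning in peak-center windows and hypergeometric motif enrichment.

A motif is either an IUPAC consensus string (exact degenerate-code matching)
or a 4 x width probability matrix scored as a log2 likelihood ratio against a
uniform background with a per-motif bit threshold. Scanning covers both
strands; a peak *carries* a motif when its +/- ``flank`` bp window around the
peak center contains at least one hit.

Enrichment of a motif in a target peak set against a background peak set is
the upper-tail cumulative hypergeometric probability of the observed carrier
count, with the population being the union of the two sets. Motifs are ranked
by log p-value, and two ranked conditions can be compared by rank difference
(the "waterfall" comparison): a large positive shift means the motif climbed
the ranking between condition A and condition B.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, UsageError
from .genome import Genome, reverse_complement
from .intervals import GenomicInterval, PeakSet, center_window
from .stats import log_hypergeom_sf

__all__ = [
    "Motif",
    "MotifHit",
    "EnrichmentRow",
    "RankShift",
    "scan",
    "peak_has_motif",
    "enrich_motifs",
    "rank_by_logp",
    "rank_differential",
    "filter_peaks_with_motif",
    "read_motifs",
    "write_motifs",
    "read_enrichment_tsv",
    "write_enrichment_tsv",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Motif:
    """IUPAC consensus or probability-matrix motif.

    ``matrix`` has shape (4, width) with rows A, C, G, T; ``pseudocount`` is
    added to every cell before column renormalization, and matches require a
    log2 likelihood-ratio score of at least ``log_odds_threshold`` bits.
    """

    name: str
    consensus: str | None = None
    matrix: tuple[tuple[float, ...], ...] | None = None
    log_odds_threshold: float = 0.0
    pseudocount: float = 0.001

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.matrix is None):
            raise UsageError(
                f"motif {self.name}: exactly one of consensus or matrix required"
            )
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise DataFormatError(
                    f"motif {self.name}: non-IUPAC codes {sorted(bad)}"
                )
            object.__setattr__(self, "consensus", self.consensus.upper())
        else:
            m = np.asarray(self.matrix, dtype=float)
            if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] == 0:
                raise DataFormatError(
                    f"motif {self.name}: matrix must be 4 x width"
                )

    @property
    def width(self) -> int:
        if self.consensus is not None:
            return len(self.consensus)
        return len(self.matrix[0])

    def _normalized_matrix(self) -> np.ndarray:
        m = np.asarray(self.matrix, dtype=float) + self.pseudocount
        return m / m.sum(axis=0, keepdims=True)


@dataclass(frozen=True)
class MotifHit:
    offset: int
    strand: str
    score: float
    window_id: str | None = None
    chrom: str | None = None


@dataclass(frozen=True)
class EnrichmentRow:
    """One motif's enrichment in target vs. background peaks.

    ``k`` of ``n`` target peaks carry the motif; ``K`` of the ``N`` peaks in
    the combined population do. ``log_p`` is the natural log of the upper-tail
    cumulative hypergeometric probability.
    """

    motif_name: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    log_p: float
    rank: int | None = None


@dataclass(frozen=True)
class RankShift:
    """Rank difference of one motif between two ranked conditions."""

    motif_name: str
    rank_a: int
    rank_b: int

    @property
    def shift(self) -> int:
        """rank_a - rank_b; positive = more enriched in condition B."""
        return self.rank_a - self.rank_b


def _consensus_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in consensus
    )
    return re.compile(f"(?=({body}))")


def _scan_consensus(seq: str, motif: Motif) -> list[tuple[int, str, float]]:
    hits = []
    width = motif.width
    for strand, pattern in (
        ("+", _consensus_regex(motif.consensus)),
        ("-", _consensus_regex(reverse_complement(motif.consensus))),
    ):
        for m in pattern.finditer(seq):
            hits.append((m.start(), strand, float(width)))
    return hits


def _scan_matrix(seq: str, motif: Motif) -> list[tuple[int, str, float]]:
    width = motif.width
    if len(seq) < width:
        return []
    probs = motif._normalized_matrix()
    lods = np.log2(probs / 0.25)  # (4, width)
    idx = np.full(len(seq), -1, dtype=int)
    for base, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    n_pos = len(seq) - width + 1
    offsets = np.arange(n_pos)[:, None] + np.arange(width)[None, :]
    codes = idx[offsets]  # (n_pos, width)
    valid = (codes >= 0).all(axis=1)
    hits = []
    for strand, mat in (("+", lods), ("-", lods[::-1, ::-1])):
        scores = np.where(
            valid,
            mat[np.clip(codes, 0, 3), np.arange(width)[None, :]].sum(axis=1),
            -np.inf,
        )
        for off in np.nonzero(scores >= motif.log_odds_threshold)[0]:
            hits.append((int(off), strand, float(scores[off])))
    return hits


def scan(
    sequence: str,
    motif: Motif,
    window_id: str | None = None,
    chrom: str | None = None,
) -> list[MotifHit]:
    """All motif occurrences on both strands of ``sequence``.

    Hits are ordered by ascending offset with '+' before '-' at equal offset.
    ``N`` bases never match a non-N consensus code and score -inf in matrix
    mode. A sequence shorter than the motif yields no hits.
    """
    seq = sequence.upper()
    raw = (
        _scan_consensus(seq, motif)
        if motif.consensus is not None
        else _scan_matrix(seq, motif)
    )
    raw.sort(key=lambda h: (h[0], h[1]))
    return [
        MotifHit(offset=o, strand=s, score=sc, window_id=window_id, chrom=chrom)
        for o, s, sc in raw
    ]


def _window_sequence(
    peak: GenomicInterval, genome: Genome, flank: int
) -> str:
    win = center_window(peak, flank, genome.length(peak.chrom))
    return genome.fetch(win.chrom, win.start, win.end)


def peak_has_motif(
    peak: GenomicInterval, genome: Genome, motif: Motif, flank: int = 50
) -> bool:
    """True iff the peak's center window contains >= 1 hit on either strand."""
    return bool(scan(_window_sequence(peak, genome, flank), motif))


def enrich_motifs(
    target: PeakSet,
    background: PeakSet,
    motifs: Sequence[Motif],
    genome: Genome,
    flank: int = 50,
) -> list[EnrichmentRow]:
    """Cumulative hypergeometric enrichment of each motif in target peaks.

    The population is the union of target and background peaks (N peaks, K
    carriers); the draw is the target set (n peaks, k carriers); the p-value
    is P(X >= k), computed in log space.
    """
    if len(target) == 0 or len(background) == 0:
        raise UsageError("target and background peak sets must be non-empty")
    target_seqs = [_window_sequence(p, genome, flank) for p in target]
    bg_seqs = [_window_sequence(p, genome, flank) for p in background]
    rows = []
    for motif in motifs:
        k = sum(1 for s in target_seqs if scan(s, motif))
        K = k + sum(1 for s in bg_seqs if scan(s, motif))
        n, N = len(target_seqs), len(target_seqs) + len(bg_seqs)
        log_p = log_hypergeom_sf(k, N, K, n)
        rows.append(
            EnrichmentRow(
                motif_name=motif.name, k=k, n=n, K=K, N=N,
                p_value=float(np.exp(log_p)), log_p=log_p,
            )
        )
    return rows


def rank_by_logp(rows: Sequence[EnrichmentRow]) -> list[EnrichmentRow]:
    """Assign ranks 1..M by ascending log p (ties: motif name lexicographic)."""
    if not rows:
        raise UsageError("cannot rank an empty enrichment table")
    ordered = sorted(rows, key=lambda r: (r.log_p, r.motif_name))
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def rank_differential(
    rows_a: Sequence[EnrichmentRow], rows_b: Sequence[EnrichmentRow]
) -> list[RankShift]:
    """Per-motif rank difference between two ranked conditions.

    Output is sorted by shift descending (largest gain in condition B first),
    ties broken by motif name. Both inputs must be ranked over the same motif
    universe.
    """
    ranks_a = {r.motif_name: r.rank for r in rows_a}
    ranks_b = {r.motif_name: r.rank for r in rows_b}
    if None in ranks_a.values() or None in ranks_b.values():
        raise UsageError("inputs must be ranked (call rank_by_logp first)")
    missing = sorted(set(ranks_a) ^ set(ranks_b))
    if missing:
        raise UsageError(
            f"motif universes differ between conditions: {', '.join(missing)}"
        )
    shifts = [
        RankShift(name, ranks_a[name], ranks_b[name]) for name in ranks_a
    ]
    shifts.sort(key=lambda s: (-s.shift, s.motif_name))
    return shifts


def filter_peaks_with_motif(
    peaks: PeakSet, genome: Genome, motif: Motif, flank: int = 50
) -> PeakSet:
    """Subset of peaks whose center windows contain the motif."""
    kept = [p for p in peaks if peak_has_motif(p, genome, motif, flank)]
    return PeakSet(f"{peaks.label}|{motif.name}", kept)


# ---------------------------------------------------------------------------
# Motif file format: ">name<TAB>consensus_or_MATRIX<TAB>threshold"; matrix
# motifs are followed by one line per position with 4 probabilities (A C G T).
# ---------------------------------------------------------------------------

def read_motifs(path) -> list[Motif]:
    motifs = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i]
        i += 1
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise DataFormatError(
                f"{path}:{i}: expected a '>' header line, got {line!r}"
            )
        parts = line[1:].split("\t")
        if len(parts) < 2:
            raise DataFormatError(f"{path}:{i}: header needs name and body")
        name, body = parts[0], parts[1]
        threshold = float(parts[2]) if len(parts) > 2 else 0.0
        if body != "MATRIX":
            motifs.append(
                Motif(name=name, consensus=body, log_odds_threshold=threshold)
            )
            continue
        cols = []
        while i < len(lines) and lines[i].strip() and not lines[i].startswith(">"):
            vals = lines[i].split()
            if len(vals) != 4:
                raise DataFormatError(
                    f"{path}:{i + 1}: matrix rows need 4 probabilities"
                )
            cols.append([float(v) for v in vals])
            i += 1
        if not cols:
            raise DataFormatError(f"{path}: matrix motif {name} has no rows")
        matrix = tuple(zip(*cols))  # per-position rows -> (4, width)
        motifs.append(
            Motif(name=name, matrix=matrix, log_odds_threshold=threshold)
        )
    return motifs


def write_enrichment_tsv(path, rows: Sequence[EnrichmentRow]) -> None:
    pd.DataFrame(
        [
            {"motif": r.motif_name, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
             "p_value": r.p_value, "log_p": r.log_p,
             "rank": r.rank if r.rank is not None else "."}
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def read_enrichment_tsv(path) -> list[EnrichmentRow]:
    df = pd.read_csv(path, sep="\t")
    required = {"motif", "k", "n", "K", "N", "p_value", "log_p", "rank"}
    if not required.issubset(df.columns):
        raise DataFormatError(
            f"{path}: enrichment table missing columns "
            f"{sorted(required - set(df.columns))}"
        )
    return [
        EnrichmentRow(
            motif_name=str(r.motif), k=int(r.k), n=int(r.n), K=int(r.K),
            N=int(r.N), p_value=float(r.p_value), log_p=float(r.log_p),
            rank=None if str(r.rank) == "." else int(r.rank),
        )
        for r in df.itertuples()
    ]


def write_motifs(path, motifs: Iterable[Motif]) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            if m.consensus is not None:
                fh.write(f">{m.name}\t{m.consensus}\t{m.log_odds_threshold}\n")
            else:
                fh.write(f">{m.name}\tMATRIX\t{m.log_odds_threshold}\n")
                arr = np.asarray(m.matrix)
                for col in arr.T:
                    fh.write(" ".join(f"{v:.3f}" for v in col) + "\n")
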