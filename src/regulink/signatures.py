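"""Gene-signature scoring, cistrome-consensus derivation, and ORA.

A signature is a named gene list. Scores are per-sample sums: in
``zscore_sum`` mode the sum of per-gene z-scores over the signature genes; in
``log2_sum`` mode the sum of log2(FPKM/TPM + 1). Sums (not means) match the
score definitions in common use; a coverage count of signature genes found in
the matrix is always reported, since scores are comparable across matrices
only at equal coverage.

Signature derivation intersects several cistrome-annotated gene sets (the
consensus of the bound genes) and keeps the consensus genes whose expression
log2 fold change strictly exceeds a threshold (default 2).

Over-representation analysis (ORA) is the upper-tail hypergeometric test of a
query gene set against named pathways within a stated universe, with
Benjamini–Hochberg adjustment across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, UsageError
from .expression import ExpressionMatrix, log_transform, zscore_per_gene
from .stats import bh_adjust, log_hypergeom_sf

__all__ = [
    "Signature",
    "ScoreResult",
    "ORAResult",
    "signature_score",
    "derive_signature",
    "ora",
    "read_gmt",
    "read_signature_tsv",
    "write_signature_tsv",
    "write_scores_tsv",
]


@dataclass(frozen=True)
class Signature:
    """A named gene list with derivation provenance."""

    name: str
    gene_ids: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise UsageError(f"signature {self.name!r} has no genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise UsageError(f"signature {self.name!r} has duplicate genes")


@dataclass(frozen=True)
class ScoreResult:
    scores: pd.Series  # sample_id -> score
    mode: str
    n_genes_found: int
    n_genes_missing: int


@dataclass(frozen=True)
class ORAResult:
    pathway: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    p_adjusted: float = field(default=float("nan"), compare=False)


def signature_score(
    m: ExpressionMatrix, sig: Signature, mode: str = "zscore_sum"
) -> ScoreResult:
    """Per-sample signature score.

    ``zscore_sum``: z-transform the matrix per gene and sum the signature
    rows (needs >= 2 samples). ``log2_sum``: sum log2(value + 1) over the
    signature rows of an FPKM/TPM matrix. Signature genes absent from the
    matrix are skipped and counted.
    """
    if mode not in ("zscore_sum", "log2_sum"):
        raise UsageError(f"unknown scoring mode {mode!r}")
    present = [g for g in sig.gene_ids if g in m.values.index]
    if not present:
        raise UsageError(
            f"no gene of signature {sig.name!r} found in the matrix"
        )
    if mode == "zscore_sum":
        transformed = zscore_per_gene(m)
    else:
        if m.unit not in ("fpkm", "tpm"):
            raise UsageError(
                f"log2_sum scoring expects fpkm/tpm values, got {m.unit!r}"
            )
        transformed = log_transform(m)
    scores = transformed.values.loc[present].sum(axis=0)
    scores.name = sig.name
    return ScoreResult(
        scores=scores,
        mode=mode,
        n_genes_found=len(present),
        n_genes_missing=len(sig.gene_ids) - len(present),
    )


def derive_signature(
    bound_gene_sets: Sequence[set[str] | frozenset[str] | Sequence[str]],
    de_log2fc: pd.Series,
    fc_thresh: float = 2.0,
    name: str = "consensus_signature",
) -> Signature:
    """Consensus-of-cistromes signature.

    Intersects all bound-gene sets, then keeps consensus genes whose log2
    fold change strictly exceeds ``fc_thresh``. Genes absent from the
    fold-change table cannot qualify.
    """
    if len(bound_gene_sets) < 2:
        raise UsageError("need at least 2 bound-gene sets to form a consensus")
    if de_log2fc.empty:
        raise UsageError("differential-expression table is empty")
    sets = [frozenset(s) for s in bound_gene_sets]
    consensus = frozenset.intersection(*sets)
    if not consensus:
        sizes = ", ".join(str(len(s)) for s in sets)
        raise UsageError(
            f"empty consensus: the {len(sets)} gene sets (sizes {sizes}) "
            "share no gene"
        )
    kept = sorted(
        g for g in consensus
        if g in de_log2fc.index and float(de_log2fc[g]) > fc_thresh
    )
    if not kept:
        raise UsageError(
            f"no consensus gene exceeds log2FC > {fc_thresh} "
            f"(consensus size {len(consensus)})"
        )
    provenance = (
        f"consensus of {len(sets)} cistrome gene sets "
        f"({len(consensus)} shared genes), filtered at log2FC > {fc_thresh}"
    )
    return Signature(name=name, gene_ids=tuple(kept), provenance=provenance)


def ora(
    query: set[str] | Sequence[str],
    universe: set[str] | Sequence[str],
    pathways: Mapping[str, Sequence[str]],
) -> list[ORAResult]:
    """Hypergeometric over-representation of a query set in named pathways.

    Each pathway is intersected with the universe before testing; p-values
    are BH-adjusted across the tested pathways. Results are sorted by p
    ascending, ties by pathway name.
    """
    query = set(query)
    universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise UsageError(
            f"query genes outside the universe: {', '.join(offenders[:10])}"
        )
    N, n = len(universe), len(query)
    results = []
    for name in sorted(pathways):
        members = set(pathways[name]) & universe
        K = len(members)
        k = len(query & members)
        log_p = log_hypergeom_sf(k, N, K, n)
        results.append(
            ORAResult(pathway=name, k=k, n=n, K=K, N=N,
                      p_value=float(np.exp(log_p)))
        )
    adjusted = bh_adjust([r.p_value for r in results])
    results = [
        ORAResult(pathway=r.pathway, k=r.k, n=r.n, K=r.K, N=r.N,
                  p_value=r.p_value, p_adjusted=float(a))
        for r, a in zip(results, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


# ---------------------------------------------------------------------------
# File formats: GMT pathways and two-column signature TSV
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file (name, description, genes...)."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    ">= 1 gene"
                )
            name = fields[0]
            if name in pathways:
                raise DataFormatError(
                    f"{path}:{lineno}: duplicate gene set {name!r}"
                )
            pathways[name] = [g for g in fields[2:] if g]
    return pathways


def read_signature_tsv(path) -> list[Signature]:
    """Two-column TSV (set_name, gene_id) -> one Signature per set name."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
    return [
        Signature(name=str(name), gene_ids=tuple(group["gene"].astype(str)))
        for name, group in df.groupby("set", sort=True)
    ]


def write_signature_tsv(path, sig: Signature) -> None:
    with open(path, "w") as fh:
        for g in sig.gene_ids:
            fh.write(f"{sig.name}\t{g}\n")


def write_scores_tsv(path, result: ScoreResult) -> None:
    df = pd.DataFrame(
        {
            "sample_id": result.scores.index,
            "score": result.scores.values,
            "n_genes_found": result.n_genes_found,
        }
    )
    df.to_csv(path, sep="\t", index=False)
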