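"""Seeded synthetic study generator with machine-readable planted truth.

The generator emulates the inputs of a multi-condition chromatin-accessibility
study at desk scale: a miniature random genome with non-overlapping gene
models, per-condition peak sets built from *loci* that are either shared by
all conditions or unique to one (realized with small jitter so the fractional
overlap rule is exercised), transcription-factor motif occurrences planted
into peak-center windows at configured per-group carrier rates, and a
negative-binomial count matrix with planted size factors and planted
activated/repressed genes whose gained/lost peaks sit within linking distance
of their TSS.

Two properties make the truth tables exact rather than approximate:

* motif instances are written into the genome sequence inside carrier
  windows, and chance occurrences of non-carried motifs inside any peak
  window are re-randomized away ("scrubbed"), so the carrier flag table is
  bit-exact against a scan of the emitted FASTA;
* every random draw comes from a named substream of the single config seed,
  so artifacts are bytewise reproducible and partial regeneration is stable.

The last condition in ``conditions`` plays the role of the perturbed state:
its unique peaks are the gained regions and carry the planted activated
genes; the first condition's unique peaks are the lost regions with the
repressed genes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel, write_gtf
from .errors import UsageError
from .expression import ExpressionMatrix, write_matrix_tsv, write_log2fc_tsv
from .genome import Genome
from .intervals import GenomicInterval, PeakSet, write_narrowpeak
from .motifs import IUPAC, Motif, scan

__all__ = [
    "SimulationConfig",
    "PeakSimulation",
    "SimulatedStudy",
    "DEFAULT_MOTIF_CONSENSUS",
    "simulate_genome",
    "assign_gene_classes",
    "simulate_peaks",
    "simulate_expression",
    "simulate_signature_matrix",
    "simulate_study",
    "noisy_log2fc",
    "write_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# plausible consensus strings for factors recurrent in prostate/NE biology;
# the E-box CAGCTG is the canonical ASCL1 core
DEFAULT_MOTIF_CONSENSUS: dict[str, str] = {
    "ASCL1_EBOX": "CAGCTG",
    "NEUROD1_EBOX": "CATCTG",
    "FOXA1": "TGTTTAC",
    "ARE": "AGAACANNNTGTTCT",
    "GATA": "WGATAR",
    "KLF": "GGGGNGGGG",
    "OCT": "ATGCAAAT",
    "NFI": "TTGGCA",
    "SOX2": "CATTGTT",
    "CTCF": "CCACNAGGTGGCAG",
}


def _default_rates(conditions: Sequence[str]) -> dict[str, dict[str, float]]:
    rates = {name: {"default": 0.05} for name in DEFAULT_MOTIF_CONSENSUS}
    rates["ASCL1_EBOX"] = {"default": 0.05, f"unique_{conditions[-1]}": 0.6}
    return rates


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; round-trips through YAML losslessly."""

    seed: int = 0
    # genome / gene models
    n_chroms: int = 2
    chrom_length: int = 250_000
    n_genes: int = 40
    gene_length_min: int = 1000
    gene_length_max: int = 3000
    gene_gap_min: int = 500
    gene_gap_max: int = 2000
    # peak design
    conditions: tuple[str, ...] = ("baseline", "treated")
    n_shared: int = 60
    n_unique: tuple[int, ...] = (30, 30)
    peak_width_min: int = 200
    peak_width_max: int = 600
    peak_gap: int = 200
    flank: int = 50
    motif_consensus: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_CONSENSUS)
    )
    motif_carrier_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    # expression
    n_activated: int = 8
    n_repressed: int = 8
    planted_log2fc: float = 2.0
    link_max_dist: int = 50_000
    n_samples: tuple[int, ...] = (3, 3)
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    size_factors: tuple[float, ...] | None = None
    # signature-scoring matrix
    signature_size: int = 50
    n_score_samples: int = 20
    n_signature_positive: int = 10
    signature_shift_sd: float = 1.5

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.n_unique = tuple(int(x) for x in self.n_unique)
        self.n_samples = tuple(int(x) for x in self.n_samples)
        if self.size_factors is not None:
            self.size_factors = tuple(float(x) for x in self.size_factors)
        if len(self.conditions) < 2:
            raise UsageError("need at least 2 conditions")
        if len(self.n_unique) != len(self.conditions):
            raise UsageError("n_unique must align with conditions")
        if len(self.n_samples) != len(self.conditions):
            raise UsageError("n_samples must align with conditions")
        if not self.motif_carrier_rates:
            self.motif_carrier_rates = _default_rates(self.conditions)
        for name, groups in self.motif_carrier_rates.items():
            if name not in self.motif_consensus:
                raise UsageError(f"carrier rate for unknown motif {name!r}")
            for rate in groups.values():
                if not (0.0 <= rate <= 1.0):
                    raise UsageError(f"carrier rate {rate} outside [0, 1]")
        for attr in ("n_shared", "n_genes", "n_activated", "n_repressed"):
            if getattr(self, attr) < 0:
                raise UsageError(f"{attr} must be >= 0")
        if self.n_activated > self.n_unique[-1]:
            raise UsageError(
                "n_activated exceeds the unique peak budget of the last condition"
            )
        if self.n_repressed > self.n_unique[0]:
            raise UsageError(
                "n_repressed exceeds the unique peak budget of the first condition"
            )
        if self.n_activated + self.n_repressed > self.n_genes:
            raise UsageError("more planted gene classes than genes")
        if self.size_factors is not None and len(self.size_factors) != sum(
            self.n_samples
        ):
            raise UsageError("size_factors must have one entry per sample")
        if self.n_signature_positive > self.n_score_samples:
            raise UsageError("more signature-positive samples than samples")

    @property
    def motifs(self) -> list[Motif]:
        return [
            Motif(name=name, consensus=cons)
            for name, cons in sorted(self.motif_consensus.items())
        ]

    def carrier_rate(self, motif_name: str, group: str) -> float:
        groups = self.motif_carrier_rates.get(motif_name, {})
        return float(groups.get(group, groups.get("default", 0.0)))

    # -- config file round-trip -------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["n_unique"] = list(self.n_unique)
        d["n_samples"] = list(self.n_samples)
        if self.size_factors is not None:
            d["size_factors"] = list(self.size_factors)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stream(cfg_seed: int, key: int) -> np.random.Generator:
    # one named substream per artifact kind keeps partial regeneration stable
    return np.random.default_rng([key, cfg_seed])


_GENOME_STREAM, _PEAK_STREAM, _EXPR_STREAM, _SCORE_STREAM, _CLASS_STREAM = range(5)


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def simulate_genome(cfg: SimulationConfig) -> tuple[Genome, list[GeneModel]]:
    """Uniform-background genome plus non-overlapping multi-exon genes."""
    rng = _stream(cfg.seed, _GENOME_STREAM)
    seqs = {}
    for i in range(cfg.n_chroms):
        arr = rng.choice(_BASES, size=cfg.chrom_length)
        seqs[f"chr{i + 1}"] = arr.tobytes().decode()
    genes: list[GeneModel] = []
    remaining = cfg.n_genes
    gid = 0
    for chrom in seqs:
        pos = int(rng.integers(cfg.gene_gap_min, cfg.gene_gap_max + 1))
        while remaining > 0:
            length = int(rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1))
            if pos + length >= cfg.chrom_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            cuts = np.sort(
                rng.choice(
                    np.arange(pos + 1, pos + length - 1),
                    size=2 * n_exons - 2,
                    replace=False,
                )
            )
            bounds = [pos, *cuts.tolist(), pos + length]
            exons = tuple(
                (int(bounds[2 * j]), int(bounds[2 * j + 1]))
                for j in range(n_exons)
            )
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}", chrom=chrom, strand=strand,
                    tx_start=pos, tx_end=pos + length, exons=exons,
                )
            )
            remaining -= 1
            pos += length + int(
                rng.integers(cfg.gene_gap_min, cfg.gene_gap_max + 1)
            )
        if remaining == 0:
            break
    if remaining > 0:
        raise UsageError(
            f"could not place {cfg.n_genes} genes on {cfg.n_chroms} x "
            f"{cfg.chrom_length} bp; increase chrom_length or n_chroms"
        )
    return Genome(seqs), genes


def assign_gene_classes(
    cfg: SimulationConfig, genes: Sequence[GeneModel]
) -> dict[str, str]:
    """Randomly designate activated / repressed genes (all others null)."""
    rng = _stream(cfg.seed, _CLASS_STREAM)
    ids = [g.gene_id for g in genes]
    chosen = rng.choice(
        len(ids), size=cfg.n_activated + cfg.n_repressed, replace=False
    )
    classes = {gid: "null" for gid in ids}
    for j in chosen[: cfg.n_activated]:
        classes[ids[int(j)]] = "activated"
    for j in chosen[cfg.n_activated:]:
        classes[ids[int(j)]] = "repressed"
    return classes


# ---------------------------------------------------------------------------
# peaks with planted motif truth
# ---------------------------------------------------------------------------

@dataclass
class PeakSimulation:
    genome: Genome            # sequence after motif planting/scrubbing
    peak_sets: dict[str, PeakSet]
    loci: pd.DataFrame        # locus_id, group, chrom, summit, width, target_gene
    carriers: pd.DataFrame    # index locus_id, one boolean column per motif


class _Occupancy:
    """Per-chromosome occupied spans for rejection-sampled placement."""

    def __init__(self) -> None:
        self._spans: dict[str, list[tuple[int, int]]] = {}

    def try_claim(self, chrom: str, start: int, end: int) -> bool:
        spans = self._spans.setdefault(chrom, [])
        for s, e in spans:
            if start < e and s < end:
                return False
        spans.append((start, end))
        return True


def _sample_instance(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        code if len(IUPAC[code]) == 1
        else IUPAC[code][int(rng.integers(len(IUPAC[code])))]
        for code in consensus
    )


def simulate_peaks(
    cfg: SimulationConfig,
    genome: Genome,
    genes: Sequence[GeneModel],
    gene_classes: Mapping[str, str] | None = None,
) -> PeakSimulation:
    """Place shared/unique peak loci and plant motif occurrences.

    Loci are mutually disjoint with at least ``peak_gap`` bp between them, so
    realizations of different loci can never satisfy the overlap rule while
    realizations of the same shared locus always do (jitter is bounded by a
    tenth of the width). Activated genes get a gained locus (unique to the
    last condition) within linking distance of their TSS; repressed genes a
    lost locus (unique to the first condition).
    """
    rng = _stream(cfg.seed, _PEAK_STREAM)
    gene_classes = gene_classes or {}
    by_id = {g.gene_id: g for g in genes}
    chroms = list(genome.chroms())
    occupancy = _Occupancy()

    # locus specs: (group, target_gene_or_None), planted gene loci first
    specs: list[tuple[str, str | None]] = []
    lost_group = f"unique_{cfg.conditions[0]}"
    gained_group = f"unique_{cfg.conditions[-1]}"
    activated = sorted(g for g, c in gene_classes.items() if c == "activated")
    repressed = sorted(g for g, c in gene_classes.items() if c == "repressed")
    specs += [(gained_group, g) for g in activated]
    specs += [(lost_group, g) for g in repressed]
    for cond, n_u in zip(cfg.conditions, cfg.n_unique):
        group = f"unique_{cond}"
        already = sum(1 for g, _ in specs if g == group)
        specs += [(group, None)] * (n_u - already)
    specs += [("shared", None)] * cfg.n_shared

    loci_rows = []
    carrier_rows = {}
    motifs = cfg.motifs
    seqs = {c: bytearray(genome.sequence(c).encode()) for c in chroms}

    for idx, (group, target_gene) in enumerate(specs):
        width = int(rng.integers(cfg.peak_width_min, cfg.peak_width_max + 1))
        placed = False
        for _ in range(1000):
            if target_gene is not None:
                g = by_id[target_gene]
                lim = max(1, int(0.8 * cfg.link_max_dist))
                chrom = g.chrom
                center = g.tss + int(rng.integers(-lim, lim + 1))
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                center = int(
                    rng.integers(cfg.peak_gap + width,
                                 cfg.chrom_length - cfg.peak_gap - width)
                )
            start = center - width // 2
            end = start + width
            if start < cfg.peak_gap or end > cfg.chrom_length - cfg.peak_gap:
                continue
            if occupancy.try_claim(chrom, start - cfg.peak_gap, end + cfg.peak_gap):
                placed = True
                break
        if not placed:
            raise UsageError(
                "could not place all peak loci; the genome is too crowded "
                "(increase chrom_length or reduce peak counts)"
            )
        locus_id = f"L{idx:05d}"
        summit = start + width // 2
        loci_rows.append(
            {"locus_id": locus_id, "group": group, "chrom": chrom,
             "start": start, "end": end, "summit": summit, "width": width,
             "target_gene": target_gene or "."}
        )
        carrier_rows[locus_id] = {
            m.name: bool(rng.random() < cfg.carrier_rate(m.name, group))
            for m in motifs
        }

    loci = pd.DataFrame(loci_rows).set_index("locus_id", drop=False)
    carriers = pd.DataFrame.from_dict(carrier_rows, orient="index").loc[
        loci.index, [m.name for m in motifs]
    ]

    _plant_and_scrub(cfg, seqs, loci, carriers, motifs, rng)
    planted_genome = Genome(
        {c: seqs[c].decode() for c in chroms}
    )

    # realizations per condition, jittered within the locus
    peak_sets = {}
    for cond in cfg.conditions:
        intervals = []
        for row in loci.itertuples():
            if row.group != "shared" and row.group != f"unique_{cond}":
                continue
            jit = row.width // 10
            dstart = int(rng.integers(-jit, jit + 1))
            dend = int(rng.integers(-jit, jit + 1))
            start, end = row.start + dstart, row.end + dend
            intervals.append(
                GenomicInterval(
                    chrom=row.chrom, start=start, end=end,
                    name=f"{row.locus_id}_{cond}",
                    score=float(rng.integers(100, 1000)),
                    strand=".",
                    summit_offset=row.summit - start,
                    extra=("0", "-1", "-1"),
                )
            )
        peak_sets[cond] = PeakSet(cond, intervals)

    return PeakSimulation(
        genome=planted_genome, peak_sets=peak_sets, loci=loci, carriers=carriers
    )


def _plant_and_scrub(
    cfg: SimulationConfig,
    seqs: dict[str, bytearray],
    loci: pd.DataFrame,
    carriers: pd.DataFrame,
    motifs: Sequence[Motif],
    rng: np.random.Generator,
) -> None:
    """Write carried motif instances into windows; erase chance hits of
    non-carried motifs so the carrier table is exact."""
    by_name = {m.name: m for m in motifs}
    for row in loci.itertuples():
        flags = carriers.loc[row.locus_id]
        carried = [by_name[n] for n in carriers.columns if flags[n]]
        absent = [by_name[n] for n in carriers.columns if not flags[n]]
        ok = False
        for _ in range(25):
            if _plant_locus_once(cfg, seqs[row.chrom], row.summit,
                                 carried, absent, rng):
                ok = True
                break
        if not ok:
            raise UsageError(
                f"could not realize the motif design in locus "
                f"{row.locus_id}; reduce carrier rates or motif count"
            )


def _plant_locus_once(cfg, seq, summit, carried, absent, rng) -> bool:
    """One attempt at planting/scrubbing one window; False = retry."""
    win_lo, win_hi = summit - cfg.flank, summit + cfg.flank
    original = bytes(seq[win_lo:win_hi])
    protected: set[int] = set()
    for motif in carried:
        instance = _sample_instance(motif.consensus, rng)
        w = len(instance)
        slot = None
        for _ in range(200):
            off = int(rng.integers(win_lo, win_hi - w + 1))
            # 2 bp spacing so any hit crossing two planted slots keeps at
            # least one rewritable (unprotected) position
            if not protected.intersection(range(off - 2, off + w + 2)):
                slot = off
                break
        if slot is None:
            seq[win_lo:win_hi] = original
            return False
        seq[slot:slot + w] = instance.encode()
        protected.update(range(slot, slot + w))
    for _ in range(300):
        window = seq[win_lo:win_hi].decode()
        dirty: list[tuple[int, int]] = []
        for motif in absent:
            for hit in scan(window, motif):
                dirty.append((win_lo + hit.offset,
                              win_lo + hit.offset + motif.width))
        if not dirty:
            return True
        for s, e in dirty:
            free = [p for p in range(s, e) if p not in protected]
            if not free:
                # a planted instance embeds a non-carried motif: re-draw
                seq[win_lo:win_hi] = original
                return False
            for p in free:
                seq[p] = int(rng.choice(_BASES))
    seq[win_lo:win_hi] = original
    return False


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    gene_classes: Mapping[str, str],
) -> tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """Negative-binomial counts with planted size factors and fold changes.

    Returns the raw count matrix, the planted per-gene log2 fold change
    (last condition over the others), and the planted per-sample size
    factors. NB variance is mean + dispersion * mean^2; dispersion 0 gives
    Poisson counts.
    """
    rng = _stream(cfg.seed, _EXPR_STREAM)
    sample_ids, cond_of = [], []
    for cond, n_s in zip(cfg.conditions, cfg.n_samples):
        for j in range(n_s):
            sample_ids.append(f"{cond}_r{j + 1}")
            cond_of.append(cond)
    factors = (
        np.ones(len(sample_ids))
        if cfg.size_factors is None
        else np.asarray(cfg.size_factors, dtype=float)
    )
    gene_ids = [g.gene_id for g in genes]
    base = rng.lognormal(mean=np.log(cfg.nb_mean), sigma=1.0, size=len(gene_ids))
    fc = pd.Series(0.0, index=gene_ids, name="log2fc")
    for gid in gene_ids:
        if gene_classes.get(gid) == "activated":
            fc[gid] = cfg.planted_log2fc
        elif gene_classes.get(gid) == "repressed":
            fc[gid] = -cfg.planted_log2fc
    perturbed = cfg.conditions[-1]
    means = np.empty((len(gene_ids), len(sample_ids)))
    for j, (sid, cond) in enumerate(zip(sample_ids, cond_of)):
        m = base * (2.0 ** fc.values if cond == perturbed else 1.0)
        means[:, j] = m * factors[j]
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + means)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(means)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), unit="counts"
    )
    sf = pd.Series(factors, index=sample_ids, name="size_factor")
    return matrix, fc, sf


def simulate_signature_matrix(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """FPKM-like matrix with signature-positive samples shifted upward.

    Gene g has baseline Normal(mu_g, sigma_g) expression (clipped at 0);
    signature-positive samples get +shift * sigma_g on every signature gene.
    Returns the matrix, the signature gene ids and the positive sample ids.
    """
    rng = _stream(cfg.seed, _SCORE_STREAM)
    n_genes = max(cfg.n_genes, cfg.signature_size)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_score_samples)]
    mu = rng.uniform(5.0, 50.0, size=n_genes)
    sigma = rng.uniform(0.5, 2.0, size=n_genes)
    sig_idx = rng.choice(n_genes, size=cfg.signature_size, replace=False)
    pos_idx = rng.choice(
        cfg.n_score_samples, size=cfg.n_signature_positive, replace=False
    )
    vals = rng.normal(mu[:, None], sigma[:, None],
                      size=(n_genes, cfg.n_score_samples))
    for j in pos_idx:
        vals[sig_idx, j] += cfg.signature_shift_sd * sigma[sig_idx]
    vals = np.clip(vals, 0.0, None)
    matrix = ExpressionMatrix(
        pd.DataFrame(vals, index=gene_ids, columns=sample_ids), unit="fpkm"
    )
    return (
        matrix,
        sorted(gene_ids[int(i)] for i in sig_idx),
        sorted(sample_ids[int(i)] for i in pos_idx),
    )


def noisy_log2fc(
    truth: pd.Series, sd: float, rng: np.random.Generator
) -> pd.Series:
    """Planted log2 fold changes with Gaussian measurement noise."""
    noisy = truth + rng.normal(0.0, sd, size=len(truth))
    noisy.name = "log2fc"
    return noisy


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: Genome
    genes: list[GeneModel]
    gene_classes: dict[str, str]
    peak_sets: dict[str, PeakSet]
    loci: pd.DataFrame
    carriers: pd.DataFrame
    counts: ExpressionMatrix
    truth_log2fc: pd.Series
    truth_size_factors: pd.Series

    @property
    def gained(self) -> PeakSet:
        """Peaks unique (by design) to the perturbed condition."""
        return self.group_peaks(f"unique_{self.config.conditions[-1]}")

    @property
    def lost(self) -> PeakSet:
        return self.group_peaks(f"unique_{self.config.conditions[0]}")

    def group_peaks(self, group: str, condition: str | None = None) -> PeakSet:
        """Realized peaks of one design group.

        Unique groups live in their own condition; for the shared group a
        ``condition`` must be named (default: the first condition).
        """
        if group.startswith("unique_"):
            cond = group.removeprefix("unique_")
        else:
            cond = condition or self.config.conditions[0]
        keep = set(self.loci.loc[self.loci.group == group, "locus_id"])
        return PeakSet(
            f"{group}:{cond}" if group == "shared" else group,
            [p for p in self.peak_sets[cond] if p.name.rsplit("_", 1)[0] in keep],
        )


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: genome, genes, peaks, motifs, expression."""
    genome, genes = simulate_genome(cfg)
    gene_classes = assign_gene_classes(cfg, genes)
    peaks = simulate_peaks(cfg, genome, genes, gene_classes)
    counts, fc, sf = simulate_expression(cfg, genes, gene_classes)
    return SimulatedStudy(
        config=cfg, genome=peaks.genome, genes=genes,
        gene_classes=gene_classes, peak_sets=peaks.peak_sets,
        loci=peaks.loci, carriers=peaks.carriers,
        counts=counts, truth_log2fc=fc, truth_size_factors=sf,
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Emit FASTA, GTF, narrowPeak per condition, counts and truth TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.config.to_yaml(out / "config.yaml")
    study.genome.to_fasta(out / "genome.fa")
    write_gtf(out / "genes.gtf", study.genes)
    for cond, ps in study.peak_sets.items():
        write_narrowpeak(out / f"peaks_{cond}.narrowPeak", ps.intervals)
    write_matrix_tsv(out / "counts.tsv", study.counts)
    write_log2fc_tsv(out / "truth_log2fc.tsv", study.truth_log2fc)
    study.loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
    study.carriers.to_csv(out / "truth_carriers.tsv", sep="\t",
                          index_label="locus_id")
    pd.DataFrame(
        {"gene_id": list(study.gene_classes),
         "class": list(study.gene_classes.values())}
    ).to_csv(out / "truth_gene_classes.tsv", sep="\t", index=False)
    study.truth_size_factors.to_csv(
        out / "truth_size_factors.tsv", sep="\t", index_label="sample_id"
    )
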