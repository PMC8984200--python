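"""Synthetic inputs for every pipeline stage.

Four generators, all seeded and bit-reproducible:

* pooled allele counts for two populations with a neutral background
  differentiation level and optional planted high-F_ST sweep regions
  (Balding-Nichols Beta model for population frequencies, binomial read
  sampling at the pool depth);
* a multi-generation half-sib pedigree with additive breeding values and
  ordinal 4-level phenotypes generated from a latent Gaussian score with
  a cage-tier fixed effect;
* FASTQ files with exact, disjoint counts of adapter-bearing, N-rich and
  low-quality reads, so downstream filter tallies are deterministic;
* a non-overlapping gene annotation plus GMT gene sets.

Defaults mirror the study design being emulated: pools of 36 and 48
individuals sequenced at 5x per individual (pool depths 180x and 240x),
and latent-scale variance components sigma2_a = 0.043, sigma2_e = 0.120
(heritability ~ 0.26).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_ADAPTER = "AGATCGGAAGAGC"  # Illumina TruSeq stem

#: cage tiers, bottom to top
CAGE_TIERS = ("down", "middle", "up")


@dataclass
class SimConfig:
    """Design of a two-pool Pool-Seq experiment.

    ``sweep_regions`` is a list of ``(chrom, start, end, sweep_fst)``
    tuples (0-based half-open bp); everywhere else differentiation is
    ``background_fst``.  Per-pool depth is fixed at
    ``pool_size * per_individual_depth`` unless ``poisson_depth`` is set,
    in which case it is Poisson with that mean.
    """

    n_chrom: int = 1
    chrom_length: int = 10_000_000
    n_snps: int = 10_000
    background_fst: float = 0.02
    sweep_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    pool_sizes: tuple[int, int] = (36, 48)
    per_individual_depth: int = 5
    poisson_depth: bool = False
    seed: int = 0

    @property
    def pool_depths(self) -> tuple[int, int]:
        return (
            self.pool_sizes[0] * self.per_individual_depth,
            self.pool_sizes[1] * self.per_individual_depth,
        )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def validate(self) -> None:
        if self.n_chrom < 1 or self.chrom_length < 1 or self.n_snps < 0:
            raise ValueError("n_chrom, chrom_length must be >= 1 and n_snps >= 0")
        if not 0.0 <= self.background_fst < 1.0:
            raise ValueError("background_fst must lie in [0, 1)")
        names = set(self.chrom_names())
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, f in self.sweep_regions:
            if chrom not in names:
                raise ValueError(f"sweep region on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_length):
                raise ValueError(f"sweep region {chrom}:{start}-{end} outside chromosome bounds")
            if not f > self.background_fst:
                raise ValueError("sweep_fst must exceed background_fst")
            if not f < 1.0:
                raise ValueError("sweep_fst must be < 1")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping sweep regions on {chrom}: "
                        f"[{s1}, {e1}) and [{s2}, {e2})"
                    )


@dataclass
class QuantGenConfig:
    """Pedigree + ordinal-phenotype simulation design.

    Founders are split into sires and dams; each later generation mates
    every dam of the previous generation to a random sire of that
    generation, producing ``family_size`` offspring per dam (paternal
    half-sib families).  Breeding values follow the additive infinitesimal
    model: founders ~ N(0, sigma2_a), offspring = mid-parent +
    N(0, sigma2_a / 2) Mendelian sampling (inbreeding ignored).  The
    latent score is mu + cage effect + breeding value + N(0, sigma2_e);
    the observed level is 1 + the number of ``thresholds`` below it.
    """

    n_founders: int = 200
    n_generations: int = 2
    family_size: int = 3
    sigma2_a: float = 0.043
    sigma2_e: float = 0.120
    mu: float = 0.0
    cage_effects: tuple[float, float, float] = (0.15, 0.0, 0.0)  # down/middle/up
    thresholds: tuple[float, float, float] = (-0.05, 0.35, 0.69)
    sire_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.n_founders < 2 or self.family_size < 1:
            raise ValueError("need >= 2 founders and family_size >= 1")
        if self.sigma2_a < 0 or self.sigma2_e <= 0:
            raise ValueError("sigma2_a must be >= 0 and sigma2_e > 0")
        if list(self.thresholds) != sorted(self.thresholds) or len(set(self.thresholds)) != 3:
            raise ValueError("thresholds must be strictly increasing")
        if not 0.0 < self.sire_fraction < 1.0:
            raise ValueError("sire_fraction must lie in (0, 1)")

    @property
    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else float("nan")


def simulate_pool_counts(cfg: SimConfig) -> pd.DataFrame:
    """Draw a two-pool allele-count table under the Balding-Nichols model.

    Per SNP: an ancestral frequency p ~ U[0.05, 0.95]; each population's
    frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) with F the site's target
    differentiation (populations identical when F = 0); alt read counts
    are Binomial(pool depth, frequency).  Output sorted by (chrom, pos),
    positions 1-based.  Monomorphic draws are retained; the F_ST stage
    decides their fate.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = cfg.chrom_names()

    # spread SNPs across chromosomes as evenly as possible
    per = np.full(cfg.n_chrom, cfg.n_snps // cfg.n_chrom)
    per[: cfg.n_snps % cfg.n_chrom] += 1

    frames = []
    for chrom, n in zip(names, per):
        if n == 0:
            continue
        pos = np.sort(rng.choice(cfg.chrom_length, size=n, replace=False)) + 1
        f = np.full(n, cfg.background_fst)
        for rchrom, start, end, sweep_f in cfg.sweep_regions:
            if rchrom == chrom:
                in_region = (pos - 1 >= start) & (pos - 1 < end)
                f[in_region] = sweep_f
        p_anc = rng.uniform(0.05, 0.95, size=n)
        freqs = np.empty((n, 2))
        neutral = f == 0.0
        freqs[neutral, 0] = freqs[neutral, 1] = p_anc[neutral]
        drift = ~neutral
        if drift.any():
            alpha = p_anc[drift] * (1.0 - f[drift]) / f[drift]
            beta = (1.0 - p_anc[drift]) * (1.0 - f[drift]) / f[drift]
            freqs[drift, 0] = rng.beta(alpha, beta)
            freqs[drift, 1] = rng.beta(alpha, beta)
        depths = np.empty((n, 2), dtype=np.int64)
        for k, d in enumerate(cfg.pool_depths):
            depths[:, k] = rng.poisson(d, size=n) if cfg.poisson_depth else d
        alt = rng.binomial(depths, freqs)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref_count_1": depths[:, 0] - alt[:, 0],
                    "alt_count_1": alt[:, 0],
                    "ref_count_2": depths[:, 1] - alt[:, 1],
                    "alt_count_2": alt[:, 1],
                    "true_fst": f,
                    "true_p1": freqs[:, 0],
                    "true_p2": freqs[:, 1],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "chrom", "pos", "ref_count_1", "alt_count_1",
                "ref_count_2", "alt_count_2", "true_fst", "true_p1", "true_p2",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def simulate_pedigree_phenotypes(
    cfg: QuantGenConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a half-sib pedigree and ordinal phenotypes with known h2.

    Returns ``(pedigree, phenotypes)``: pedigree columns ``id, sire, dam``
    (0 = unknown, parents precede offspring); phenotype columns
    ``id, cage_tier, kb_level`` plus the simulation truth ``breeding_value``
    and ``latent`` for parameter-recovery checks.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    sd_a = np.sqrt(cfg.sigma2_a)
    ids = list(range(1, cfg.n_founders + 1))
    sire_col = [0] * cfg.n_founders
    dam_col = [0] * cfg.n_founders
    bv = list(rng.normal(0.0, sd_a, size=cfg.n_founders))

    n_sires = max(1, int(round(cfg.sire_fraction * cfg.n_founders)))
    gen_ids = np.array(ids)
    gen_sires = gen_ids[:n_sires]
    gen_dams = gen_ids[n_sires:]

    next_id = cfg.n_founders + 1
    for _ in range(cfg.n_generations - 1):
        if len(gen_dams) == 0 or len(gen_sires) == 0:
            break
        mates = rng.choice(gen_sires, size=len(gen_dams))
        new_ids = []
        for dam, sire in zip(gen_dams, mates):
            mid = 0.5 * (bv[sire - 1] + bv[dam - 1])
            ms = rng.normal(0.0, np.sqrt(cfg.sigma2_a / 2.0), size=cfg.family_size)
            for k in range(cfg.family_size):
                ids.append(next_id)
                sire_col.append(int(sire))
                dam_col.append(int(dam))
                bv.append(mid + ms[k])
                new_ids.append(next_id)
                next_id += 1
        gen_ids = np.array(new_ids)
        k = max(1, int(round(cfg.sire_fraction * len(gen_ids))))
        perm = rng.permutation(gen_ids)
        gen_sires, gen_dams = perm[:k], perm[k:]

    n = len(ids)
    bv_arr = np.asarray(bv)
    tier_idx = rng.integers(0, 3, size=n)
    cage = np.asarray(cfg.cage_effects)[tier_idx]
    latent = cfg.mu + cage + bv_arr + rng.normal(0.0, np.sqrt(cfg.sigma2_e), size=n)
    level = 1 + np.searchsorted(np.asarray(cfg.thresholds), latent, side="left")

    ped = pd.DataFrame({"id": ids, "sire": sire_col, "dam": dam_col})
    phen = pd.DataFrame(
        {
            "id": ids,
            "cage_tier": np.asarray(CAGE_TIERS)[tier_idx],
            "kb_level": level.astype(int),
            "breeding_value": bv_arr,
            "latent": latent,
        }
    )
    return ped, phen


def simulate_fastq(
    n_reads: int,
    read_len: int = 100,
    adapter_fraction: float = 0.0,
    n_fraction: float = 0.0,
    lowq_fraction: float = 0.0,
    seed: int = 0,
    adapter: str = DEFAULT_ADAPTER,
) -> list[tuple[str, str, str]]:
    """Construct FASTQ records with exact, disjoint violator counts.

    Exactly ``round(fraction * n_reads)`` reads carry the adapter as a
    substring, have >10% N bases, or have >50% of bases below Phred 10
    (offset 33), respectively; the three sets are disjoint and their
    membership is shuffled deterministically.  Returns ``(title, seq,
    qual)`` tuples; use :func:`keelscan.io.write_fastq` to serialise.
    """
    for frac in (adapter_fraction, n_fraction, lowq_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads == 0:
        return []
    if read_len < len(adapter):
        raise ValueError(f"read_len {read_len} shorter than adapter ({len(adapter)} bp)")
    n_ad = round(adapter_fraction * n_reads)
    n_n = round(n_fraction * n_reads)
    n_lq = round(lowq_fraction * n_reads)
    if n_ad + n_n + n_lq > n_reads:
        raise ValueError("violator fractions sum to more than 1; sets must be disjoint")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    good_q = chr(33 + 35)  # Phred 35
    bad_q = chr(33 + 5)  # Phred 5

    kinds = np.array(
        ["adapter"] * n_ad
        + ["nrich"] * n_n
        + ["lowq"] * n_lq
        + ["clean"] * (n_reads - n_ad - n_n - n_lq)
    )
    rng.shuffle(kinds)

    records = []
    for i, kind in enumerate(kinds):
        seq = rng.choice(bases, size=read_len)
        qual = [good_q] * read_len
        if kind == "adapter":
            start = int(rng.integers(0, read_len - len(adapter) + 1))
            seq[start : start + len(adapter)] = list(adapter)
        elif kind == "nrich":
            # strictly more than 10% N
            k = int(np.floor(0.10 * read_len)) + 1
            seq[rng.choice(read_len, size=k, replace=False)] = "N"
        elif kind == "lowq":
            # strictly more than 50% of bases below Phred 10
            k = int(np.floor(0.50 * read_len)) + 1
            for j in rng.choice(read_len, size=k, replace=False):
                qual[j] = bad_q
        s = "".join(seq)
        if kind != "adapter" and adapter in s:
            # avoid an accidental adapter hit promoting a read's category
            s = s.replace(adapter, adapter[:-1] + ("C" if adapter[-1] != "C" else "G"))
        records.append((f"read_{i}", s, "".join(qual)))
    return records


def simulate_annotation(
    n_genes: int,
    chrom_lengths: dict[str, int],
    seed: int = 0,
    gene_length: int = 5_000,
    set_sizes: Sequence[int] = (10, 20, 30),
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Place non-overlapping genes and partition a subset into gene sets.

    Genes (fixed length, random strand) are spread across chromosomes in
    proportion to length, with uniformly drawn inter-gene gaps.  Gene sets
    take disjoint slices of a seeded permutation of the gene identifiers.
    Returns a BED-like frame (gene_id, chrom, start, end, strand; 0-based
    half-open) and a ``{set_name: [gene ids]}`` dict.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if sum(set_sizes) > n_genes:
        raise ValueError("gene sets cannot partition more genes than exist")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(n_genes * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-lengths):
        if alloc.sum() >= n_genes:
            break
        alloc[i] += 1
    while alloc.sum() > n_genes:
        alloc[np.argmax(alloc)] -= 1

    rows = []
    gi = 0
    for chrom, n in zip(chroms, alloc):
        if n == 0:
            continue
        free = chrom_lengths[chrom] - n * gene_length
        if free < 0:
            raise ValueError(
                f"{n} genes of {gene_length} bp do not fit on {chrom} "
                f"({chrom_lengths[chrom]} bp) without overlap"
            )
        gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
        start = 0
        for k in range(n):
            start += gaps[k]
            rows.append(
                {
                    "gene_id": f"GENE{gi:05d}",
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(start + gene_length),
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            start += gene_length
            gi += 1
    genes = pd.DataFrame(rows)

    perm = rng.permutation(genes["gene_id"].to_numpy())
    gene_sets = {}
    at = 0
    for k, size in enumerate(set_sizes):
        gene_sets[f"SET{k + 1}"] = sorted(perm[at : at + size].tolist())
        at += size
    return genes, gene_sets
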