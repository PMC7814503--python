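"""Synthetic barley-style genotype/phenotype panels with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a diverse inbred panel with two subpopulations (a proxy for the
2-row / 6-row split), block-wise linkage disequilibrium, winter-survival
percentages scored in multiple field environments with shared and
environment-specific QTLs, and a censored days-to-flowering trait driven
by a two-locus (vernalization-style) epistatic interaction.

Population structure uses a Balding-Nichols-style model: each LD block has
an ancestral allele frequency, and the two subpopulations draw diverged
frequencies from a beta distribution around it, with a single scalar
controlling divergence.  LD within a block comes from copying a template
allele with a per-marker flip probability, which controls r^2 directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, PhenotypeTable, SnpRecord

#: The ten field environments with differential winter survival that the
#: default configuration emulates (two years at five sites).
DEFAULT_ENVIRONMENTS = (
    "MN-14", "MN-15", "OH-14", "OH-15", "AB-14",
    "AB-15", "DE-14", "ID-15", "UK-15", "ES-15",
)


@dataclass(frozen=True)
class QtlSpec:
    """An additive winter-survival QTL.

    ``effect`` is in phenotype units (survival percentage points) per alt
    allele; ``env_mask`` names the environments where the locus is active,
    so loci can be shared, environment-specific, or anything in between.
    """

    snp_index: int
    effect: float
    env_mask: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.env_mask) == 0:
            raise ValueError("env_mask must name at least one environment")
        if not np.isfinite(self.effect):
            raise ValueError("QTL effect must be finite")


@dataclass(frozen=True)
class EpistasisSpec:
    """Two-locus genotype-combination means for the censored DTF trait.

    ``table[i, j]`` is the mean days-to-flowering for dosage ``i`` at the
    first locus (a VRN-H1-style vernalization gene) and dosage ``j`` at the
    second (a VRN-H2-style repressor): late flowering requires functional
    alleles at both, mimicking the classic vernalization two-gene model.
    """

    locus1: int
    locus2: int
    table: tuple = (
        (60.0, 62.0, 64.0),
        (62.0, 120.0, 140.0),
        (64.0, 140.0, 150.0),
    )
    noise_sd: float = 8.0
    censor: int = 154

    def __post_init__(self) -> None:
        tab = np.asarray(self.table, dtype=float)
        if tab.shape != (3, 3):
            raise ValueError("epistasis table must cover all 3x3 dosage pairs")
        if self.censor < tab.max():
            raise ValueError("censor value must be >= the largest table mean")

    def mean_array(self) -> np.ndarray:
        return np.asarray(self.table, dtype=float)


def default_ws_qtls(n_snps: int = 5725, envs=DEFAULT_ENVIRONMENTS) -> list[QtlSpec]:
    """A 15-locus architecture mirroring a winter-hardiness panel: two major
    frost-tolerance loci active in 6/10 environments, two moderate loci in
    two environments, four environment-specific loci, and seven weak loci
    active everywhere (detectable only by pooling environments)."""
    idx = np.linspace(0, n_snps - 1, 17, dtype=int)[1:-1]
    six = tuple(envs[:6])
    qtls = [
        QtlSpec(int(idx[0]), 10.0, six),
        QtlSpec(int(idx[1]), 10.0, six),
        QtlSpec(int(idx[2]), 8.0, tuple(envs[4:6])),
        QtlSpec(int(idx[3]), 8.0, tuple(envs[6:8])),
    ]
    for j in range(4):
        qtls.append(QtlSpec(int(idx[4 + j]), 8.0, (envs[j],)))
    for j in range(7):
        qtls.append(QtlSpec(int(idx[8 + j]), 3.0, tuple(envs)))
    return qtls


@dataclass
class SimConfig:
    """Panel-generator configuration.

    Defaults emulate the study panel: 882 accessions, 5,725 biallelic SNPs
    on 7 chromosomes, a ~60/40 two-subpopulation split, MAF >= 0.05, and
    ten environments with mean survival around 38% (phenotype units are
    percentage points).
    """

    n_accessions: int = 882
    n_snps: int = 5725
    n_chrom: int = 7
    chrom_length_bp: int = 600_000_000
    subpop_proportions: tuple[float, ...] = (0.6, 0.4)
    divergence: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_len: int = 10
    flip_prob: float = 0.05
    missing_rate: float = 0.02
    environments: tuple[str, ...] = DEFAULT_ENVIRONMENTS
    env_intercepts: tuple[float, ...] | None = None
    env_sd: tuple[float, ...] | None = None
    ws_qtls: list[QtlSpec] = field(default_factory=list)
    epistasis: EpistasisSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subpop_proportions) - 1.0) > 1e-9:
            raise ValueError("subpopulation proportions must sum to 1")
        k = len(self.environments)
        if self.env_intercepts is None:
            self.env_intercepts = tuple([38.0] * k)
        if self.env_sd is None:
            self.env_sd = tuple([10.0] * k)
        if len(self.env_intercepts) != k or len(self.env_sd) != k:
            raise ValueError("per-environment parameter length mismatch")
        if any(s < 0 for s in self.env_sd):
            raise ValueError("residual standard deviations must be >= 0")
        if len(self.ws_qtls) > self.n_snps:
            raise ValueError("more causal SNPs requested than n_snps")
        for q in self.ws_qtls:
            if not 0 <= q.snp_index < self.n_snps:
                raise ValueError(f"QTL index {q.snp_index} out of range")
            unknown = set(q.env_mask) - set(self.environments)
            if unknown:
                raise ValueError(f"QTL env_mask names unknown environments {unknown}")


def study_like_config(
    seed: int = 0, n_accessions: int = 882, n_snps: int = 5725
) -> SimConfig:
    """Default study-scale configuration with the 15-locus WS architecture
    and a VRN-style epistatic DTF pair.

    ``n_accessions``/``n_snps`` down-scale the panel while keeping causal
    loci at the same relative map positions.
    """
    cfg = SimConfig(seed=seed, n_accessions=n_accessions, n_snps=n_snps)
    cfg.ws_qtls = default_ws_qtls(cfg.n_snps, cfg.environments)
    m = cfg.n_snps
    cfg.epistasis = EpistasisSpec(locus1=int(m * 0.64), locus2=int(m * 0.52))
    return cfg


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated panel."""

    qtl_snp_ids: list[str]
    effects: list[float]
    env_masks: list[tuple[str, ...]]
    heritability: dict[str, float]
    epistatic_pair: tuple[str, str] | None
    block_index: np.ndarray
    clipped_fraction: dict[str, float]

    def block_of(self, snp_id: str, snp_ids: list[str]) -> int:
        return int(self.block_index[snp_ids.index(snp_id)])


def _simulate_genotypes(cfg: SimConfig, rng: np.random.Generator):
    """Haplotype-pair dosages with block LD and two-subpopulation structure."""
    m, n = cfg.n_snps, cfg.n_accessions
    # chromosome assignment and sorted physical positions
    chrom_of = np.repeat(np.arange(cfg.n_chrom), int(np.ceil(m / cfg.n_chrom)))[:m]
    pos = np.empty(m, dtype=np.int64)
    block_index = np.empty(m, dtype=np.int64)
    next_block = 0
    for c in range(cfg.n_chrom):
        on_c = np.flatnonzero(chrom_of == c)
        pos[on_c] = np.sort(
            rng.integers(1, cfg.chrom_length_bp, size=len(on_c), dtype=np.int64)
        )
        nb = int(np.ceil(len(on_c) / cfg.block_len))
        block_index[on_c] = next_block + np.arange(len(on_c)) // cfg.block_len
        next_block += nb
    n_blocks = next_block

    # subpopulation sizes and per-block diverged allele frequencies
    sizes = np.floor(np.asarray(cfg.subpop_proportions) * n).astype(int)
    sizes[-1] = n - sizes[:-1].sum()
    subpop = np.repeat(np.arange(len(sizes)), sizes)

    lo, hi = cfg.maf_range
    p0 = rng.uniform(lo, hi, size=n_blocks)
    flip = rng.random(n_blocks) < 0.5
    p0 = np.where(flip, 1.0 - p0, p0)
    F = cfg.divergence
    if F > 0:
        a = p0 * (1.0 - F) / F
        b = (1.0 - p0) * (1.0 - F) / F
        p_sub = rng.beta(
            np.tile(a, (len(sizes), 1)), np.tile(b, (len(sizes), 1))
        )  # (n_subpops, n_blocks)
        p_sub = np.clip(p_sub, 0.01, 0.99)
    else:
        p_sub = np.tile(p0, (len(sizes), 1))

    # template-copy haplotypes: block template allele per haplotype, then
    # a per-marker flip that controls within-block r^2
    p_acc = p_sub[subpop]  # (n, n_blocks)
    dosage = np.zeros((m, n), dtype=np.int16)
    for _ in range(2):  # two haplotypes per inbred-ish accession
        template = (rng.random((n, n_blocks)) < p_acc).astype(np.int8)
        hap = template[:, block_index]  # (n, m)
        flips = rng.random((n, m)) < cfg.flip_prob
        hap = hap ^ flips
        dosage += hap.T.astype(np.int16)
    return dosage, chrom_of, pos, block_index


def simulate_panel(cfg: SimConfig):
    """Generate ``(GenotypeMatrix, PhenotypeTable, SimTruth)`` from ``cfg``.

    Winter survival in environment *e* is
    ``intercept_e + sum_q effect_q * dosage_q`` over QTLs active in *e*,
    plus Gaussian noise, then clipped to [0, 100] (the clipped fraction is
    recorded per environment).  DTF comes from the epistasis table plus
    noise, censored at the censor value.  Phenotypes are generated from the
    complete genotypes; missing calls are masked afterwards, so missingness
    never biases the trait.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    dosage, chrom_of, pos, block_index = _simulate_genotypes(cfg, rng)
    m, n = dosage.shape

    accessions = [f"ACC{i:04d}" for i in range(n)]
    snps = [
        SnpRecord(
            snp_id=f"SNP{i:05d}",
            chrom=f"{chrom_of[i] + 1}H",
            pos=int(pos[i]),
            alleles=("A", "B"),
        )
        for i in range(m)
    ]

    data = pd.DataFrame(index=pd.Index(accessions, name="accession"))
    herit: dict[str, float] = {}
    clipped: dict[str, float] = {}
    for e_idx, env in enumerate(cfg.environments):
        g = np.zeros(n)
        for q in cfg.ws_qtls:
            if env in q.env_mask:
                g = g + q.effect * dosage[q.snp_index]
        noise = rng.normal(0.0, cfg.env_sd[e_idx], size=n)
        y = cfg.env_intercepts[e_idx] + g + noise
        var_y = y.var()
        herit[env] = float(g.var() / var_y) if var_y > 0 else 0.0
        y_clip = np.clip(y, 0.0, 100.0)
        clipped[env] = float((y_clip != y).mean())
        data[f"ws_{env}"] = y_clip

    epi_pair = None
    if cfg.epistasis is not None:
        ep = cfg.epistasis
        tab = ep.mean_array()
        mu = tab[dosage[ep.locus1], dosage[ep.locus2]]
        raw = mu + rng.normal(0.0, ep.noise_sd, size=n)
        censored = raw >= ep.censor
        dtf = np.minimum(np.maximum(np.rint(raw), 1), ep.censor).astype(int)
        data["dtf"] = dtf
        data["dtf_censored"] = censored
        epi_pair = (snps[ep.locus1].snp_id, snps[ep.locus2].snp_id)

    calls = dosage.copy()
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    gm = GenotypeMatrix(accessions=accessions, snps=snps, calls=calls)
    censor = cfg.epistasis.censor if cfg.epistasis is not None else 154
    pt = PhenotypeTable(
        data=data, environments=list(cfg.environments), censor_value=censor
    )
    truth = SimTruth(
        qtl_snp_ids=[snps[q.snp_index].snp_id for q in cfg.ws_qtls],
        effects=[q.effect for q in cfg.ws_qtls],
        env_masks=[q.env_mask for q in cfg.ws_qtls],
        heritability=herit,
        epistatic_pair=epi_pair,
        block_index=block_index,
        clipped_fraction=clipped,
    )
    return gm, pt, truth


def simulate_null_pvalues(k: int, m: int, seed: int) -> np.ndarray:
    """An ``(m, k)`` matrix of i.i.d. Uniform(0, 1] p-values (a calibration
    harness for the meta-analysis stage)."""
    if k < 1 or m < 1:
        raise ValueError("k and m must be >= 1")
    rng = np.random.default_rng(seed)
    return 1.0 - rng.random((m, k))
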