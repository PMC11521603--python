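"""Synthetic cohort generator with full ground truth.

Emulates the statistical structure the CNV analysis assumes, so every
downstream stage can be tested against planted truth:

* diploid copy numbers as the sum of two independently drawn haploid
  alleles — bi-allelic genes carry deletion/duplication alleles at
  configurable frequencies (heterozygote deletion -> diploid CN 1,
  heterozygote duplication -> CN 3 for a single-copy gene), while a
  multi-allelic gene draws haploid counts from an explicit distribution,
  supporting wide diploid ranges such as 1–29;
* genomic segments on which several genes gain and lose copies together
  (one shared event perturbs all member genes identically);
* depth-proportional Poisson read counts per region, including a two-copy
  reference gene, with per-sample mean coverage drawn around a target depth;
* expression with linear dosage coupling (positive or negative slope) plus
  Gaussian noise, truncated at zero;
* ddPCR droplet counts from binomial partitioning consistent with the
  Poisson model the quantifier inverts.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .depth import ReadCountMatrix

__all__ = [
    "GeneSimSpec",
    "SegmentSpec",
    "DosageSpec",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "default_config",
    "load_config",
    "save_config",
    "simulate_true_cn",
    "simulate_read_counts",
    "simulate_expression",
    "simulate_ddpcr_wells",
    "simulate_cohort",
    "write_alignment_fixture",
]


@dataclass
class GeneSimSpec:
    """Copy-number model for one assay group.

    Bi-allelic genes (default): each haplotype carries ``base`` copies
    (base = expected_cn / 2), a deletion allele with ``deletion_freq``
    (base − 1 copies) or a duplication allele with ``duplication_freq``
    (base + 1 copies). A multi-allelic gene instead draws haploid copy
    counts from ``haploid_distribution`` (copy count -> probability).
    """

    assay_group: str
    expected_cn: int = 2
    deletion_freq: float = 0.0
    duplication_freq: float = 0.0
    haploid_distribution: dict[int, float] | None = None
    region_length: int = 2500

    def __post_init__(self) -> None:
        if self.expected_cn < 2 or self.expected_cn % 2:
            raise ValueError(
                f"{self.assay_group}: expected_cn must be a positive even "
                f"integer, got {self.expected_cn}"
            )
        if not 0 <= self.deletion_freq <= 1 or not 0 <= self.duplication_freq <= 1:
            raise ValueError(f"{self.assay_group}: allele frequencies must be in [0,1]")
        if self.deletion_freq + self.duplication_freq > 1:
            raise ValueError(
                f"{self.assay_group}: deletion_freq + duplication_freq > 1"
            )
        if self.haploid_distribution is not None:
            probs = np.array(list(self.haploid_distribution.values()), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.assay_group}: haploid distribution must sum to 1"
                )
            if any(k < 0 for k in self.haploid_distribution):
                raise ValueError(f"{self.assay_group}: haploid copies must be >= 0")


@dataclass
class SegmentSpec:
    """A copy-number-variable segment shared by several genes.

    One diploid event (two alleles, each −1 copy with ``deletion_freq`` or
    +1 copy with ``duplication_freq``) is applied identically to every
    member gene, on top of the genes' own CN draws.
    """

    members: list[str]
    deletion_freq: float = 0.0
    duplication_freq: float = 0.0

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a segment needs at least 2 member genes")
        if self.deletion_freq + self.duplication_freq > 1:
            raise ValueError("segment deletion_freq + duplication_freq > 1")


@dataclass
class DosageSpec:
    """Linear expression model TPM = max(0, intercept + slope*CN + noise)."""

    intercept: float = 50.0
    slope: float = 0.0
    noise_sd: float = 5.0


@dataclass
class SyntheticCohortConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the study conditions at desk scale: 100 diploid
    individuals at ~30x coverage (normal around the target, floored at 5x),
    150 bp reads, a 19 kb two-copy reference region, ~20000 droplets per
    ddPCR well with reference λ 0.2 copies/droplet.
    """

    n_samples: int = 100
    genes: list[GeneSimSpec] = field(default_factory=list)
    segments: list[SegmentSpec] = field(default_factory=list)
    dosage: dict[str, DosageSpec] = field(default_factory=dict)
    mean_depth: float = 30.0
    depth_sd: float = 5.0
    min_depth: float = 5.0
    read_length: int = 150
    reference_gene: str = "TP53"
    reference_length: int = 19000
    droplets_total: int = 20000
    ddpcr_lambda_ref: float = 0.2
    breeds: dict[str, float] = field(default_factory=lambda: {"Holstein": 1.0})
    seed: int | None = None

    def __post_init__(self) -> None:
        names = [g.assay_group for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate assay_group in gene specs")
        known = set(names)
        for seg in self.segments:
            missing = set(seg.members) - known
            if missing:
                raise ValueError(f"segment members not in gene specs: {sorted(missing)}")
        if abs(sum(self.breeds.values()) - 1.0) > 1e-9:
            raise ValueError("breed proportions must sum to 1")

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("simulation requires an explicit seed")
        return np.random.default_rng(self.seed)


def default_multiallelic_distribution(
    max_haploid: int = 15, decay: float = 0.75
) -> dict[int, float]:
    """Truncated geometric haploid-copy distribution (mean ≈ 3 copies).

    Supports haploid counts 0..max_haploid, hence diploid totals 0..30 —
    wide enough to emulate an extensively multi-allelic gene with a diploid
    range of 1–29.
    """
    k = np.arange(max_haploid + 1)
    p = (1 - decay) * decay**k
    p /= p.sum()
    return {int(i): float(v) for i, v in zip(k, p)}


def default_config(seed: int, n_samples: int = 100) -> SyntheticCohortConfig:
    """A cohort emulating the study's data structure.

    Ten bi-allelic singleton genes with uncommon deletion/duplication
    alleles, one extensively multi-allelic six-copy gene (DEFB103-like), a
    three-gene shared segment (DEFB113–DEFB112–DEFB110-1), and dosage
    coupling: one positive-slope gene (DEFB10), two negative (DEFB127,
    DEFB103), the rest null.
    """
    singletons = [
        "DEFB1-1",
        "DEFB10",
        "DEFB110-1",
        "DEFB112",
        "DEFB113",
        "DEFB123-1",
        "DEFB124",
        "DEFB126",
        "DEFB127",
        "DEFB402",
    ]
    genes = [
        GeneSimSpec(g, expected_cn=2, deletion_freq=0.05, duplication_freq=0.05)
        for g in singletons
    ]
    # the segment members' own alleles stay quiet so the shared event dominates
    for g in genes:
        if g.assay_group in ("DEFB110-1", "DEFB112", "DEFB113"):
            g.deletion_freq = 0.0
            g.duplication_freq = 0.0
    genes.append(
        GeneSimSpec(
            "DEFB103",
            expected_cn=6,
            haploid_distribution=default_multiallelic_distribution(),
            region_length=3900,  # three ~1.3 kb regions quantified jointly
        )
    )
    return SyntheticCohortConfig(
        n_samples=n_samples,
        genes=genes,
        segments=[
            SegmentSpec(
                members=["DEFB113", "DEFB112", "DEFB110-1"],
                deletion_freq=0.2,
                duplication_freq=0.15,
            )
        ],
        # noise_sd chosen as |slope|*sd(CN)*sqrt(1/r^2 - 1) to plant a
        # population dosage correlation of |r| ~= 0.5 per coupled gene
        dosage={
            "DEFB10": DosageSpec(intercept=20.0, slope=15.0, noise_sd=12.0),
            "DEFB127": DosageSpec(intercept=120.0, slope=-20.0, noise_sd=15.0),
            "DEFB103": DosageSpec(intercept=40.0, slope=-1.5, noise_sd=12.0),
            "DEFB124": DosageSpec(intercept=300.0, slope=0.0, noise_sd=60.0),
        },
        breeds={"Holstein": 0.5, "Charolais": 0.3, "Angus": 0.2},
        seed=seed,
    )


def _sample_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def simulate_true_cn(
    config: SyntheticCohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Integer diploid copy numbers per sample and assay group.

    Each gene's diploid CN is the sum of two independent haploid draws;
    segment events then shift all member genes identically; totals are
    floored at zero.
    """
    rng = rng or config.rng()
    n = config.n_samples
    cn = {}
    for gene in config.genes:
        if gene.haploid_distribution is not None:
            copies = np.array(list(gene.haploid_distribution.keys()))
            probs = np.array(list(gene.haploid_distribution.values()))
            haploid = rng.choice(copies, size=(n, 2), p=probs / probs.sum())
        else:
            base = gene.expected_cn // 2
            u = rng.random(size=(n, 2))
            haploid = np.full((n, 2), base)
            haploid = np.where(u < gene.deletion_freq, base - 1, haploid)
            haploid = np.where(
                u >= 1 - gene.duplication_freq, base + 1, haploid
            )
        cn[gene.assay_group] = haploid.sum(axis=1)
    df = pd.DataFrame(cn, index=_sample_ids(n))
    for seg in config.segments:
        u = rng.random(size=(n, 2))
        alleles = np.zeros((n, 2), dtype=int)
        alleles = np.where(u < seg.deletion_freq, -1, alleles)
        alleles = np.where(u >= 1 - seg.duplication_freq, 1, alleles)
        offset = alleles.sum(axis=1)
        for member in seg.members:
            df[member] = df[member] + offset
    return df.clip(lower=0).astype(int)


def simulate_read_counts(
    true_cn: pd.DataFrame,
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
) -> ReadCountMatrix:
    """Poisson read counts per region plus the two-copy reference gene.

    Expected count for sample s, gene g:
    depth_s * length_g * CN(s, g) / (2 * read_length) — i.e. the haploid-
    normalized number of read starts falling in the region at that depth.
    """
    rng = rng or config.rng()
    n = len(true_cn)
    depths = np.maximum(
        rng.normal(config.mean_depth, config.depth_sd, size=n), config.min_depth
    )
    lengths = {g.assay_group: g.region_length for g in config.genes}
    counts = {}
    for gene in true_cn.columns:
        lam = depths * lengths[gene] * true_cn[gene].to_numpy() / (
            2 * config.read_length
        )
        counts[gene] = rng.poisson(lam)
    ref_lam = depths * config.reference_length * 2 / (2 * config.read_length)
    counts[config.reference_gene] = rng.poisson(ref_lam)
    breed_names = list(config.breeds)
    breed_draw = rng.choice(
        breed_names, size=n, p=np.array(list(config.breeds.values()))
    )
    return ReadCountMatrix(
        pd.DataFrame(counts, index=true_cn.index),
        mean_coverage=pd.Series(depths, index=true_cn.index, name="mean_coverage"),
        breed=pd.Series(breed_draw, index=true_cn.index, name="breed"),
    )


def simulate_expression(
    true_cn: pd.DataFrame,
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dosage-coupled expression, TPM-scale, truncated at zero.

    Genes without a dosage spec get a null model (slope 0) with the default
    intercept and noise, so permutation-based checks see realistic variance.
    """
    rng = rng or config.rng()
    out = {}
    for gene in true_cn.columns:
        spec = config.dosage.get(gene, DosageSpec())
        noise = rng.normal(0.0, spec.noise_sd, size=len(true_cn))
        vals = spec.intercept + spec.slope * true_cn[gene].to_numpy() + noise
        out[gene] = np.maximum(vals, 0.0)
    return pd.DataFrame(out, index=true_cn.index)


def simulate_ddpcr_wells(
    true_cn: pd.DataFrame,
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Droplet counts for target and reference wells of every sample.

    λ_target = λ_ref * CN / 2; positives ~ Binomial(total, 1 − e^(−λ)).
    Warns when a λ implies a positive-droplet probability above 0.999 (the
    assay would be saturated and outside its dynamic range).
    """
    rng = rng or config.rng()
    if config.droplets_total <= 0:
        raise ValueError("droplets_total must be positive")
    genes = genes if genes is not None else list(true_cn.columns)
    lam_ref = config.ddpcr_lambda_ref
    rows = []
    for sample in true_cn.index:
        for gene in genes:
            lam = lam_ref * true_cn.at[sample, gene] / 2.0
            p = 1.0 - np.exp(-lam)
            if p > 0.999:
                warnings.warn(
                    f"{sample}/{gene}: saturation probability {p:.4f} — "
                    "assay outside dynamic range",
                    RuntimeWarning,
                    stacklevel=2,
                )
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "role": "target",
                    "droplets_total": config.droplets_total,
                    "droplets_positive": int(
                        rng.binomial(config.droplets_total, p)
                    ),
                }
            )
        p_ref = 1.0 - np.exp(-lam_ref)
        rows.append(
            {
                "sample": sample,
                "gene": config.reference_gene,
                "role": "reference",
                "droplets_total": config.droplets_total,
                "droplets_positive": int(
                    rng.binomial(config.droplets_total, p_ref)
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SyntheticCohort:
    """All simulated layers plus the generating configuration."""

    config: SyntheticCohortConfig
    true_cn: pd.DataFrame
    read_counts: ReadCountMatrix
    expression: pd.DataFrame
    ddpcr_wells: pd.DataFrame

    @property
    def breed(self) -> pd.Series:
        return self.read_counts.breed


def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate every layer from one seeded RNG in a fixed draw order."""
    rng = config.rng()
    true_cn = simulate_true_cn(config, rng)
    counts = simulate_read_counts(true_cn, config, rng)
    expr = simulate_expression(true_cn, config, rng)
    wells = simulate_ddpcr_wells(true_cn, config, rng)
    return SyntheticCohort(
        config=config,
        true_cn=true_cn,
        read_counts=counts,
        expression=expr,
        ddpcr_wells=wells,
    )


# -- config file round-trip ---------------------------------------------------


def save_config(config: SyntheticCohortConfig, path: str | Path) -> None:
    """Write the config as YAML (nested key-value sections)."""
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def load_config(path: str | Path) -> SyntheticCohortConfig:
    raw = yaml.safe_load(Path(path).read_text())
    genes = [GeneSimSpec(**g) for g in raw.pop("genes", [])]
    for g in genes:
        if g.haploid_distribution is not None:
            g.haploid_distribution = {
                int(k): float(v) for k, v in g.haploid_distribution.items()
            }
    segments = [SegmentSpec(**s) for s in raw.pop("segments", [])]
    dosage = {k: DosageSpec(**v) for k, v in raw.pop("dosage", {}).items()}
    return SyntheticCohortConfig(
        genes=genes, segments=segments, dosage=dosage, **raw
    )


def write_alignment_fixture(
    outdir: str | Path,
    regions: dict[str, tuple[str, int, int]],
    read_counts: dict[str, int],
    duplicate_counts: dict[str, int] | None = None,
    read_length: int = 100,
    sample_id: str = "synthetic",
) -> tuple[Path, Path]:
    """Emit a tiny sorted+indexed BAM and matching BED for the count reader.

    Synthetic alignments only: ``read_counts[name]`` reads are placed with
    alignment starts evenly spaced inside each 1-based inclusive region
    ``regions[name] = (chrom, start, end)``; ``duplicate_counts`` of them are
    additionally duplicate-flagged (and must be excluded by the reader).
    Returns (bam_path, bed_path).
    """
    import pysam

    duplicate_counts = duplicate_counts or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms: dict[str, int] = {}
    for chrom, start, end in regions.values():
        chroms[chrom] = max(chroms.get(chrom, 0), end + read_length + 1000)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(chroms.items())],
    }
    chrom_ids = {c: i for i, c in enumerate(sorted(chroms))}

    reads = []
    for name, (chrom, start, end) in regions.items():
        n = read_counts.get(name, 0)
        n_dup = duplicate_counts.get(name, 0)
        if n == 0:
            continue
        starts0 = np.linspace(start - 1, end - 1, num=n).astype(int)
        for i, s0 in enumerate(starts0):
            a = pysam.AlignedSegment()
            a.query_name = f"{name}_read{i}"
            a.query_sequence = "A" * read_length
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            a.reference_id = chrom_ids[chrom]
            a.reference_start = int(s0)
            a.cigarstring = f"{read_length}M"
            a.mapping_quality = 0 if i % 2 else 60  # multi-mappers stay counted
            a.flag = 0
            if i < n_dup:
                a.flag |= 0x400  # PCR duplicate
            reads.append((chrom_ids[chrom], int(s0), a))
    reads.sort(key=lambda t: (t[0], t[1]))

    bam_path = outdir / f"{sample_id}.bam"
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for _, _, a in reads:
            bam.write(a)
    pysam.index(str(bam_path))

    bed_path = outdir / f"{sample_id}.bed"
    with open(bed_path, "w") as fh:
        for name, (chrom, start, end) in regions.items():
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
    return bam_path, bed_path
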