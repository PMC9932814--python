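"""Synthetic RI panels with the statistical structure the analysis assumes.

The generators emulate a two-founder recombinant-inbred panel: each strain's
chromosome is a mosaic of the two parental haplotypes laid down by a
first-order switch process along the marker map.  For sib-mated RI lines the
probability that adjacent markers carry different founder haplotypes is the
map-expanded recombination fraction

    R = 4r / (1 + 6r)

with r the Haldane recombination fraction for the inter-marker distance
(r = (1 - exp(-2d_Morgan))/2).  Phenotypes are additive: each planted QTL
contributes +/- half its class-mean difference depending on the haplotype at
the nearest marker, a normal between-strain residual models polygenic
background, and within-strain replicates get proportional (CV-based) noise.

Default parameters mirror the mapped architecture of AII amacrine cell
number in the AXB/BXA panel: 26 strains, three additive QTLs on Chrs 9, 19
(A raises the trait: class-mean differences 11,139 and 13,585 cells) and 11
(B raises it: 13,252 cells), baseline ~67,000 cells, within-strain CV 0.05,
four replicates per strain.

Variant catalogs are emitted with truth labels recording exactly which
prioritization rules each record should fire, so classifier agreement can be
checked in closed loop.  Expression matrices plant cis effects at the marker
nearest a probed gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenotypeMatrix, MarkerInfo, StrainPhenotype, ValidationError
from .expression_eqtl import ExpressionMatrix, ProbeInfo
from .variant_priority import VariantRecord


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_cM: float
    length_Mb: float


@dataclass(frozen=True)
class QtlSpec:
    chromosome: str
    position_cM: float
    class_mean_difference: float  # cells, between homozygous classes
    high_allele: str = "A"  # which haplotype carries the larger mean


DEFAULT_CHROMOSOMES = (
    Chromosome("1", 100.0, 195.0),
    Chromosome("2", 90.0, 182.0),
    Chromosome("9", 70.0, 124.0),
    Chromosome("11", 80.0, 122.0),
    Chromosome("19", 55.0, 61.0),
)

# Planted loci follow the mapped peaks: Chr 9 ~46.5 Mb and Chr 19 ~12.4 Mb
# with A alleles raising cell number, Chr 11 ~11.1 Mb with B alleles raising
# it; cM positions place each at the same relative map location.
DEFAULT_QTLS = (
    QtlSpec("9", 26.0, 11139.0, "A"),
    QtlSpec("19", 11.0, 13585.0, "A"),
    QtlSpec("11", 7.0, 13252.0, "B"),
)


@dataclass
class SimConfig:
    n_strains: int = 26
    chromosomes: tuple[Chromosome, ...] = DEFAULT_CHROMOSOMES
    marker_spacing_cM: float = 5.0
    qtls: tuple[QtlSpec, ...] = DEFAULT_QTLS
    baseline_mean: float = 67000.0
    between_strain_residual_sd: float = 2000.0
    within_strain_cv: float = 0.05
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValidationError("need >=2 strains")
        if self.marker_spacing_cM <= 0:
            raise ValidationError("marker spacing must be > 0")
        for c in self.chromosomes:
            if c.length_cM < 0 or c.length_Mb <= 0:
                raise ValidationError(f"chromosome {c.name}: lengths must be > 0")
        if self.within_strain_cv < 0:
            raise ValidationError("within_strain_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def haldane_r(d_cM: float) -> float:
    """Haldane recombination fraction for a map distance in cM."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


def ri_switch_probability(d_cM: float) -> float:
    """Sib-mating RI map expansion: R = 4r/(1+6r) with Haldane r."""
    r = haldane_r(d_cM)
    return 4.0 * r / (1.0 + 6.0 * r)


def marker_map(cfg: SimConfig) -> list[MarkerInfo]:
    """Evenly spaced markers along every chromosome (cM and proportional Mb)."""
    markers: list[MarkerInfo] = []
    for chrom in cfg.chromosomes:
        n = max(int(math.floor(chrom.length_cM / cfg.marker_spacing_cM)) + 1, 1)
        for i in range(n):
            cm = i * cfg.marker_spacing_cM
            frac = cm / chrom.length_cM if chrom.length_cM > 0 else 0.0
            mb = max(frac * chrom.length_Mb, 0.001)  # keep Mb strictly positive
            markers.append(
                MarkerInfo(f"C{chrom.name}M{i:03d}", chrom.name, cm, round(mb, 4))
            )
    return markers


def simulate_ri_genotypes(cfg: SimConfig, seed: int | None = None) -> GenotypeMatrix:
    """Draw an RI genotype panel by the founder-draw + switch process."""
    rng = _rng(cfg.seed if seed is None else seed, 1)
    markers = marker_map(cfg)
    strains = [f"RIS{i + 1:03d}" for i in range(cfg.n_strains)]
    columns: list[np.ndarray] = []
    idx = 0
    for chrom in cfg.chromosomes:
        chrom_markers = [m for m in markers if m.chromosome == chrom.name]
        m = len(chrom_markers)
        state = rng.random(cfg.n_strains) < 0.5  # founder haplotype, True = A
        alleles = np.empty((cfg.n_strains, m), dtype=bool)
        alleles[:, 0] = state
        for j in range(1, m):
            d = chrom_markers[j].position_cM - chrom_markers[j - 1].position_cM
            pr = ri_switch_probability(d)
            switch = rng.random(cfg.n_strains) < pr
            alleles[:, j] = alleles[:, j - 1] ^ switch
        columns.append(alleles)
        idx += m
    allele_matrix = np.concatenate(columns, axis=1)
    calls = np.where(allele_matrix, "A", "B").astype("<U1")
    return GenotypeMatrix(strains, markers, calls)


def expected_breakpoints(cfg: SimConfig) -> float:
    """Expected haplotype switches per strain: sum of R over marker intervals."""
    total = 0.0
    for chrom in cfg.chromosomes:
        n = max(int(math.floor(chrom.length_cM / cfg.marker_spacing_cM)) + 1, 1)
        total += (n - 1) * ri_switch_probability(cfg.marker_spacing_cM)
    return total


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def snap_qtls_to_markers(
    genotypes: GenotypeMatrix, qtls: Sequence[QtlSpec]
) -> list[tuple[QtlSpec, str]]:
    """Nearest genotyped marker (by cM, same chromosome) for each QTL."""
    out = []
    for q in qtls:
        candidates = [m for m in genotypes.markers if m.chromosome == q.chromosome]
        if not candidates:
            raise ValidationError(f"no markers on chromosome {q.chromosome}")
        nearest = min(candidates, key=lambda m: abs(m.position_cM - q.position_cM))
        out.append((q, nearest.name))
    return out


def simulate_phenotypes(
    genotypes: GenotypeMatrix, cfg: SimConfig, seed: int | None = None
) -> list[StrainPhenotype]:
    """Additive strain values plus proportional replicate noise.

    Each QTL contributes +/- difference/2 with the sign arranged so the
    configured high allele's homozygous class mean exceeds the other class
    by exactly the class-mean difference (before residual noise).
    """
    rng = _rng(cfg.seed if seed is None else seed, 2)
    snapped = snap_qtls_to_markers(genotypes, cfg.qtls)
    indicator = genotypes.indicator()
    values = np.full(genotypes.n_strains, cfg.baseline_mean)
    for q, marker_name in snapped:
        x = indicator[:, genotypes.marker_index(marker_name)]
        x = np.nan_to_num(x, nan=0.5)  # U strains sit midway (none by default)
        signed = x - 0.5 if q.high_allele == "A" else 0.5 - x
        values = values + signed * q.class_mean_difference
    values = values + rng.normal(0.0, cfg.between_strain_residual_sd, genotypes.n_strains)
    phens = []
    for i, strain in enumerate(genotypes.strains):
        noise_sd = cfg.within_strain_cv * abs(values[i])
        reps = values[i] + rng.normal(0.0, noise_sd, cfg.n_replicates)
        phens.append(StrainPhenotype(strain, [float(v) for v in reps]))
    return phens


# ---------------------------------------------------------------------------
# Variant catalogs with truth labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    start: int  # bp, 1-based inclusive
    end: int
    tss: int


DEFAULT_GENES = (
    GeneModel("GeneA", "9", 46_000_000, 46_045_000, 46_000_000),
    GeneModel("GeneB", "19", 12_350_000, 12_427_000, 12_427_000),
    GeneModel("GeneC", "11", 11_000_000, 11_060_000, 11_000_000),
)


@dataclass(frozen=True)
class TruthLabel:
    functional: bool
    regulatory: bool
    rules: tuple[str, ...]


#: Template names understood by :func:`simulate_variant_catalog`.
VARIANT_TEMPLATES = (
    "F1",
    "F2_group",
    "F2_domain",
    "F3",
    "F4",
    "R1",
    "R2",
    "R3",
    "neg",
)

_GROUPED_AA = {
    "nonpolar": "AVLIMFWP",
    "polar": "STNQYC",
    "positive": "KRH",
    "negative": "DE",
}

_BASES = "ACGT"


def _make_variant(
    template: str, gene: GeneModel, pos: int, rng: np.random.Generator
) -> tuple[VariantRecord, TruthLabel]:
    snp = dict(ref="A", alt="G", vclass="SNP")
    indel = dict(ref="A", alt="AT", vclass="INDEL")
    sv = dict(ref="A", alt="<DEL>", vclass="SV")
    common = dict(chrom=gene.chrom, pos=pos, gene=gene.name, in_ecr=False)

    if template == "F1":
        cons = str(rng.choice(["frameshift", "stop_gained", "stop_lost"]))
        kind = indel if cons == "frameshift" else snp
        v = VariantRecord(consequences=frozenset({cons}), **kind, **common)
        return v, TruthLabel(True, False, ("F1",))
    if template == "F2_group":
        g1, g2 = rng.choice(list(_GROUPED_AA), size=2, replace=False)
        aa_ref = str(rng.choice(list(_GROUPED_AA[g1])))
        aa_alt = str(rng.choice(list(_GROUPED_AA[g2])))
        v = VariantRecord(
            consequences=frozenset({"missense"}),
            aa_ref=aa_ref,
            aa_alt=aa_alt,
            in_domain=False,
            **snp,
            **common,
        )
        return v, TruthLabel(True, False, ("F2",))
    if template == "F2_domain":
        group = str(rng.choice(list(_GROUPED_AA)))
        aa_ref, aa_alt = rng.choice(list(_GROUPED_AA[group]), size=2, replace=False)
        v = VariantRecord(
            consequences=frozenset({"missense"}),
            aa_ref=str(aa_ref),
            aa_alt=str(aa_alt),
            in_domain=True,
            **snp,
            **common,
        )
        return v, TruthLabel(True, False, ("F2",))
    if template == "F3":
        v = VariantRecord(
            consequences=frozenset({"inframe_indel"}),
            in_domain=True,
            ref="A",
            alt="AGTC",
            vclass="INDEL",
            **common,
        )
        return v, TruthLabel(True, False, ("F3",))
    if template == "F4":
        cons = str(rng.choice(["splice_region", "splice_donor", "splice_acceptor"]))
        v = VariantRecord(consequences=frozenset({cons, "intronic"}), **snp, **common)
        return v, TruthLabel(True, False, ("F4",))
    if template == "R1":
        where = str(rng.choice(["utr5", "utr3", "upstream"]))
        tss_d = float(rng.integers(-TSS_NEAR, TSS_NEAR + 1)) if where == "upstream" else 5000.0
        kind = snp if rng.random() < 0.5 else indel
        common_r = dict(common, in_ecr=True)
        v = VariantRecord(
            consequences=frozenset({where}),
            tss_distance=tss_d,
            **kind,
            **common_r,
        )
        return v, TruthLabel(False, True, ("R1",))
    if template == "R2":
        common_r = dict(common, in_ecr=True)
        v = VariantRecord(consequences=frozenset({"intronic"}), **sv, **common_r)
        return v, TruthLabel(False, True, ("R2",))
    if template == "R3":
        v = VariantRecord(
            consequences=frozenset({"utr3"}),
            mirna_site_change=True,
            **snp,
            **common,
        )
        return v, TruthLabel(False, True, ("R3",))
    if template == "neg":
        kind = str(
            rng.choice(
                [
                    "synonymous",
                    "intronic",
                    "missense_same_group",
                    "far_upstream",
                    "utr3_no_ecr",
                    "inframe_no_domain",
                    "sv_intergenic",
                ]
            )
        )
        if kind == "missense_same_group":
            group = str(rng.choice(["nonpolar", "polar"]))
            aa_ref, aa_alt = rng.choice(list(_GROUPED_AA[group]), size=2, replace=False)
            v = VariantRecord(
                consequences=frozenset({"missense"}),
                aa_ref=str(aa_ref),
                aa_alt=str(aa_alt),
                in_domain=False,
                **snp,
                **common,
            )
        elif kind == "far_upstream":
            v = VariantRecord(
                consequences=frozenset({"upstream"}),
                tss_distance=40_000.0,
                **snp,
                **common,
            )
        elif kind == "utr3_no_ecr":
            v = VariantRecord(consequences=frozenset({"utr3"}), **snp, **common)
        elif kind == "inframe_no_domain":
            v = VariantRecord(
                consequences=frozenset({"inframe_indel"}),
                in_domain=False,
                ref="A",
                alt="AGTC",
                vclass="INDEL",
                **common,
            )
        elif kind == "sv_intergenic":
            v = VariantRecord(consequences=frozenset({"intergenic"}), **sv, **common)
        else:
            v = VariantRecord(consequences=frozenset({kind}), **snp, **common)
        return v, TruthLabel(False, False, ())
    raise ValidationError(f"unknown variant template {template!r}")


TSS_NEAR = 500


def simulate_variant_catalog(
    genes: Sequence[GeneModel] = DEFAULT_GENES,
    rates: Mapping[str, float] | None = None,
    n_variants: int = 100,
    seed: int = 0,
) -> list[tuple[VariantRecord, TruthLabel]]:
    """Emit variants with known rule-truth labels at configurable rates.

    ``rates`` weights the templates in :data:`VARIANT_TEMPLATES`; zero total
    weight (or ``n_variants=0``) yields an empty catalog.  Truth labels state
    which functional/regulatory rules must fire under the default
    (ECR-conjunctive) classifier configuration.
    """
    if rates is None:
        rates = {t: 1.0 for t in VARIANT_TEMPLATES}
    unknown = set(rates) - set(VARIANT_TEMPLATES)
    if unknown:
        raise ValidationError(f"unknown variant templates: {sorted(unknown)}")
    names = [t for t in VARIANT_TEMPLATES if rates.get(t, 0.0) > 0]
    weights = np.array([rates[t] for t in names], dtype=float)
    if n_variants == 0 or not names:
        return []
    weights = weights / weights.sum()
    rng = _rng(seed, 3)
    out = []
    positions: set[tuple[str, int]] = set()
    for _ in range(n_variants):
        template = str(rng.choice(names, p=weights))
        gene = genes[int(rng.integers(len(genes)))]
        while True:
            pos = int(rng.integers(gene.start, gene.end + 1))
            if (gene.chrom, pos) not in positions:
                positions.add((gene.chrom, pos))
                break
        out.append(_make_variant(template, gene, pos, rng))
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeSpec:
    probe: str
    gene: str
    chromosome: str
    position_Mb: float
    cis_effect: float  # log2 units added when the A haplotype is present
    noise_sd: float
    base: float = 9.0  # log2 units, above the background threshold


def simulate_expression(
    genotypes: GenotypeMatrix,
    probe_specs: Sequence[ProbeSpec],
    seed: int = 0,
) -> ExpressionMatrix:
    """Plant cis effects at the marker nearest each probed gene."""
    rng = _rng(seed, 4)
    values = np.empty((genotypes.n_strains, len(probe_specs)))
    probes = []
    for j, spec in enumerate(probe_specs):
        candidates = [
            (k, m)
            for k, m in enumerate(genotypes.markers)
            if m.chromosome == spec.chromosome
        ]
        if not candidates:
            raise ValidationError(f"no markers on chromosome {spec.chromosome}")
        k, _ = min(candidates, key=lambda km: abs(km[1].position_Mb - spec.position_Mb))
        x = np.nan_to_num(genotypes.indicator()[:, k], nan=0.5)
        values[:, j] = (
            spec.base
            + spec.cis_effect * x
            + rng.normal(0.0, spec.noise_sd, genotypes.n_strains)
        )
        probes.append(
            ProbeInfo(spec.probe, spec.gene, spec.chromosome, spec.position_Mb)
        )
    return ExpressionMatrix(genotypes.strains, probes, values)
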