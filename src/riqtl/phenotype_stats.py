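"""Per-retina total-cell estimation and panel-level descriptive statistics.

Totals are estimated the way retinal wholemount counts are usually scaled up:
cells counted in a handful of sampled fields of known area define a mean
density, which is multiplied by total retinal area.  Panel summaries cover
broad-sense heritability from a one-way random-effects decomposition
(strain as the random factor), the average within-strain coefficient of
variation, percent differences between strains, and two-locus haplotype
group means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenotypeMatrix, StrainPhenotype, ValidationError

logger = logging.getLogger("riqtl")

#: Area of one sampled wholemount field in mm^2 (40x objective).
DEFAULT_FIELD_AREA_MM2 = 0.032


@dataclass
class FieldSample:
    """Cell counts from sampled fields of one retina.

    counts: cells per field; field_area: mm^2 per field; retinal_area: mm^2.
    """

    counts: list[float]
    field_area: float = DEFAULT_FIELD_AREA_MM2
    retinal_area: float = 1.0

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ValidationError("need at least one field count")
        if any(c < 0 for c in self.counts):
            raise ValidationError("field counts must be >= 0")
        if self.field_area <= 0:
            raise ValidationError("field_area must be > 0")
        if self.retinal_area <= 0:
            raise ValidationError("retinal_area must be > 0")


@dataclass
class PanelSummary:
    h2: float
    mean_cv: float
    strain_means: dict[str, float] = field(default_factory=dict)


def estimate_total(sample: FieldSample) -> float:
    """Mean field density (cells/mm^2) times total retinal area (mm^2)."""
    density = float(np.mean(sample.counts)) / sample.field_area
    return density * sample.retinal_area


def heritability(phenotypes: Sequence[StrainPhenotype]) -> float:
    """Broad-sense heritability from one-way random-effects components.

    Between- and within-strain variance components are estimated from the
    ANOVA expected mean squares with the harmonic mean of replicate counts
    standing in for the common group size in unbalanced panels.  A negative
    between-strain component is truncated at zero, so the estimate lies in
    [0, 1].  Strains with a single replicate contribute to the between-strain
    sum of squares only.
    """
    with_reps = [p for p in phenotypes if p.n >= 2]
    if len(phenotypes) < 2:
        raise ValidationError("need >=2 strains")
    if not with_reps:
        raise ValidationError("within-strain variance inestimable: all strains n=1")
    k = len(phenotypes)
    values = [np.asarray(p.replicates, dtype=float) for p in phenotypes]
    ns = np.array([v.size for v in values])
    grand = float(np.concatenate(values).mean())
    ss_between = float(sum(n * (v.mean() - grand) ** 2 for n, v in zip(ns, values)))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df_between = k - 1
    df_within = int(ns.sum()) - k
    if df_within <= 0:
        raise ValidationError("within-strain variance inestimable")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    n0 = len(ns) / float((1.0 / ns).sum())  # harmonic mean replicate count
    sigma_b2 = max((ms_between - ms_within) / n0, 0.0)
    total = sigma_b2 + ms_within
    return sigma_b2 / total if total > 0 else 0.0


def mean_cv(phenotypes: Sequence[StrainPhenotype]) -> float:
    """Unweighted mean of per-strain coefficients of variation."""
    cvs = [p.cv for p in phenotypes if not math.isnan(p.cv)]
    if not cvs:
        raise ValidationError("no strain has a defined CV")
    return float(np.mean(cvs))


def percent_change(a: float, b: float) -> float:
    """Percent change from ``a`` to ``b``: (b - a)/a * 100."""
    if a <= 0:
        raise ValidationError("baseline value must be > 0")
    return (b - a) / a * 100.0


def panel_summary(phenotypes: Sequence[StrainPhenotype]) -> PanelSummary:
    return PanelSummary(
        h2=heritability(phenotypes),
        mean_cv=mean_cv(phenotypes),
        strain_means={p.strain: p.mean for p in phenotypes},
    )


@dataclass
class HaplotypeGroup:
    codes: tuple[str, str]
    strains: list[str]
    mean: float  # NaN when the group is empty

    @property
    def n(self) -> int:
        return len(self.strains)


def haplotype_group_means(
    genotypes: GenotypeMatrix,
    phenotypes: Sequence[StrainPhenotype] | Mapping[str, float],
    loci: tuple[str, str],
) -> dict[tuple[str, str], HaplotypeGroup]:
    """Mean of strain means in the four two-locus haplotype groups.

    Strains carrying U at either marker, or absent from the phenotype table,
    are excluded (logged).  Groups are keyed (code at loci[0], code at
    loci[1]); empty groups are reported with n=0 and a NaN mean.
    """
    if isinstance(phenotypes, Mapping):
        means = dict(phenotypes)
    else:
        means = {p.strain: p.mean for p in phenotypes}
    j0 = genotypes.marker_index(loci[0])
    j1 = genotypes.marker_index(loci[1])
    groups: dict[tuple[str, str], list[str]] = {
        (a, b): [] for a in "AB" for b in "AB"
    }
    n_dropped = 0
    for i, strain in enumerate(genotypes.strains):
        c0, c1 = genotypes.calls[i, j0], genotypes.calls[i, j1]
        if c0 == "U" or c1 == "U" or strain not in means:
            n_dropped += 1
            continue
        groups[(c0, c1)].append(strain)
    if n_dropped:
        logger.info("haplotype_group_means: %d strains excluded", n_dropped)
    if all(not members for members in groups.values()):
        raise ValidationError("no strain could be assigned to any haplotype group")
    return {
        codes: HaplotypeGroup(
            codes,
            members,
            float(np.mean([means[s] for s in members])) if members else math.nan,
        )
        for codes, members in groups.items()
    }
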