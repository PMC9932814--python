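"""Weighted single-marker LOD scans for recombinant-inbred panels.

At every genotyped marker the strain means are regressed on a 0/1 parental
haplotype indicator by weighted least squares, and linkage strength is
summarized as

    LOD = (n/2) * log10(RSS_null / RSS_full)

where the null model is the weighted intercept-only fit (plus any background
control markers under composite mapping) and n is the number of strains used
at that marker.  The additive effect is reported as the full weighted
class-mean difference mean(A) - mean(B), so a positive effect means the A
haplotype increases the trait.

Genome-wide significance comes from permutation: strain labels of the
(mean, weight) pairs are shuffled jointly, the whole genome is rescanned, and
the maximum LOD per permutation is recorded.  The suggestive threshold is the
33rd empirical percentile of those maxima (genome-wide p < 0.67) and the
significant threshold the 95th (p < 0.05), both using the "higher" quantile
rule so thresholds are attained values.

QTL support intervals follow the 1.5-LOD drop rule: the interval is the run
of positions where the LOD trace stays above peak minus the drop, with
boundaries linearly interpolated in Mb between the markers straddling each
crossing, and nearby sub-intervals merged when the gap between them is small
(a recombination event in a single strain can split one locus in two).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenotypeMatrix, MarkerInfo, StrainPhenotype, ValidationError

logger = logging.getLogger("riqtl")

#: Markers closer than this (cM) to a same-chromosome control marker are
#: flagged "near-covariate" in composite scans (flag only; never dropped).
COVARIATE_EXCLUSION_CM = 10.0

#: Perfect-separation guard: RSS_full below this fraction of RSS_null caps
#: the LOD at (n/2)*12 with a "separation" flag instead of +inf.
SEPARATION_RTOL = 1e-12
SEPARATION_LOG10 = 12.0

DEFAULT_MERGE_GAP_MB = 10.0


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanRecord:
    marker: MarkerInfo
    lod: float
    effect: float
    n_used: int
    flags: tuple[str, ...] = ()


@dataclass
class ScanResult:
    records: list[ScanRecord]
    covariate_markers: list[str] = field(default_factory=list)
    weights_used: bool = False

    @property
    def lods(self) -> np.ndarray:
        return np.array([r.lod for r in self.records])

    @property
    def effects(self) -> np.ndarray:
        return np.array([r.effect for r in self.records])

    def chromosome(self, chrom: str) -> list[ScanRecord]:
        return [r for r in self.records if r.marker.chromosome == chrom]

    def peak(self, chrom: str | None = None) -> ScanRecord:
        """Highest-LOD record; ties broken by lowest Mb position (logged)."""
        recs = self.records if chrom is None else self.chromosome(chrom)
        if not recs:
            raise ValidationError(f"no scanned markers on chromosome {chrom!r}")
        best = max(recs, key=lambda r: r.lod)
        tied = [r for r in recs if r.lod == best.lod]
        if len(tied) > 1:
            tied.sort(key=lambda r: (r.marker.position_Mb, r.marker.position_cM))
            logger.info("peak tie at LOD %.3f broken by lowest Mb", best.lod)
            return tied[0]
        return best


@dataclass
class PermutationResult:
    n_perm: int
    seed: int
    max_lods: np.ndarray
    suggestive: float
    significant: float


@dataclass
class SupportInterval:
    chromosome: str
    peak_marker: str
    peak_lod: float
    start_Mb: float
    end_Mb: float
    drop: float = 1.5
    merged_from: int = 1
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Alignment of genotype and phenotype tables
# ---------------------------------------------------------------------------


def _align(
    genotypes: GenotypeMatrix,
    phenotypes: Sequence[StrainPhenotype] | Mapping[str, float],
    weights: Mapping[str, float] | None,
    exclude_strains: Sequence[str],
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    if isinstance(phenotypes, Mapping):
        means = dict(phenotypes)
        auto_w: dict[str, float] = {}
    else:
        means = {p.strain: p.mean for p in phenotypes}
        auto_w = {
            p.strain: p.weight for p in phenotypes if not math.isnan(p.weight)
        }
    shared = [
        s for s in genotypes.strains if s in means and s not in set(exclude_strains)
    ]
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} strains shared between genotypes and phenotypes; need >=3"
        )
    g = genotypes.subset_strains(shared)
    y = np.array([means[s] for s in shared], dtype=float)
    if weights is not None:
        w = np.array([weights[s] for s in shared], dtype=float)
    elif auto_w and all(s in auto_w for s in shared):
        w = np.array([auto_w[s] for s in shared], dtype=float)
    else:
        w = np.ones(len(shared))
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValidationError("strain weights must be finite and > 0")
    return g, y, w


# ---------------------------------------------------------------------------
# Scan engines
# ---------------------------------------------------------------------------


def _marker_stats(
    X: np.ndarray, M: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized weighted marker regression from sufficient statistics.

    X: (n, m) 0/1 indicator with NaN replaced by 0; M: (n, m) validity mask.
    Returns (lod, effect, n_used, monomorphic, separation) arrays of length m.
    """
    wc = w[:, None] * M
    W = wc.sum(axis=0)
    Sy = wc.T @ y
    Syy = wc.T @ (y * y)
    Sx = (wc * X).sum(axis=0)
    Sxy = (wc * X).T @ y
    n_used = M.sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        rss_null = Syy - Sy * Sy / W
        sxx_c = Sx - Sx * Sx / W
        sxy_c = Sxy - Sx * Sy / W
        rss_full = rss_null - np.where(sxx_c > 0, sxy_c * sxy_c / np.maximum(sxx_c, 1e-300), 0.0)
        # class means: A where x=1, B where x=0
        wB = W - Sx
        effect = np.where(
            (Sx > 0) & (wB > 0), Sxy / np.maximum(Sx, 1e-300) - (Sy - Sxy) / np.maximum(wB, 1e-300), np.nan
        )
    # A marker is monomorphic when every used strain is in one class
    n_A = (M & (X > 0.5)).sum(axis=0)
    monomorphic = (n_A == 0) | (n_A == n_used)
    rss_full = np.clip(rss_full, 0.0, None)

    lod = np.zeros(X.shape[1])
    ok = (~monomorphic) & (rss_null > 0)
    sep = ok & (rss_full < SEPARATION_RTOL * rss_null)
    fit = ok & ~sep
    lod[fit] = (n_used[fit] / 2.0) * np.log10(rss_null[fit] / rss_full[fit])
    lod[sep] = (n_used[sep] / 2.0) * SEPARATION_LOG10
    lod = np.clip(lod, 0.0, None)
    return lod, effect, n_used, monomorphic, sep


def lod_scan(
    genotypes: GenotypeMatrix,
    phenotypes: Sequence[StrainPhenotype] | Mapping[str, float],
    weights: Mapping[str, float] | None = None,
    covariate_markers: Sequence[str] | None = None,
    exclude_strains: Sequence[str] = (),
) -> ScanResult:
    """Weighted single-marker LOD scan of strain means on haplotype codes.

    Strains with a U call at a marker are dropped for that marker only.
    Markers with all used strains in one genotype class get LOD 0 and the
    flag "monomorphic".  A perfect fit is capped (flag "separation").  With
    ``covariate_markers`` the scan is a composite scan: the control-marker
    indicators enter both null and full models.
    """
    if covariate_markers:
        return composite_scan(
            genotypes, phenotypes, list(covariate_markers), weights, exclude_strains
        )
    g, y, w = _align(genotypes, phenotypes, weights, exclude_strains)
    Xi = g.indicator()
    M = np.isfinite(Xi)
    X = np.nan_to_num(Xi)
    lod, effect, n_used, mono, sep = _marker_stats(X, M, y, w)
    records = []
    for j, m in enumerate(g.markers):
        flags = []
        if mono[j]:
            flags.append("monomorphic")
        if sep[j]:
            flags.append("separation")
        records.append(
            ScanRecord(m, float(lod[j]), float(effect[j]), int(n_used[j]), tuple(flags))
        )
    return ScanResult(records, [], weights is not None or not np.allclose(w, w[0]))


def composite_scan(
    genotypes: GenotypeMatrix,
    phenotypes: Sequence[StrainPhenotype] | Mapping[str, float],
    control_markers: Sequence[str],
    weights: Mapping[str, float] | None = None,
    exclude_strains: Sequence[str] = (),
) -> ScanResult:
    """Composite interval mapping: scan with background-marker covariates.

    Control-marker genotype indicators are included in both the null and the
    full model, so the LOD at each position measures linkage of the residual
    variation.  Positions within :data:`COVARIATE_EXCLUSION_CM` of a
    same-chromosome control marker are flagged "near-covariate" (LOD still
    reported).  An empty control list reduces to :func:`lod_scan`.
    """
    if not control_markers:
        return lod_scan(genotypes, phenotypes, weights, None, exclude_strains)
    g, y, w = _align(genotypes, phenotypes, weights, exclude_strains)
    Xi = g.indicator()
    M = np.isfinite(Xi)
    X = np.nan_to_num(Xi)

    ctrl_idx = [g.marker_index(name) for name in control_markers]
    ctrl_info = [g.markers[j] for j in ctrl_idx]
    C = Xi[:, ctrl_idx]  # (n, c) with NaN for U
    ctrl_ok = np.isfinite(C).all(axis=1)
    for name, j in zip(control_markers, ctrl_idx):
        col = Xi[ctrl_ok, j]
        if len(np.unique(col)) < 2:
            raise ValidationError(f"control marker {name} is monomorphic")

    sw = np.sqrt(w)
    records = []
    for j, m in enumerate(g.markers):
        use = M[:, j] & ctrl_ok
        n = int(use.sum())
        flags = []
        for c in ctrl_info:
            if c.chromosome == m.chromosome and abs(c.position_cM - m.position_cM) <= COVARIATE_EXCLUSION_CM:
                flags.append("near-covariate")
                break
        if n < 3:
            records.append(ScanRecord(m, 0.0, math.nan, n, tuple(flags + ["too-few-strains"])))
            continue
        yv = y[use]
        swv = sw[use]
        ones = np.ones(n)
        D_null = np.column_stack([ones, C[use]])
        x = X[use, j]
        D_full = np.column_stack([D_null, x])
        rss_null = _wrss(D_null, yv, swv)
        rss_full = _wrss(D_full, yv, swv)
        n_A = int((x > 0.5).sum())
        mono = n_A == 0 or n_A == n
        wv = w[use]
        if mono:
            effect = math.nan
            lod = 0.0
            flags.append("monomorphic")
        else:
            effect = float(
                np.average(yv[x > 0.5], weights=wv[x > 0.5])
                - np.average(yv[x < 0.5], weights=wv[x < 0.5])
            )
            if rss_null <= 0:
                lod = 0.0
            elif rss_full < SEPARATION_RTOL * rss_null:
                lod = (n / 2.0) * SEPARATION_LOG10
                flags.append("separation")
            else:
                lod = max((n / 2.0) * math.log10(rss_null / rss_full), 0.0)
        records.append(ScanRecord(m, float(lod), effect, n, tuple(flags)))
    return ScanResult(records, list(control_markers), True)


def _wrss(D: np.ndarray, y: np.ndarray, sqrt_w: np.ndarray) -> float:
    """Weighted residual sum of squares of y on design D via least squares."""
    Dw = D * sqrt_w[:, None]
    yw = y * sqrt_w
    beta, *_ = np.linalg.lstsq(Dw, yw, rcond=None)
    r = yw - Dw @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------


def permutation_thresholds(
    genotypes: GenotypeMatrix,
    phenotypes: Sequence[StrainPhenotype] | Mapping[str, float],
    n_perm: int = 2000,
    seed: int = 0,
    weights: Mapping[str, float] | None = None,
    exclude_strains: Sequence[str] = (),
) -> PermutationResult:
    """Genome-wide empirical LOD thresholds from strain-label permutation.

    Each permutation shuffles the (mean, weight) pairs jointly across strain
    labels, rescans every marker, and records the genome-wide maximum LOD.
    Thresholds are the 33rd (suggestive, p < 0.67) and 95th (significant,
    p < 0.05) "higher"-rule percentiles of the maxima.
    """
    if n_perm < 100:
        warnings.warn("thresholds unstable: n_perm < 100", stacklevel=2)
    g, y, w = _align(genotypes, phenotypes, weights, exclude_strains)
    Xi = g.indicator()
    M = np.isfinite(Xi)
    X = np.nan_to_num(Xi)
    rng = np.random.default_rng(seed)
    n = len(y)
    max_lods = np.empty(n_perm)
    for p in range(n_perm):
        idx = rng.permutation(n)
        lod, *_ = _marker_stats(X, M, y[idx], w[idx])
        max_lods[p] = lod.max(initial=0.0)
    suggestive = float(np.quantile(max_lods, 0.33, method="higher"))
    significant = float(np.quantile(max_lods, 0.95, method="higher"))
    return PermutationResult(n_perm, seed, max_lods, suggestive, significant)


# ---------------------------------------------------------------------------
# 1.5-LOD support intervals
# ---------------------------------------------------------------------------


def support_intervals(
    scan: ScanResult,
    chromosome: str,
    drop: float = 1.5,
    merge_gap_Mb: float = DEFAULT_MERGE_GAP_MB,
    suggestive: float | None = None,
) -> list[SupportInterval]:
    """QTL support intervals from the LOD-drop rule on one chromosome.

    threshold = chromosome peak LOD - drop.  Contiguous runs of markers at or
    above the threshold become sub-intervals whose boundaries are linearly
    interpolated in Mb between the flanking markers straddling the crossing
    (clamped to the first/last scanned position).  Sub-intervals separated by
    a gap smaller than ``merge_gap_Mb`` are merged and ``merged_from``
    counts the runs.  If ``suggestive`` is given and the peak is below it,
    the interval carries the flag "sub-threshold".
    """
    recs = sorted(
        scan.chromosome(chromosome), key=lambda r: r.marker.position_Mb
    )
    if len(recs) < 2:
        raise ValidationError(
            f"need >=2 scanned markers on chromosome {chromosome!r}"
        )
    pos = np.array([r.marker.position_Mb for r in recs])
    lod = np.array([r.lod for r in recs])
    if np.isnan(pos).any():
        raise ValidationError("support intervals require Mb positions for all markers")
    peak_lod = float(lod.max())
    threshold = peak_lod - drop

    above = lod >= threshold
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(recs):
        if above[i]:
            j = i
            while j + 1 < len(recs) and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    def _edge(inner: int, outer: int) -> float:
        """Interpolated Mb where the trace crosses the threshold."""
        l_in, l_out = lod[inner], lod[outer]
        if l_in == l_out:
            return float(pos[outer])
        frac = (l_in - threshold) / (l_in - l_out)
        return float(pos[inner] + frac * (pos[outer] - pos[inner]))

    sub: list[tuple[float, float]] = []
    for i0, i1 in runs:
        start = float(pos[0]) if i0 == 0 else _edge(i0, i0 - 1)
        end = float(pos[-1]) if i1 == len(recs) - 1 else _edge(i1, i1 + 1)
        sub.append((start, end))

    merged: list[tuple[float, float, list[tuple[int, int]]]] = []
    for (start, end), run in zip(sub, runs):
        if merged and start - merged[-1][1] < merge_gap_Mb:
            s0, _, runlist = merged[-1]
            merged[-1] = (s0, end, runlist + [run])
        else:
            merged.append((start, end, [run]))

    intervals = []
    for start, end, runlist in merged:
        members = [k for i0, i1 in runlist for k in range(i0, i1 + 1)]
        best = max(members, key=lambda k: (lod[k], -pos[k]))
        flags: list[str] = []
        if suggestive is not None and lod[best] < suggestive:
            flags.append("sub-threshold")
        intervals.append(
            SupportInterval(
                chromosome=chromosome,
                peak_marker=recs[best].marker.name,
                peak_lod=float(lod[best]),
                start_Mb=start,
                end_Mb=end,
                drop=drop,
                merged_from=len(runlist),
                flags=tuple(flags),
            )
        )
    return intervals
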