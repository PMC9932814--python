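"""Expression-trait correlation, cis-eQTL detection, and qPCR quantities.

Microarray expression values are consumed on a log2 normalized scale (one
unit = one doubling of expression); probe values at or below a background
threshold across every strain are flagged.  The eQTL scan reuses the marker
regression engine with a probe's strain values as the phenotype (unit
weights) and calls a cis-eQTL when the genome-wide peak lands on the probed
gene's own chromosome within a window of the gene and clears the suggestive
permutation threshold.

qPCR relative quantities follow the standard 2^-Cq formulation with the
target normalized by the geometric mean of two reference genes, assuming a
perfect amplification efficiency of 2.0 per cycle.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypeMatrix, ValidationError
from . import qtl_scan

#: log2 units; values above this are considered above background.
DEFAULT_BACKGROUND = 7.0

#: cis window: peak within this many Mb of the gene on its own chromosome.
DEFAULT_CIS_WINDOW_MB = 10.0


@dataclass
class ProbeInfo:
    probe: str
    gene: str
    chromosome: str | None = None
    position_Mb: float | None = None


@dataclass
class ExpressionMatrix:
    """Strains x probes log2 expression with probe metadata."""

    strains: list[str]
    probes: list[ProbeInfo]
    values: np.ndarray  # (n_strains, n_probes)
    background: float = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.strains), len(self.probes)):
            raise ValidationError("expression matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must be finite")

    @property
    def probe_names(self) -> list[str]:
        return [p.probe for p in self.probes]

    def probe_index(self, name: str) -> int:
        try:
            return self.probe_names.index(name)
        except ValueError:
            raise KeyError(f"probe {name!r} not in matrix") from None

    def probe_vector(self, name: str) -> dict[str, float]:
        j = self.probe_index(name)
        return {s: float(self.values[i, j]) for i, s in enumerate(self.strains)}

    def below_background(self) -> list[str]:
        """Probes whose values never exceed the background threshold."""
        flagged = (self.values <= self.background).all(axis=0)
        return [p.probe for p, f in zip(self.probes, flagged) if f]


def trait_correlation(
    expr: Mapping[str, float], phen: Mapping[str, float]
) -> tuple[float, int]:
    """Pearson correlation of a probe with strain trait means.

    Only strains present in both tables with finite values are used; returns
    (r, n).  Raises when either vector is constant over the shared strains.
    """
    shared = [
        s
        for s in expr
        if s in phen and math.isfinite(expr[s]) and math.isfinite(phen[s])
    ]
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared strains; need >=3")
    x = np.array([expr[s] for s in shared])
    y = np.array([phen[s] for s in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in expression or trait vector")
    r = stats.pearsonr(x, y).statistic
    return float(r), len(shared)


@dataclass
class EqtlResult:
    scan: qtl_scan.ScanResult
    cis_call: bool | None  # None = indeterminate (gene location missing)
    peak_marker: str
    peak_lod: float
    flags: tuple[str, ...] = ()


def eqtl_scan(
    expr: Mapping[str, float],
    genotypes: GenotypeMatrix,
    probe: ProbeInfo,
    suggestive: float | None = None,
    cis_window_Mb: float = DEFAULT_CIS_WINDOW_MB,
) -> EqtlResult:
    """Map a probe's strain values as a phenotype and call cis vs not.

    cis_call is True when the genome-wide peak marker lies on the probed
    gene's chromosome within ``cis_window_Mb`` of the gene position and the
    peak LOD is at or above the suggestive threshold.  Unit weights are used:
    array strain values carry no replicate SEMs.
    """
    scan = qtl_scan.lod_scan(genotypes, dict(expr), weights=None)
    peak = scan.peak()
    flags: list[str] = []
    if probe.chromosome is None or probe.position_Mb is None:
        return EqtlResult(
            scan, None, peak.marker.name, peak.lod, ("no-gene-location",)
        )
    cis = (
        peak.marker.chromosome == probe.chromosome
        and abs(peak.marker.position_Mb - probe.position_Mb) <= cis_window_Mb
    )
    if suggestive is not None:
        cis = cis and peak.lod >= suggestive
    else:
        flags.append("no-threshold")
    return EqtlResult(scan, bool(cis), peak.marker.name, peak.lod, tuple(flags))


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

#: Assumed amplification efficiency (perfect doubling per cycle).
AMPLIFICATION_EFFICIENCY = 2.0


@dataclass
class QpcrSample:
    """Per-target Cq replicate readings (cycles) for one sample."""

    sample: str
    cq: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target, reps in self.cq.items():
            if not reps:
                raise ValidationError(f"{self.sample}/{target}: no Cq replicates")
            if any(c <= 0 for c in reps):
                raise ValidationError(f"{self.sample}/{target}: Cq must be > 0")

    def mean_cq(self, target: str) -> float:
        if target not in self.cq:
            raise ValidationError(f"{self.sample}: target {target!r} missing")
        return float(np.mean(self.cq[target]))


def qpcr_relative_quantity(
    sample: QpcrSample,
    target: str,
    references: tuple[str, str] = ("Gapdh", "B2m"),
) -> float:
    """Target quantity normalized by the geometric mean of two references.

    quantity = E^-Cq with E = 2; normalized = q_target / geomean(q_ref1,
    q_ref2), which equals 2^(mean(Cq_refs) - Cq_target).
    """
    cq_t = sample.mean_cq(target)
    cq_refs = [sample.mean_cq(r) for r in references]
    # geometric mean of 2^-Cq over refs = 2^-mean(Cq)
    return float(AMPLIFICATION_EFFICIENCY ** (np.mean(cq_refs) - cq_t))


def transcript_ratio(full: float, truncated: float) -> float:
    """Ratio of truncated to full-length normalized transcript quantities."""
    if full <= 0:
        raise ValidationError("full-length quantity must be > 0")
    return truncated / full


def read_qpcr_csv(path: str | os.PathLike) -> list[QpcrSample]:
    """Read a qPCR CSV with columns sample, target, replicate, cq."""
    frame = pd.read_csv(os.fspath(path))
    frame.columns = [c.strip().lower() for c in frame.columns]
    samples: dict[str, dict[str, list[float]]] = {}
    for row in frame.itertuples(index=False):
        samples.setdefault(str(row.sample), {}).setdefault(str(row.target), []).append(
            float(row.cq)
        )
    return [QpcrSample(name, cq) for name, cq in samples.items()]


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | os.PathLike) -> ExpressionMatrix:
    """Read an expression TSV with a probe metadata header block.

    Layout: ``#probe <probe> gene=<g> chrom=<c> Mb=<x>`` comment lines, then
    a table with a ``strain`` column and one column per probe.
    """
    meta: dict[str, ProbeInfo] = {}
    with open(os.fspath(path)) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#probe"):
            parts = ln.split()
            name = parts[1]
            kv = dict(p.split("=", 1) for p in parts[2:] if "=" in p)
            meta[name] = ProbeInfo(
                probe=name,
                gene=kv.get("gene", ""),
                chromosome=kv.get("chrom"),
                position_Mb=float(kv["Mb"]) if "Mb" in kv else None,
            )
        elif ln.startswith("#"):
            continue
        else:
            body_start = i
            break
    frame = pd.read_csv(
        os.fspath(path), sep="\t", skiprows=body_start
    )
    strains = [str(s) for s in frame["strain"]]
    probe_names = [c for c in frame.columns if c != "strain"]
    probes = [meta.get(p, ProbeInfo(p, "")) for p in probe_names]
    values = frame[probe_names].to_numpy(dtype=float)
    return ExpressionMatrix(strains, probes, values)


def write_expression_tsv(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        for p in expr.probes:
            extra = ""
            if p.chromosome is not None:
                extra += f" chrom={p.chromosome}"
            if p.position_Mb is not None:
                extra += f" Mb={p.position_Mb:.6g}"
            fh.write(f"#probe {p.probe} gene={p.gene}{extra}\n")
        fh.write("strain\t" + "\t".join(expr.probe_names) + "\n")
        for i, s in enumerate(expr.strains):
            vals = "\t".join(f"{v:.6g}" for v in expr.values[i])
            fh.write(f"{s}\t{vals}\n")
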