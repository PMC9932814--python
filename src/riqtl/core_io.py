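"""Shared data model and file IO for recombinant-inbred (RI) panel analysis.

The in-memory model is deliberately small: a genotype matrix of two-letter
parental haplotype codes over a genetic/physical marker map, and per-strain
replicate phenotype records with derived summary statistics.  RI strains are
fully inbred, so the genotype alphabet is ``{A, B, U}`` — any other code in an
input file (heterozygote calls included) is recoded to ``U`` (unknown) with a
logged count.

Physical coordinates are held 1-based in megabases; BED output converts to
0-based half-open base pairs.
"""

from __future__ import annotations

import csv
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("riqtl")

GENOTYPE_CODES = ("A", "B", "U")
MISSING_CODE = "U"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerInfo:
    """A genotyped marker with genetic (cM) and physical (Mb) positions."""

    name: str
    chromosome: str
    position_cM: float
    position_Mb: float = math.nan

    @property
    def has_physical(self) -> bool:
        return not math.isnan(self.position_Mb)


@dataclass
class GenotypeMatrix:
    """Strains x markers haplotype calls over an ordered marker map.

    ``calls`` is a ``(n_strains, n_markers)`` array of single-character codes
    in ``{A, B, U}``.  Markers on a chromosome must be strictly increasing in
    cM (and Mb where present) and marker names must be unique.
    """

    strains: list[str]
    markers: list[MarkerInfo]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.strains), len(self.markers)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.strains)} strains x {len(self.markers)} markers"
            )
        if len(set(self.strains)) != len(self.strains):
            raise ValidationError("duplicate strain ids")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate marker names: {', '.join(dupes)}")
        bad = ~np.isin(self.calls, GENOTYPE_CODES)
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} genotype calls outside alphabet {GENOTYPE_CODES}"
            )
        self._check_map_monotone()
        fully_missing = (self.calls == MISSING_CODE).all(axis=1)
        if fully_missing.any():
            who = [s for s, m in zip(self.strains, fully_missing) if m]
            raise ValidationError(f"strains fully missing: {', '.join(who)}")

    def _check_map_monotone(self) -> None:
        by_chrom: dict[str, list[MarkerInfo]] = {}
        for m in self.markers:
            by_chrom.setdefault(m.chromosome, []).append(m)
        for chrom, ms in by_chrom.items():
            cm = [m.position_cM for m in ms]
            if any(b <= a for a, b in zip(cm, cm[1:])):
                raise ValidationError(
                    f"marker map not strictly increasing in cM on chromosome {chrom}"
                )
            mb = [m.position_Mb for m in ms if m.has_physical]
            if any(b <= a for a, b in zip(mb, mb[1:])):
                raise ValidationError(
                    f"marker map not strictly increasing in Mb on chromosome {chrom}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for m in self.markers:
            if m.chromosome not in seen:
                seen.append(m.chromosome)
        return seen

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in map") from None

    def indicator(self) -> np.ndarray:
        """Numeric coding of calls: A -> 1.0, B -> 0.0, U -> NaN."""
        out = np.full(self.calls.shape, np.nan)
        out[self.calls == "A"] = 1.0
        out[self.calls == "B"] = 0.0
        return out

    def subset_strains(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.strains.index(s) for s in keep]
        return GenotypeMatrix(list(keep), list(self.markers), self.calls[idx])

    def to_frame(self) -> pd.DataFrame:
        """Marker-per-row table: marker, chr, cM, Mb, one column per strain."""
        rows = {
            "marker": self.marker_names,
            "chr": [m.chromosome for m in self.markers],
            "cM": [m.position_cM for m in self.markers],
            "Mb": [m.position_Mb for m in self.markers],
        }
        frame = pd.DataFrame(rows)
        for i, strain in enumerate(self.strains):
            frame[strain] = self.calls[:, i]
        return frame


@dataclass
class StrainPhenotype:
    """Replicate trait values (cells/retina) for one strain with summaries.

    ``sem`` and ``cv`` are NaN for single-replicate strains; ``weight`` is
    filled by :func:`assign_weights` (inverse-SEM^2 with median imputation).
    """

    strain: str
    replicates: list[float]
    mean: float = field(init=False)
    sem: float = field(init=False)
    n: int = field(init=False)
    cv: float = field(init=False)
    weight: float = math.nan

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValidationError(f"strain {self.strain}: no replicate values")
        vals = np.asarray(self.replicates, dtype=float)
        self.n = int(vals.size)
        self.mean = float(vals.mean())
        if self.n >= 2:
            sd = float(vals.std(ddof=1))
            self.sem = sd / math.sqrt(self.n)
            self.cv = sd / self.mean if self.mean != 0 else math.nan
        else:
            self.sem = math.nan
            self.cv = math.nan


def assign_weights(phenotypes: Sequence[StrainPhenotype]) -> list[StrainPhenotype]:
    """Set per-strain regression weights w = 1/SEM^2 in place.

    Strains whose SEM is missing (single replicate) or zero receive the
    median weight of the remaining panel; if no strain has a usable SEM all
    weights are 1.  Returns the same list for chaining.
    """
    usable = [p for p in phenotypes if not math.isnan(p.sem) and p.sem > 0]
    weights = {id(p): 1.0 / p.sem**2 for p in usable}
    fallback = float(np.median(list(weights.values()))) if weights else 1.0
    n_imputed = 0
    for p in phenotypes:
        w = weights.get(id(p))
        if w is None:
            w = fallback
            n_imputed += 1
        p.weight = w
    if n_imputed:
        logger.info("assign_weights: %d strains given the panel median weight", n_imputed)
    return list(phenotypes)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _build_matrix(
    strains: list[str],
    records: list[tuple[str, str, float, float, list[str]]],
    source: str,
) -> GenotypeMatrix:
    markers: list[MarkerInfo] = []
    columns: list[list[str]] = []
    n_recoded = 0
    for name, chrom, cm, mb, codes in records:
        if len(codes) != len(strains):
            raise ValidationError(
                f"{source}: marker {name}: {len(codes)} calls for {len(strains)} strains"
            )
        markers.append(MarkerInfo(name, chrom, cm, mb))
        clean = []
        for c in codes:
            c = c.strip().upper()
            if c not in ("A", "B"):
                if c != MISSING_CODE:
                    n_recoded += 1
                c = MISSING_CODE
            clean.append(c)
        columns.append(clean)
    if n_recoded:
        logger.info("%s: %d non-A/B genotype codes recoded to U", source, n_recoded)
    calls = np.array(columns, dtype="<U1").T if columns else np.empty((len(strains), 0), "<U1")
    return GenotypeMatrix(strains, markers, calls)


def read_genotypes(path: str | os.PathLike, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype table from CSV or GeneNetwork-style ``.geno``.

    CSV layout: header ``marker,chr,cM[,Mb],<strain...>``, one marker per row.
    ``.geno`` layout: ``#`` comment and ``@`` metadata lines, then a
    whitespace-delimited header ``Chr Locus cM [Mb] <strain...>`` and one
    marker per row.  Unknown call codes are recoded to U and counted.
    """
    path = os.fspath(path)
    if format is None:
        format = "geno" if path.endswith(".geno") else "csv"
    if format == "csv":
        return _read_genotypes_csv(path)
    if format == "geno":
        return _read_genotypes_geno(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_csv(path: str) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty genotype file") from None
        header = [h.strip() for h in header]
        lowered = [h.lower() for h in header]
        if lowered[:3] != ["marker", "chr", "cm"]:
            raise ValidationError(f"{path}: header must start marker,chr,cM")
        has_mb = len(lowered) > 3 and lowered[3] == "mb"
        strain_start = 4 if has_mb else 3
        strains = header[strain_start:]
        if not strains:
            raise ValidationError(f"{path}: header declares no strains")
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                cm = float(row[2])
                mb = float(row[3]) if has_mb and row[3].strip() else math.nan
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-numeric map position") from None
            records.append((row[0].strip(), row[1].strip(), cm, mb, row[strain_start:]))
    return _build_matrix(strains, records, path)


def _read_genotypes_geno(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [ln for ln in lines if ln.strip() and not ln.startswith(("#", "@"))]
    if not body:
        raise ValidationError(f"{path}: no header row in .geno file")
    header = body[0].split()
    lowered = [h.lower() for h in header]
    if lowered[:3] != ["chr", "locus", "cm"]:
        raise ValidationError(f"{path}: .geno header must start 'Chr Locus cM'")
    has_mb = len(lowered) > 3 and lowered[3] == "mb"
    strain_start = 4 if has_mb else 3
    strains = header[strain_start:]
    if not strains:
        raise ValidationError(f"{path}: .geno header declares no strains")
    records = []
    for ln in body[1:]:
        parts = ln.split()
        try:
            cm = float(parts[2])
            mb = float(parts[3]) if has_mb else math.nan
        except (ValueError, IndexError):
            raise ValidationError(f"{path}: bad map position in line {ln!r}") from None
        records.append((parts[1], parts[0], cm, mb, parts[strain_start:]))
    return _build_matrix(strains, records, path)


def read_phenotypes(path: str | os.PathLike) -> list[StrainPhenotype]:
    """Read a per-retina phenotype CSV with columns ``strain,value``."""
    path = os.fspath(path)
    groups: dict[str, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"{path}: no phenotype rows")
        lowered = [h.strip().lower() for h in header]
        if lowered[:2] != ["strain", "value"]:
            raise ValidationError(f"{path}: header must be strain,value")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            strain = row[0].strip()
            try:
                value = float(row[1])
            except (ValueError, IndexError):
                raise ValidationError(f"{path}:{lineno}: non-numeric value") from None
            groups.setdefault(strain, []).append(value)
    if not groups:
        raise ValidationError(f"{path}: no phenotype rows")
    phens = [StrainPhenotype(s, vals) for s, vals in groups.items()]
    n_single = sum(1 for p in phens if p.n == 1)
    if n_single:
        logger.info("read_phenotypes: %d single-replicate strains (SEM missing)", n_single)
    return phens


# ---------------------------------------------------------------------------
# Writers (all deterministic: fixed column order, fixed float formatting)
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def write_genotypes_csv(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["marker", "chr", "cM", "Mb", *g.strains])
        for j, m in enumerate(g.markers):
            w.writerow(
                [m.name, m.chromosome, _fmt(m.position_cM), _fmt(m.position_Mb), *g.calls[:, j]]
            )


def write_genotypes_geno(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("@type:riset\n@mat:B\n@pat:A\n")
        fh.write("\t".join(["Chr", "Locus", "cM", "Mb", *g.strains]) + "\n")
        for j, m in enumerate(g.markers):
            fh.write(
                "\t".join(
                    [m.chromosome, m.name, _fmt(m.position_cM), _fmt(m.position_Mb), *g.calls[:, j]]
                )
                + "\n"
            )


def write_phenotypes_csv(
    phenotypes: Iterable[StrainPhenotype], path: str | os.PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["strain", "value"])
        for p in phenotypes:
            for v in p.replicates:
                w.writerow([p.strain, _fmt(v)])


def write_scan_tsv(scan, path: str | os.PathLike) -> None:
    """Write a ScanResult as TSV with a fixed header and marker order."""
    with open(path, "w") as fh:
        fh.write("marker\tchr\tcM\tMb\tlod\teffect\tn_used\tflags\n")
        for rec in scan.records:
            m = rec.marker
            fh.write(
                "\t".join(
                    [
                        m.name,
                        m.chromosome,
                        _fmt(m.position_cM),
                        _fmt(m.position_Mb),
                        _fmt(rec.lod),
                        _fmt(rec.effect),
                        str(rec.n_used),
                        ";".join(rec.flags) if rec.flags else ".",
                    ]
                )
                + "\n"
            )


def write_intervals_tsv(intervals, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart_Mb\tend_Mb\tpeak_marker\tpeak_lod\tdrop\tmerged_from\tflags\n"
        )
        for iv in sorted(intervals, key=lambda iv: (iv.chromosome, iv.start_Mb)):
            fh.write(
                "\t".join(
                    [
                        iv.chromosome,
                        _fmt(iv.start_Mb),
                        _fmt(iv.end_Mb),
                        iv.peak_marker,
                        _fmt(iv.peak_lod),
                        _fmt(iv.drop),
                        str(iv.merged_from),
                        ";".join(iv.flags) if iv.flags else ".",
                    ]
                )
                + "\n"
            )


def write_intervals_bed(intervals, path: str | os.PathLike) -> None:
    """BED output: 0-based half-open base pairs from 1-based Mb coordinates."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda iv: (iv.chromosome, iv.start_Mb)):
            start_bp = int(round(iv.start_Mb * 1e6))
            end_bp = int(round(iv.end_Mb * 1e6))
            name = f"{iv.peak_marker}_drop{iv.drop:g}"
            fh.write(f"chr{iv.chromosome}\t{start_bp}\t{end_bp}\t{name}\n")


def write_classifications_tsv(calls, path: str | os.PathLike) -> None:
    """One row per variant with per-rule boolean columns (fixed order)."""
    from .variant_priority import ALL_RULES  # late import avoids a cycle

    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tgene\tfunctional_hp\tregulatory_hp\t"
            + "\t".join(ALL_RULES)
            + "\n"
        )
        for call in calls:
            v = call.variant
            fired = set(call.fired_rules)
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        v.gene,
                        str(call.functional_hp),
                        str(call.regulatory_hp),
                        *[str(r in fired) for r in ALL_RULES],
                    ]
                )
                + "\n"
            )


def read_scan_tsv(path: str | os.PathLike):
    """Rebuild a ScanResult from a scan TSV written by :func:`write_scan_tsv`."""
    from .qtl_scan import ScanRecord, ScanResult  # late import avoids a cycle

    frame = pd.read_csv(os.fspath(path), sep="\t", na_values=["NA"])
    records = []
    for row in frame.itertuples(index=False):
        marker = MarkerInfo(
            str(row.marker),
            str(getattr(row, "chr")),
            float(row.cM),
            float(row.Mb) if not pd.isna(row.Mb) else math.nan,
        )
        flags = () if row.flags in (".", "", None) else tuple(str(row.flags).split(";"))
        records.append(
            ScanRecord(
                marker,
                float(row.lod),
                float(row.effect) if not pd.isna(row.effect) else math.nan,
                int(row.n_used),
                flags,
            )
        )
    return ScanResult(records)


def scan_to_frame(scan) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": [r.marker.name for r in scan.records],
            "chr": [r.marker.chromosome for r in scan.records],
            "cM": [r.marker.position_cM for r in scan.records],
            "Mb": [r.marker.position_Mb for r in scan.records],
            "lod": [r.lod for r in scan.records],
            "effect": [r.effect for r in scan.records],
            "n_used": [r.n_used for r in scan.records],
            "flags": [";".join(r.flags) if r.flags else "." for r in scan.records],
        }
    )
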