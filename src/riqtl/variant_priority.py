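"""Rule-based prioritization of sequence variants and candidate genes.

Variants discriminating the two parental genomes inside a QTL interval are
sorted into high-priority *functional* variants (expected to alter the
protein) and high-priority *regulatory* variants (expected to alter
expression).  The rules are deliberately mechanical so every call is
auditable from the list of fired rule ids:

Functional
    F1  frameshift or stop gained/lost
    F2  missense changing the amino-acid side-chain group, or falling in an
        annotated domain / membrane-spanning region
    F3  small in-frame indel inside an annotated domain
    F4  any splice-site/region consequence

Regulatory
    R1  SNP/INDEL in the proximal promoter (within 500 bp of a TSS) or in a
        5'/3' UTR, co-occurring with an evolutionarily conserved region (ECR)
    R2  structural variant anywhere within a gene, inside an ECR
    R3  3'UTR variant that disrupts or creates a predicted microRNA site

An ECR here means: the 100-bp window centred on the variant intersects a
conserved interval in two or more species' conservation tracks.

Candidate genes are then ranked on three criteria — at least one
high-priority variant, retinal/AII expression, and a function plausibly
affecting cell number (gene regulation, proliferation, apoptosis) — with
"top candidates" meeting all three.

Consequence, domain, TSS and microRNA annotations are consumed as
pre-computed input fields; this module performs no sequence analysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import ValidationError

#: Controlled vocabulary for variant consequences.
CONSEQUENCE_TERMS = frozenset(
    {
        "frameshift",
        "stop_gained",
        "stop_lost",
        "missense",
        "inframe_indel",
        "splice_region",
        "splice_donor",
        "splice_acceptor",
        "synonymous",
        "intronic",
        "utr5",
        "utr3",
        "upstream",
        "downstream",
        "intergenic",
    }
)

SPLICE_TERMS = frozenset({"splice_region", "splice_donor", "splice_acceptor"})

FUNCTIONAL_RULES = ("F1", "F2", "F3", "F4")
REGULATORY_RULES = ("R1", "R2", "R3")
ALL_RULES = FUNCTIONAL_RULES + REGULATORY_RULES

#: Proximal promoter half-width around a transcriptional start site (bp).
TSS_WINDOW_BP = 500

#: Half-width of the conservation window centred on a variant (bp).
ECR_HALF_WINDOW_BP = 50

#: Minimum number of species whose conservation track must intersect.
ECR_MIN_SPECIES = 2

# Amino-acid side-chain groups (one-letter codes).  Glycine is kept apart as
# "special"; a change into or out of any group — special included — counts as
# a side-chain group difference.
SIDE_CHAIN_GROUPS: dict[str, str] = {}
for _aa in "AVLIMFWP":
    SIDE_CHAIN_GROUPS[_aa] = "nonpolar"
for _aa in "STNQYC":
    SIDE_CHAIN_GROUPS[_aa] = "polar"
for _aa in "KRH":
    SIDE_CHAIN_GROUPS[_aa] = "positive"
for _aa in "DE":
    SIDE_CHAIN_GROUPS[_aa] = "negative"
SIDE_CHAIN_GROUPS["G"] = "special"


def side_chain_group(aa: str) -> str:
    """Side-chain group of a one-letter amino-acid code."""
    try:
        return SIDE_CHAIN_GROUPS[aa.upper()]
    except KeyError:
        raise ValidationError(f"unknown amino-acid code {aa!r}") from None


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based bp
    ref: str
    alt: str
    vclass: str  # SNP | INDEL | SV
    consequences: frozenset[str]
    gene: str = ""
    aa_ref: str | None = None
    aa_alt: str | None = None
    in_domain: bool = False
    tss_distance: float | None = None  # bp, signed; None when unknown
    in_ecr: bool | None = None  # None -> derive from conservation tracks
    mirna_site_change: bool = False

    def __post_init__(self) -> None:
        if self.vclass not in ("SNP", "INDEL", "SV"):
            raise ValidationError(f"unknown variant class {self.vclass!r}")
        self.consequences = frozenset(self.consequences)
        unknown = self.consequences - CONSEQUENCE_TERMS
        if unknown:
            raise ValidationError(f"unknown consequence terms: {sorted(unknown)}")
        if self.vclass == "SNP" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValidationError(
                f"{self.chrom}:{self.pos}: SNP requires single-base ref/alt"
            )
        has_aa = self.aa_ref is not None and self.aa_alt is not None
        if "missense" in self.consequences and not has_aa:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: missense variant lacks amino-acid fields"
            )
        if has_aa and "missense" not in self.consequences:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: amino-acid fields without missense consequence"
            )


@dataclass
class PriorityCall:
    variant: VariantRecord
    functional_hp: bool
    regulatory_hp: bool
    fired_rules: tuple[str, ...]


@dataclass
class GeneEvidence:
    gene: str
    hp_variant_count: int
    expressed: bool
    function_relevant: bool

    def __post_init__(self) -> None:
        if self.hp_variant_count < 0:
            raise ValidationError("hp_variant_count must be >= 0")


# ---------------------------------------------------------------------------
# ECR overlap
# ---------------------------------------------------------------------------


def ecr_overlap(
    chrom: str,
    pos: int,
    conservation: Mapping[str, Sequence[tuple[str, int, int]]],
) -> bool:
    """Is the 100-bp window around ``pos`` conserved in >=2 species?

    ``conservation`` maps species name to a list of BED-style intervals
    (chrom, start, end), 0-based half-open in bp.  The window spans
    pos-50 .. pos+50 inclusive in 1-based coordinates.
    """
    win_start = pos - ECR_HALF_WINDOW_BP - 1  # 0-based
    win_end = pos + ECR_HALF_WINDOW_BP  # half-open
    n_species = 0
    for intervals in conservation.values():
        for c, s, e in intervals:
            if c == chrom and s < win_end and e > win_start:
                n_species += 1
                break
    return n_species >= ECR_MIN_SPECIES


def read_ecr_tracks(paths: Mapping[str, str | os.PathLike]) -> dict[str, list[tuple[str, int, int]]]:
    """Read per-species conserved-interval BED files (chrom, start, end)."""
    tracks: dict[str, list[tuple[str, int, int]]] = {}
    for species, path in paths.items():
        frame = pd.read_csv(
            os.fspath(path),
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            comment="#",
        )
        tracks[species] = [
            (str(r.chrom), int(r.start), int(r.end)) for r in frame.itertuples()
        ]
    return tracks


# ---------------------------------------------------------------------------
# Classification rules
# ---------------------------------------------------------------------------


def classify_functional(v: VariantRecord) -> PriorityCall:
    """Apply functional rules F1-F4 to one variant."""
    fired: list[str] = []
    if v.consequences & {"frameshift", "stop_gained", "stop_lost"}:
        fired.append("F1")
    if "missense" in v.consequences:
        if v.aa_ref is None or v.aa_alt is None:
            raise ValidationError("missense variant lacks amino-acid fields")
        group_change = side_chain_group(v.aa_ref) != side_chain_group(v.aa_alt)
        if group_change or v.in_domain:
            fired.append("F2")
    if "inframe_indel" in v.consequences and v.in_domain:
        fired.append("F3")
    if v.consequences & SPLICE_TERMS:
        fired.append("F4")
    return PriorityCall(v, bool(fired), False, tuple(fired))


def classify_regulatory(
    v: VariantRecord,
    conservation: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
    ecr_mode: str = "and",
) -> PriorityCall:
    """Apply regulatory rules R1-R3 to one variant.

    ``in_ecr`` is taken from the record when set, otherwise derived from the
    conservation tracks.  ``ecr_mode="and"`` (default) requires promoter/UTR
    SNPs and INDELs to co-occur with an ECR; ``"or"`` accepts location alone.
    """
    if ecr_mode not in ("and", "or"):
        raise ValidationError(f"ecr_mode must be 'and' or 'or', got {ecr_mode!r}")
    in_utr5 = "utr5" in v.consequences
    in_utr3 = "utr3" in v.consequences
    near_tss = v.tss_distance is not None and abs(v.tss_distance) <= TSS_WINDOW_BP
    location_ok = near_tss or in_utr5 or in_utr3
    within_gene = bool(v.consequences) and "intergenic" not in v.consequences

    needs_ecr = (v.vclass in ("SNP", "INDEL") and location_ok and ecr_mode == "and") or (
        v.vclass == "SV" and within_gene
    )
    in_ecr = v.in_ecr
    if in_ecr is None:
        if conservation is None:
            if needs_ecr:
                raise ValidationError(
                    f"{v.chrom}:{v.pos}: conservation evidence required"
                )
            in_ecr = False
        else:
            in_ecr = ecr_overlap(v.chrom, v.pos, conservation)

    fired: list[str] = []
    if v.vclass in ("SNP", "INDEL") and location_ok and (in_ecr or ecr_mode == "or"):
        fired.append("R1")
    if v.vclass == "SV" and within_gene and in_ecr:
        fired.append("R2")
    if in_utr3 and v.mirna_site_change:
        fired.append("R3")
    return PriorityCall(v, False, bool(fired), tuple(fired))


def classify(
    v: VariantRecord,
    conservation: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
    ecr_mode: str = "and",
) -> PriorityCall:
    """Combined functional + regulatory call (a variant may be both)."""
    f = classify_functional(v)
    r = classify_regulatory(v, conservation, ecr_mode)
    return PriorityCall(
        v, f.functional_hp, r.regulatory_hp, f.fired_rules + r.fired_rules
    )


def classify_all(
    variants: Iterable[VariantRecord],
    conservation: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
    ecr_mode: str = "and",
) -> list[PriorityCall]:
    return [classify(v, conservation, ecr_mode) for v in variants]


# ---------------------------------------------------------------------------
# Candidate-gene ranking
# ---------------------------------------------------------------------------

VENN_REGIONS = (
    "variants+expressed+function",
    "variants+expressed",
    "variants+function",
    "expressed+function",
    "variants",
    "expressed",
    "function",
    "none",
)


def _venn_region(has_variants: bool, expressed: bool, relevant: bool) -> str:
    parts = []
    if has_variants:
        parts.append("variants")
    if expressed:
        parts.append("expressed")
    if relevant:
        parts.append("function")
    return "+".join(parts) if parts else "none"


@dataclass
class RankedCandidates:
    table: pd.DataFrame  # per-gene rows with region and top flag
    venn_counts: dict[str, int]
    top_candidates: list[str]


def rank_candidates(evidence: Sequence[GeneEvidence]) -> RankedCandidates:
    """Assign Venn regions over the three criteria and rank top candidates.

    Top candidates carry at least one high-priority variant, are expressed in
    the developing retina and/or AII amacrine cells, and have a relevant
    function; they are sub-ranked by variant count (descending), then gene id.
    """
    genes = [e.gene for e in evidence]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValidationError(f"duplicate gene rows: {', '.join(dupes)}")
    rows = []
    for e in evidence:
        has_v = e.hp_variant_count >= 1
        region = _venn_region(has_v, e.expressed, e.function_relevant)
        rows.append(
            {
                "gene": e.gene,
                "hp_variant_count": e.hp_variant_count,
                "expressed": e.expressed,
                "function_relevant": e.function_relevant,
                "venn_region": region,
                "top_candidate": region == "variants+expressed+function",
            }
        )
    table = pd.DataFrame(rows)
    counts = {region: 0 for region in VENN_REGIONS}
    for r in rows:
        counts[r["venn_region"]] += 1
    top = sorted(
        (r for r in rows if r["top_candidate"]),
        key=lambda r: (-r["hp_variant_count"], r["gene"]),
    )
    table = table.sort_values(
        ["top_candidate", "hp_variant_count", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return RankedCandidates(table, counts, [r["gene"] for r in top])


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return _BOOL[str(x).strip().lower()]


def read_variants_tsv(path: str | os.PathLike) -> list[VariantRecord]:
    """Read variants from TSV with the VariantRecord columns.

    Expected columns: chrom, pos, ref, alt, vclass, consequences
    (comma-separated terms), gene, aa_ref, aa_alt, in_domain, tss_distance,
    in_ecr, mirna_site_change.  Empty aa/tss/in_ecr cells mean "not set".
    """
    frame = pd.read_csv(os.fspath(path), sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        records.append(
            VariantRecord(
                chrom=d["chrom"],
                pos=int(d["pos"]),
                ref=d["ref"],
                alt=d["alt"],
                vclass=d["vclass"],
                consequences=frozenset(
                    t.strip() for t in d["consequences"].split(",") if t.strip()
                ),
                gene=d.get("gene", ""),
                aa_ref=d["aa_ref"] or None if "aa_ref" in d else None,
                aa_alt=d["aa_alt"] or None if "aa_alt" in d else None,
                in_domain=_parse_bool(d.get("in_domain", "false") or "false"),
                tss_distance=float(d["tss_distance"])
                if d.get("tss_distance", "") != ""
                else None,
                in_ecr=_parse_bool(d["in_ecr"]) if d.get("in_ecr", "") != "" else None,
                mirna_site_change=_parse_bool(
                    d.get("mirna_site_change", "false") or "false"
                ),
            )
        )
    return records


def write_variants_tsv(
    variants: Iterable[VariantRecord], path: str | os.PathLike
) -> None:
    """Write variants in the TSV layout :func:`read_variants_tsv` reads."""
    cols = [
        "chrom",
        "pos",
        "ref",
        "alt",
        "vclass",
        "consequences",
        "gene",
        "aa_ref",
        "aa_alt",
        "in_domain",
        "tss_distance",
        "in_ecr",
        "mirna_site_change",
    ]
    with open(os.fspath(path), "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        v.vclass,
                        ",".join(sorted(v.consequences)),
                        v.gene,
                        v.aa_ref or "",
                        v.aa_alt or "",
                        str(v.in_domain).lower(),
                        f"{v.tss_distance:g}" if v.tss_distance is not None else "",
                        "" if v.in_ecr is None else str(v.in_ecr).lower(),
                        str(v.mirna_site_change).lower(),
                    ]
                )
                + "\n"
            )


def read_gene_evidence_tsv(path: str | os.PathLike) -> list[GeneEvidence]:
    """Read a gene-evidence TSV: gene, hp_variant_count, expressed, function_relevant."""
    frame = pd.read_csv(os.fspath(path), sep="\t", dtype=str, keep_default_na=False)
    return [
        GeneEvidence(
            gene=row.gene,
            hp_variant_count=int(row.hp_variant_count),
            expressed=_parse_bool(row.expressed),
            function_relevant=_parse_bool(row.function_relevant),
        )
        for row in frame.itertuples(index=False)
    ]
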