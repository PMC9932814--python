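"""Shared golden fixture set for the variant-prioritization rules.

Builds the full cross-product of consequence x domain x side-chain-change x
location x conservation x microRNA flags (>=200 concrete variant records)
together with hand-coded expected rule firings, written independently of the
classifier implementation.
"""

import itertools

from riqtl.variant_priority import VariantRecord

CONSEQUENCES = (
    "frameshift",
    "stop_gained",
    "missense",
    "inframe_indel",
    "splice_region",
    "synonymous",
    "intronic",
    "intergenic",
)


def expected_rules(cons, vclass, domain, group_change, location, ecr, mirna):
    """Hand-written expectation table (default, ECR-conjunctive reading)."""
    fired = set()
    if cons in ("frameshift", "stop_gained", "stop_lost"):
        fired.add("F1")
    if cons == "missense" and (group_change or domain):
        fired.add("F2")
    if cons == "inframe_indel" and domain:
        fired.add("F3")
    if cons in ("splice_region", "splice_donor", "splice_acceptor"):
        fired.add("F4")
    near_promoter_or_utr = location in ("tss", "utr5", "utr3")
    if vclass in ("SNP", "INDEL") and near_promoter_or_utr and ecr:
        fired.add("R1")
    if vclass == "SV" and cons != "intergenic" and ecr:
        fired.add("R2")
    if location == "utr3" and mirna:
        fired.add("R3")
    return fired


def build_cases():
    """Yield (VariantRecord, expected_fired_rules) over the cross-product."""
    for cons, domain, group_change, location, ecr, mirna in itertools.product(
        CONSEQUENCES,
        [False, True],
        [False, True],
        ["none", "tss", "utr5", "utr3"],
        [False, True],
        [False, True],
    ):
        if group_change and cons != "missense":
            continue
        cons_set = {cons}
        if location == "utr5":
            cons_set.add("utr5")
        if location == "utr3":
            cons_set.add("utr3")
        kw = dict(
            chrom="9",
            pos=46_000_100,
            ref="A",
            alt="G",
            vclass="SNP",
            gene="GeneA",
            consequences=frozenset(cons_set),
            in_domain=domain,
            tss_distance=100.0 if location == "tss" else 10_000.0,
            in_ecr=ecr,
            mirna_site_change=mirna,
        )
        if cons == "missense":
            kw["aa_ref"], kw["aa_alt"] = ("I", "T") if group_change else ("L", "I")
        if cons in ("frameshift", "inframe_indel"):
            kw.update(ref="A", alt="AGT", vclass="INDEL")
        if cons == "intergenic":
            kw.update(alt="<DEL>", vclass="SV")
        record = VariantRecord(**kw)
        yield record, expected_rules(
            cons, record.vclass, domain, group_change, location, ecr, mirna
        )
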