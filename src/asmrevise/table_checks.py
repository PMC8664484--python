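"""Part-of relations for the shipped census tables.

Integer columns validate exactly; percentage columns use an absolute
tolerance of 0.01 (two printed decimals).
"""

from __future__ import annotations

from .data import load_table
from .report import PartOf, Violation, frame_to_values, validate_totals

PCT_TOL = 0.01

CHROMS = [f"Chr{i}" for i in range(1, 8)]

TE_CLASSES = [
    "LTR/Gypsy", "LTR/Copia", "LTR/Unknown", "Non-LTR/LINE", "Non-LTR/SINE",
    "CACTA", "Mutator", "PIF-Harbinger", "Tc1-Mariner", "hAT", "Helitron",
    "MITE/Stowaway", "MITE/Tourist", "DNA/unknown", "Unspecified",
]

RGA_CATEGORIES = ["NBS", "CNL", "TNL", "CN", "TN", "NL", "RLP", "RLK", "TM_CC"]


def census_relations(columns=("total_length", "gap_length",
                              "effective_length", "gap_number")):
    rels = []
    for col in columns:
        rels.append(PartOf(f"Total/{col}",
                           tuple(f"{c}/{col}" for c in CHROMS)))
    # effective = total - gap, expressed as total = effective + gap
    for row in CHROMS + ["Total"]:
        rels.append(PartOf(f"{row}/total_length",
                           (f"{row}/effective_length", f"{row}/gap_length")))
    return rels


def check_census(name: str) -> list[Violation]:
    values = frame_to_values(load_table(name), "seq_id")
    return validate_totals(values, census_relations())


def check_te_classes() -> list[Violation]:
    values = frame_to_values(load_table("aet_te_classes_v50"), "class")
    rels = []
    for col, tol in (("elements", 0.0), ("length_bp", 0.0),
                     ("genome_pct", PCT_TOL)):
        rels.append(PartOf(f"Total interspersed/{col}",
                           tuple(f"{c}/{col}" for c in TE_CLASSES), tol))
        rels.append(PartOf(f"Total/{col}",
                           (f"Total interspersed/{col}",
                            f"Low complexity/{col}", f"Simple repeat/{col}"),
                           tol))
    return validate_totals(values, rels)


def check_intact_ltr() -> list[Violation]:
    values = frame_to_values(load_table("aet_intact_ltr"), "chrom")
    rels = [PartOf(f"Total/{col}", tuple(f"{c}/{col}" for c in CHROMS))
            for col in ("copia_v40", "copia_v50", "gypsy_v40", "gypsy_v50",
                        "unknown_v40", "unknown_v50")]
    return validate_totals(values, rels)


def check_gene_annotation() -> list[Violation]:
    values = frame_to_values(load_table("aet_gene_annotation"), "metric")
    rels = [PartOf(f"total_genes/{col}",
                   (f"single_exon_genes/{col}", f"multi_exon_genes/{col}"))
            for col in ("hc_v40", "lc_v40", "hc_v50", "lc_v50")]
    return validate_totals(values, rels)


def check_rga() -> list[Violation]:
    values = frame_to_values(load_table("aet_rga_counts"), "species")
    rels = [PartOf(f"{sp}/total",
                   tuple(f"{sp}/{c}" for c in RGA_CATEGORIES))
            for sp in ("Ae_tauschii", "T_aestivum_D")]
    return validate_totals(values, rels)


def check_busco() -> list[Violation]:
    values = frame_to_values(load_table("aet_busco"), "annotation")
    rels = [PartOf(f"{v}/total",
                   (f"{v}/complete_single", f"{v}/complete_duplicated",
                    f"{v}/fragmented", f"{v}/missing"))
            for v in ("v40", "v50")]
    return validate_totals(values, rels)


def check_all_tables() -> list[Violation]:
    out = []
    out += check_census("aet_census_v40")
    out += check_census("aet_census_v50")
    out += check_te_classes()
    out += check_intact_ltr()
    out += check_gene_annotation()
    out += check_rga()
    out += check_busco()
    return out
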