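"""Controlled vocabulary for thiamin (B1)-related genes and compounds.

Gene labels follow the standard bacterial nomenclature for thiamin
biosynthesis, transport, and salvage. Everything downstream (annotation
curation, genotype calling, abundance profiling) is restricted to this
vocabulary plus the two structural labels ``marker`` (universal single-copy
marker gene) and ``riboswitch_TDP`` (thiamin-diphosphate riboswitch,
THI-box / RF00059).
"""

from __future__ import annotations

#: De novo synthesis core: pyrimidine branch (thiC), thiazole branch (thiG),
#: and the condensing thiamin-monophosphate synthase (thiE). Prototrophy
#: requires all three.
SYNTHESIS_GENES: tuple[str, ...] = ("thiC", "thiG", "thiE")

#: Transporters for intact B1 (or its phosphates): ThiBPQ ABC transporter
#: binding protein and the energy-coupled ThiT transporter.
B1_TRANSPORT_GENES: tuple[str, ...] = ("thiB", "thiT")

#: Putative transporters for B1 and/or pyrimidine vitamers.
PUTATIVE_TRANSPORT_GENES: tuple[str, ...] = (
    "thiV", "thiY", "cytX", "ykoF", "thiPerm", "omr1",
)

#: Salvage enzymes rebuilding B1 from vitamers: thiaminase II (tenA,
#: pyrimidine route) and thiazole kinase (thiM, thiazole route).
SALVAGE_GENES: tuple[str, ...] = ("tenA", "thiM")

#: The full 13-gene vocabulary, in a fixed canonical order.
B1_GENES: tuple[str, ...] = (
    SYNTHESIS_GENES + B1_TRANSPORT_GENES + PUTATIVE_TRANSPORT_GENES + SALVAGE_GENES
)

#: Genes reported in the acquisition repertoire of a genotype call.
ACQUISITION_GENES: tuple[str, ...] = (
    B1_TRANSPORT_GENES + PUTATIVE_TRANSPORT_GENES + SALVAGE_GENES
)

MARKER_LABEL = "marker"
RIBOSWITCH_LABEL = "riboswitch_TDP"

#: Targeted compounds: thiamin, thiamin monophosphate, and the pyrimidine
#: (HMP, AmMP, FAMP) and thiazole (HET, cHET) vitamers.
COMPOUNDS: tuple[str, ...] = ("B1", "TMP", "HMP", "HET", "FAMP", "AmMP", "cHET")

#: Typical bacterial gene lengths in bp, used by the synthetic generator.
TYPICAL_GENE_LENGTH_BP: dict[str, int] = {
    "thiC": 1890,
    "thiG": 770,
    "thiE": 630,
    "thiB": 980,
    "thiT": 550,
    "thiV": 1450,
    "thiY": 990,
    "cytX": 1300,
    "ykoF": 600,
    "tenA": 690,
    "thiM": 810,
    "thiPerm": 1200,
    "omr1": 2100,
}

RIBOSWITCH_LENGTH_BP = 110


def check_gene_labels(labels) -> None:
    """Raise ``ValueError`` if any label is outside the B1 vocabulary."""
    unknown = set(labels) - set(B1_GENES)
    if unknown:
        raise ValueError(
            f"unknown B1 gene label(s): {sorted(unknown)}; "
            f"allowed: {list(B1_GENES)}"
        )
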