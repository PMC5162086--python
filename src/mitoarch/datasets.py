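"""Published arrangement fixtures for molluscan mitogenomes.

The monoplacophoran arrangements (*Laevipilina antarctica*, *Vema ewingi*)
are the published two-strand gene-order strings for those genomes; both
strings are listed in genome positional order, with the second cluster
transcribed on the opposite strand.  The *Vema* order differs from
*L. antarctica* only in the position of trnC, which sits inside the
GEWDCYKNM tRNA complex instead of next to trnS1.

The remaining entries are reconstructions from published descriptions rather
than verbatim deposits: the *L. hyalina* partial order (the *L. antarctica*
order minus the genes reported missing -- atp8, trnT, trnC, trnW, trnG,
trnH, trnE -- with a second trnK adjacent to cox2), a
protein-coding/rRNA view of *Katharina tunicata* (conserved cluster 1
forward, cluster 2 inverted), a *Sypharochiton* arrangement (monoplacophoran
cluster orientations with the INRAK and EGQWYCM tRNA complexes), and the
lophotrochozoan ground pattern restricted to PCGs and rRNAs (both clusters
forward).  They carry the cluster-level and tRNA-complex structure needed for
comparative analysis, not base-accurate coordinates.
"""

from __future__ import annotations

from .io_annotations import parse_arrangement_string
from .records import MitogenomeRecord

LAEVIPILINA_ANTARCTICA_PLUS = (
    "trnT-atp6-atp8-cox2-cox1-nad2-trnC-trnS1-nad3-trnA-trnR-trnI-cox3-trnG"
)
LAEVIPILINA_ANTARCTICA_MINUS = (
    "trnE-trnW-trnD-trnY-trnK-trnN-trnM-rrnS-trnV-rrnL-trnL1-trnL2-nad1-"
    "trnP-nad6-cob-trnS2-nad4L-nad4-trnQ-trnH-nad5-trnF"
)

VEMA_EWINGI_PLUS = (
    "trnT-atp6-atp8-cox2-cox1-nad2-trnS1-nad3-trnA-trnR-trnI-cox3-trnG"
)
VEMA_EWINGI_MINUS = (
    "trnE-trnW-trnD-trnC-trnY-trnK-trnN-trnM-rrnS-trnV-rrnL-trnL1-trnL2-"
    "nad1-trnP-nad6-cob-trnS2-nad4L-nad4-trnQ-trnH-nad5-trnF"
)

# partial genome: atp8 and the tRNAs T, C, W, G, H, E missing; trnK
# duplicated, second copy adjacent to cox2
LAEVIPILINA_HYALINA_PLUS = (
    "atp6-cox2-trnK.2-cox1-nad2-trnS1-nad3-trnA-trnR-trnI-cox3"
)
LAEVIPILINA_HYALINA_MINUS = (
    "trnD-trnY-trnK.1-trnN-trnM-rrnS-trnV-rrnL-trnL1-trnL2-nad1-trnP-nad6-"
    "cob-trnS2-nad4L-nad4-trnQ-nad5-trnF"
)

# reconstruction: both conserved clusters forward (PCG+rRNA view)
GROUND_PATTERN_PLUS = (
    "cox3-nad3-nad2-cox1-cox2-atp8-atp6-rrnS-rrnL-nad1-nad6-cob-nad4L-"
    "nad4-nad5"
)

# reconstruction: cluster 1 forward, cluster 2 inverted (PCG+rRNA view)
KATHARINA_PLUS = "cox3-nad3-nad2-cox1-cox2-atp8-atp6"
KATHARINA_MINUS = "nad5-nad4-nad4L-cob-nad6-nad1-rrnL-rrnS"

# reconstruction: monoplacophoran cluster orientations, chitonine tRNA
# complexes INRAK and EGQWYCM
SYPHAROCHITON_PLUS = (
    "trnT-atp6-atp8-trnD-cox2-cox1-nad2-trnS1-nad3-trnI-trnN-trnR-trnA-"
    "trnK-cox3"
)
SYPHAROCHITON_MINUS = (
    "trnE-trnG-trnQ-trnW-trnY-trnC-trnM-rrnS-trnV-rrnL-trnL1-trnL2-nad1-"
    "trnP-nad6-cob-trnS2-nad4L-nad4-trnH-nad5-trnF"
)


def laevipilina_antarctica() -> MitogenomeRecord:
    """The printed complete *L. antarctica* arrangement (37 genes)."""
    return parse_arrangement_string(
        LAEVIPILINA_ANTARCTICA_PLUS, LAEVIPILINA_ANTARCTICA_MINUS,
        taxon="Laevipilina antarctica")


def vema_ewingi() -> MitogenomeRecord:
    """The printed complete *Vema ewingi* arrangement (37 genes)."""
    return parse_arrangement_string(
        VEMA_EWINGI_PLUS, VEMA_EWINGI_MINUS, taxon="Vema ewingi")


def laevipilina_hyalina() -> MitogenomeRecord:
    """Reconstructed partial *L. hyalina* arrangement (31 features, two trnK)."""
    return parse_arrangement_string(
        LAEVIPILINA_HYALINA_PLUS, LAEVIPILINA_HYALINA_MINUS,
        taxon="Laevipilina hyalina")


def ground_pattern() -> MitogenomeRecord:
    """Lophotrochozoan ground pattern, PCG+rRNA view (clusters forward)."""
    return parse_arrangement_string(
        GROUND_PATTERN_PLUS, "", taxon="Lophotrochozoan ground pattern")


def katharina_tunicata() -> MitogenomeRecord:
    """Reconstructed *Katharina tunicata* PCG+rRNA view (cluster 2 inverted)."""
    return parse_arrangement_string(
        KATHARINA_PLUS, KATHARINA_MINUS, taxon="Katharina tunicata")


def sypharochiton() -> MitogenomeRecord:
    """Reconstructed *Sypharochiton* arrangement (monoplacophoran clusters)."""
    return parse_arrangement_string(
        SYPHAROCHITON_PLUS, SYPHAROCHITON_MINUS, taxon="Sypharochiton spp.")


def monoplacophora() -> list[MitogenomeRecord]:
    """The three monoplacophoran arrangements."""
    return [laevipilina_antarctica(), vema_ewingi(), laevipilina_hyalina()]
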