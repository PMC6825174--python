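"""Published degenerate primer panel for Lamiaceae triterpenic-acid genes.

Six primer pairs targeting the triterpenic-acid biosynthetic genes FDS
(farnesyl pyrophosphate synthase), SQS (squalene synthase), SQE (squalene
epoxidase) and the oxidosqualene cyclases LUS, BAS and MFAS, as validated by
RT-PCR across *Rosmarinus officinalis*, *Salvia officinalis* and *Thymus
persicus*.  Used here as a reference input for IUPAC-algebra and design-rule
checks; product sizes are the published cDNA amplicon lengths in bp.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PanelPrimer:
    gene: str
    name: str
    direction: str  # "forward" | "reverse"
    sequence: str  # 5' -> 3', IUPAC
    amplicon_bp: int  # published product size for the pair


PUBLISHED_PANEL: list[PanelPrimer] = [
    PanelPrimer("FDS", "FDSFwd", "forward", "CATCGCCGCATTGTWCAG", 187),
    PanelPrimer("FDS", "FDSRev", "reverse", "CAATCTTTTCRGGCTCACC", 187),
    PanelPrimer("SQS", "SQSFwd", "forward", "GCTTGACACWGTTGAGGA", 111),
    PanelPrimer("SQS", "SQSRev", "reverse", "GTACCRCATGAAAAATGCCA", 111),
    PanelPrimer("SQE", "SQEFwd", "forward", "GACCATGCCMAACAGAAG", 209),
    PanelPrimer("SQE", "SQERev", "reverse", "TGTAGAAGGAYTCAAGATACT", 209),
    PanelPrimer("LUS", "LUSFwd", "forward", "ATCAGAAYGAAGATGGAGG", 200),
    PanelPrimer("LUS", "LUSRev", "reverse", "CCARAACTTTCCCCACGA", 200),
    PanelPrimer("BAS", "BASFwd", "forward", "GGAATGAAGATGCAGAGYTT", 227),
    PanelPrimer("BAS", "BASRev", "reverse", "TGCCATCCATGATCTTGRTC", 227),
    PanelPrimer("MFAS", "MFASFwd", "forward", "TCNTGGGGAAAGACNTAT", 131),
    PanelPrimer("MFAS", "MFASRev", "reverse", "CGGCARTAACACCACAT", 131),
]
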