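"""Perfluoroalkyl acid (PFAA) homolog definitions.

PFAAs split into two families: perfluoroalkyl carboxylic acids (PFCAs,
e.g. PFOA) and perfluoroalkane sulfonic acids (PFSAs, e.g. PFOS).
PFOS occurs as linear and branched isomers which are quantified
separately but pooled for downstream flux estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Family = Literal["PFCA", "PFSA"]
Isomer = Literal["linear", "branched", "sum"]


@dataclass(frozen=True)
class PFAAHomolog:
    """A single PFAA homolog.

    ``chain_length`` is the number of carbons in the perfluoroalkyl
    backbone (including the carboxyl carbon for PFCAs).
    """

    id: str
    family: Family
    chain_length: int
    isomer: Isomer = "linear"

    def __post_init__(self) -> None:
        if self.chain_length < 3:
            raise ValueError(
                f"{self.id}: perfluoroalkyl chain length must be >= 3, "
                f"got {self.chain_length}"
            )


#: The ten target PFAAs (7 PFCAs, 3 PFSAs; PFOS as linear + branched).
DEFAULT_HOMOLOGS: tuple[PFAAHomolog, ...] = (
    PFAAHomolog("PFHxA", "PFCA", 6),
    PFAAHomolog("PFHpA", "PFCA", 7),
    PFAAHomolog("PFOA", "PFCA", 8),
    PFAAHomolog("PFNA", "PFCA", 9),
    PFAAHomolog("PFDA", "PFCA", 10),
    PFAAHomolog("PFUnDA", "PFCA", 11),
    PFAAHomolog("PFDoDA", "PFCA", 12),
    PFAAHomolog("PFBS", "PFSA", 4),
    PFAAHomolog("PFHxS", "PFSA", 6),
    PFAAHomolog("L-PFOS", "PFSA", 8, "linear"),
    PFAAHomolog("B-PFOS", "PFSA", 8, "branched"),
)


def homolog_by_id(hid: str) -> PFAAHomolog:
    for h in DEFAULT_HOMOLOGS:
        if h.id == hid:
            return h
    raise KeyError(f"unknown homolog id: {hid!r}")
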