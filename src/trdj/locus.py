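"""Published annotation bookkeeping for the sheep TRA/TRD locus.

Desk-level quantities recomputed from the study's printed tables: the
functionality tallies of the annotated germline V repertoire and the
unplaced-scaffold inventory that extends the chromosome 7 locus.
"""

from __future__ import annotations

# 24 unplaced genomic scaffolds carrying extra TRAV/TRDV genes (name -> bp).
UNPLACED_SCAFFOLDS: dict[str, int] = {
    "NW_004080312": 20236,
    "NW_004084646": 5428,
    "NW_004084647": 5868,
    "NW_004080344": 6398,
    "NW_004080351": 2921,
    "NW_004080352": 6415,
    "NW_004080507": 8138,
    "NW_004080664": 6480,
    "NW_004080708": 3005,
    "NW_004080772": 15309,
    "NW_004080962": 5683,
    "NW_004081110": 23618,
    "NW_004081259": 10995,
    "NW_004081534": 24786,
    "NW_004081794": 11900,
    "NW_004081954": 3251,
    "NW_004082010": 15522,
    "NW_004082156": 2582,
    "NW_004082203": 5855,
    "NW_004082507": 54299,
    "NW_004082570": 2995,
    "NW_004082847": 15903,
    "NW_004083226": 13533,
    "NW_004083566": 7770,
}

# Germline V functionality tallies from the locus annotation.
TRAV_FUNCTIONALITY = {"functional": 43, "ORF": 5, "pseudogene": 18}
TRDV_TOTAL = 28
TRDV_ORF_OR_PSEUDOGENE = 8


def percent_functional(tallies: dict[str, int]) -> float:
    """Percent of genes classed functional among all classified genes."""
    total = sum(tallies.values())
    if total == 0:
        raise ValueError("empty tally")
    return 100.0 * tallies.get("functional", 0) / total


def percent_of(count: int, total: int) -> float:
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * count / total


def unplaced_scaffold_total_bp(scaffolds: dict[str, int] = UNPLACED_SCAFFOLDS) -> int:
    """Total span of the unplaced scaffolds assumed to extend the locus."""
    return sum(scaffolds.values())
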