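"""AAL-90 parcellation: region labels and hemisphere assignment.

The 90 supratentorial regions of the Automated Anatomical Labeling atlas
are ordered as 45 homologous left/right pairs; in the standard 1-based
atlas ordering odd indices are left-hemisphere, even indices right.
"""

from __future__ import annotations

N_NODES = 90

# 45 base region abbreviations in standard AAL order.
REGIONS_45 = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING",
    "SOG", "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG",
    "PCUN", "PCL", "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG",
]

#: node labels in atlas order: PreCG.L, PreCG.R, SFGdor.L, ...
NODE_LABELS = [f"{r}.{h}" for r in REGIONS_45 for h in ("L", "R")]

#: node label -> hemisphere ("L"/"R")
HEMISPHERE = {lab: lab[-1] for lab in NODE_LABELS}

#: node label -> base region (hemisphere stripped)
BASE_REGION = {lab: lab[:-2] for lab in NODE_LABELS}

#: node label -> 0-based index
NODE_INDEX = {lab: i for i, lab in enumerate(NODE_LABELS)}


def hemisphere_of_index(i: int) -> str:
    """Hemisphere of 0-based node index (even=L, odd=R in 0-based terms)."""
    if not 0 <= i < N_NODES:
        raise IndexError(f"node index {i} outside 0..{N_NODES - 1}")
    return "L" if i % 2 == 0 else "R"


def nodes_of_region(region: str) -> list[int]:
    """0-based node indices for a base region name or a single node label."""
    if region in NODE_INDEX:
        return [NODE_INDEX[region]]
    idx = [i for i, lab in enumerate(NODE_LABELS) if BASE_REGION[lab] == region]
    if not idx:
        raise KeyError(f"unknown region {region!r}")
    return idx
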