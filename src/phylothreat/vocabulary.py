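"""Canonical vocabularies: threat classes, IUCN Red List categories, DD scenarios.

The eleven threat classes are the top level of the IUCN threat
classification scheme (residential development through climate change),
referred to throughout by their conventional short names. The category
order ``LC < NT < VU < EN < CR`` is the ordinal risk scale used for rank
transforms; ``DD`` (data deficient) is handled separately via scenarios.
"""

from __future__ import annotations

#: Canonical short names of the 11 top-level IUCN threat classes.
THREAT_CLASSES: tuple[str, ...] = (
    "Urbanization",
    "Agri- & aquaculture",
    "Energy production",
    "Transportation",
    "Harvesting/Hunting",
    "Intrusion",
    "Ecosystem changes",
    "Exotics & pathogens",
    "Pollution",
    "Geological events",
    "Climate change",
)

#: IUCN Red List categories in increasing order of extinction risk.
IUCN_CATEGORIES: tuple[str, ...] = ("LC", "NT", "VU", "EN", "CR")

#: Data-deficient marker (not part of the ordinal risk scale).
DATA_DEFICIENT: str = "DD"

#: How to resolve data-deficient species before probabilistic analyses.
DD_SCENARIOS: tuple[str, ...] = ("exclude", "as_LC", "as_CR")

#: Ordinal code of each category (LC=0 ... CR=4).
CATEGORY_CODES: dict[str, int] = {c: i for i, c in enumerate(IUCN_CATEGORIES)}
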