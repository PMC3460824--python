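"""IUCN category handling: extinction-probability models, DD scenarios, risk ranks.

The built-in ``IUCN50`` model maps Red List categories to 50-year extinction
probabilities (LC=0.00005, NT=0.004, VU=0.05, EN=0.42, CR=0.97). Alternative
horizons or calibrations are supplied as named category → probability maps.

Data-deficient (DD) species carry no category on the ordinal risk scale and
must be resolved by a scenario — dropped, recoded as LC, or recoded as CR —
before probabilities or ranks are computed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .vocabulary import CATEGORY_CODES, DATA_DEFICIENT, DD_SCENARIOS, IUCN_CATEGORIES

__all__ = [
    "ExtinctionProbabilityModel",
    "IUCN50",
    "read_risk_csv",
    "write_risk_csv",
    "validate_risk",
    "apply_scenario",
    "probabilities",
    "risk_rank",
]


@dataclass(frozen=True)
class ExtinctionProbabilityModel:
    """Named mapping of IUCN categories to extinction probabilities."""

    name: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(IUCN_CATEGORIES) - set(self.values)
        if missing:
            raise ValueError(f"model {self.name!r} missing categories: {sorted(missing)}")
        for cat, p in self.values.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {cat} outside [0,1]: {p}")
        probs = [self.values[c] for c in IUCN_CATEGORIES]
        if any(b < a for a, b in zip(probs, probs[1:])):
            warnings.warn(
                f"model {self.name!r} is not monotone over LC..CR", stacklevel=2
            )

    def __getitem__(self, category: str) -> float:
        return self.values[category]

    @classmethod
    def from_json(cls, path) -> "ExtinctionProbabilityModel":
        with open(path) as fh:
            payload = json.load(fh)
        name = payload.pop("name", "custom")
        return cls(name=name, values={k: float(v) for k, v in payload.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, **self.values}, fh, indent=2)


#: 50-year extinction probabilities per Red List category.
IUCN50 = ExtinctionProbabilityModel(
    name="IUCN50",
    values={"LC": 0.00005, "NT": 0.004, "VU": 0.05, "EN": 0.42, "CR": 0.97},
)


def read_risk_csv(path_or_buffer) -> pd.Series:
    """Read a species,category CSV into a risk assessment Series."""
    df = pd.read_csv(path_or_buffer)
    if df.shape[1] != 2:
        raise ValueError("risk table must have two columns (species,category)")
    df.columns = ["species", "category"]
    risk = pd.Series(
        df["category"].astype(str).str.strip().values,
        index=df["species"].astype(str).str.strip(),
        name="category",
    )
    return validate_risk(risk)


def write_risk_csv(risk: pd.Series, path) -> None:
    risk.rename_axis("species").rename("category").to_csv(path)


def validate_risk(risk: pd.Series) -> pd.Series:
    allowed = set(IUCN_CATEGORIES) | {DATA_DEFICIENT}
    bad = sorted(set(risk.unique()) - allowed)
    if bad:
        raise ValueError(f"unknown IUCN categories: {bad}")
    if risk.index.has_duplicates:
        dupes = risk.index[risk.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate species in risk table: {dupes[:5]}")
    return risk


def apply_scenario(risk: pd.Series, scenario: str) -> pd.Series:
    """Resolve DD species: ``exclude`` drops them, ``as_LC``/``as_CR`` recode them."""
    if scenario not in DD_SCENARIOS:
        raise ValueError(f"unknown DD scenario {scenario!r}; choose from {DD_SCENARIOS}")
    risk = validate_risk(risk)
    is_dd = risk == DATA_DEFICIENT
    if scenario == "exclude":
        return risk[~is_dd].copy()
    out = risk.copy()
    out[is_dd] = "LC" if scenario == "as_LC" else "CR"
    return out


def probabilities(risk: pd.Series, model: ExtinctionProbabilityModel = IUCN50) -> pd.Series:
    """Per-species extinction probabilities under ``model``.

    DD categories must have been resolved first (``apply_scenario``).
    """
    dd = risk.index[risk == DATA_DEFICIENT].tolist()
    if dd:
        raise ValueError(
            f"{len(dd)} data-deficient species present (e.g. {dd[:3]}); "
            "apply a DD scenario first"
        )
    return risk.map(model.values).astype(float).rename("p_ext")


def risk_rank(risk: pd.Series) -> pd.Series:
    """Midranks of the ordinal categories LC<NT<VU<EN<CR.

    Ties within a category receive the average rank of their block, the
    standard treatment for Spearman correlations with heavy ties.
    """
    dd = (risk == DATA_DEFICIENT).sum()
    if dd:
        raise ValueError(f"{dd} data-deficient species present; apply a DD scenario first")
    codes = risk.map(CATEGORY_CODES).astype(float)
    return pd.Series(rankdata(codes.values), index=risk.index, name="risk_rank")
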