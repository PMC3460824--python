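"""End-to-end orchestration of the three analyses with reproducible seeds.

``run_pipeline`` reads a validated input bundle (tree, risk table, threat
incidence, area/habitat incidence, optional clade map), executes the
expected-PD-loss analysis under all three DD scenarios, the distinctiveness
indices, the DPCoA and correspondence analyses, and the threat-diversity
tests, writing every result plus a machine-readable summary under the output
directory. Per-stage seeds are derived from the master seed with
``numpy.random.SeedSequence`` so reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    apply_scenario, build_proximity, build_threat_by_label_table,
    corrected_rank_correlation, correspondence_analysis,
    distinctiveness_risk_correlation, distinctiveness_scores, dpcoa,
    mean_shift_test, morans_i, order_level_correlation, pdloss_table,
    phi_matrix, probabilities, risk_rank, threat_counts,
)
from .extinction_model import IUCN50, ExtinctionProbabilityModel, read_risk_csv
from .treeio import Phylogeny, read_clade_map, validate_clade_map
from .vocabulary import DD_SCENARIOS, IUCN_CATEGORIES

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    tree: str
    risk: str
    threats: str
    areas: str | None = None
    habitats: str | None = None
    clades: str | None = None
    outdir: str = "out"
    model: ExtinctionProbabilityModel = field(default_factory=lambda: IUCN50)
    dd_scenarios: tuple[str, ...] = DD_SCENARIOS
    n_perm_pdloss: int = 200
    n_perm_moran: int = 999
    n_perm_corrected: int = 999
    seed: int = 0
    land_areas: tuple[str, ...] = ()    # label subset for the land-only CA
    marine_areas: tuple[str, ...] = ()  # label subset for the marine-only CA
    stages: tuple[str, ...] = ("pdloss", "distinct", "ordinate", "threats")

    def validate(self) -> None:
        for name in ("tree", "risk", "threats", "areas", "habitats", "clades"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if self.n_perm_pdloss < 1 or self.n_perm_moran < 1 or self.n_perm_corrected < 1:
            raise ValueError("n_perm values must be >= 1")

    def hash(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _align_to_tree(tree: Phylogeny, table, what: str):
    """Drop table rows for species absent from the tree (logged warning)."""
    tips = set(tree.tip_labels)
    extra = [s for s in table.index if s not in tips]
    if extra:
        logger.warning("%s: %d species not in tree dropped: %s",
                       what, len(extra), extra[:5])
    return table.loc[[s for s in table.index if s in tips]]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all three analyses; returns the summary dict written to disk."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    seed_of = {name: int(s.generate_state(1)[0] % 2**31)
               for name, s in zip(
                   ["pdloss", "moran", "corrected", "meanshift", "spare1", "spare2"],
                   seeds)}

    tree = Phylogeny.from_file(config.tree)
    risk = _align_to_tree(tree, read_risk_csv(config.risk), "risk")
    threats = _align_to_tree(tree, pd.read_csv(config.threats, index_col=0), "threats")
    areas = (_align_to_tree(tree, pd.read_csv(config.areas, index_col=0), "areas")
             if config.areas else None)
    habitats = (_align_to_tree(tree, pd.read_csv(config.habitats, index_col=0), "habitats")
                if config.habitats else None)
    clades = (validate_clade_map(tree, read_clade_map(config.clades))
              if config.clades else {})

    summary: dict = {"config_hash": config.hash(), "seeds": seed_of, "outputs": {}}

    def record(name: str, path: Path):
        summary["outputs"][name] = str(path)

    # ---- first analysis: expected PD loss + distinctiveness, per DD scenario
    pdloss_by_clade_default: pd.Series | None = None
    for scenario in config.dd_scenarios:
        if ("pdloss" not in config.stages and "distinct" not in config.stages
                and scenario != "exclude"):
            continue  # "threats" only needs the default-scenario clade PDloss
        risk_s = apply_scenario(risk, scenario)
        tips_s = [t for t in tree.tip_labels if t in risk_s.index]
        tree_s = tree.prune_to(tips_s)
        clades_s = {k: v & set(tips_s) for k, v in clades.items()}
        clades_s = {k: v for k, v in clades_s.items() if len(v) >= 2}
        p = probabilities(risk_s, config.model)
        if "pdloss" in config.stages or "threats" in config.stages:
            table = pdloss_table(
                tree_s, p, clades_s or None,
                n_perm=config.n_perm_pdloss, seed=seed_of["pdloss"],
            )
            path = out / f"pdloss_{scenario}.csv"
            table.to_csv(path)
            record(f"pdloss_{scenario}", path)
            if scenario == "exclude":
                pdloss_by_clade_default = table["pd_loss"].drop("whole_tree")

        if "distinct" in config.stages:
            scores = distinctiveness_scores(tree_s)
            spath = out / f"distinctiveness_{scenario}.csv"
            scores.rename_axis("species").to_csv(spath)
            record(f"distinctiveness_{scenario}", spath)
            corr = distinctiveness_risk_correlation(scores, risk_rank(risk_s))
            cpath = out / f"distinctiveness_correlation_{scenario}.json"
            cpath.write_text(json.dumps(corr, indent=2))
            record(f"distinctiveness_correlation_{scenario}", cpath)

    if "ordinate" not in config.stages and "threats" not in config.stages:
        spath = out / "summary.json"
        spath.write_text(json.dumps(summary, indent=2))
        return summary

    # ---- second analysis: ordination
    if "ordinate" in config.stages:
        dp = dpcoa(threats, tree.patristic_matrix())
        _write_ordination(dp, out, "dpcoa", record)
    if "ordinate" in config.stages and areas is not None:
        table = build_threat_by_label_table(threats, areas)
        _write_ordination(correspondence_analysis(table), out, "ca_areas", record)
        for name, subset in (("land", config.land_areas), ("marine", config.marine_areas)):
            cols = [c for c in table.columns if c in subset]
            if cols:
                _write_ordination(
                    correspondence_analysis(table[cols]), out, f"ca_areas_{name}", record
                )
    if "ordinate" in config.stages and habitats is not None:
        table = build_threat_by_label_table(threats, habitats)
        _write_ordination(correspondence_analysis(table), out, "ca_habitats", record)

    if "threats" not in config.stages:
        spath = out / "summary.json"
        spath.write_text(json.dumps(summary, indent=2))
        return summary

    # ---- third analysis: threat diversity
    phi = phi_matrix(threats)
    ppath = out / "phi_matrix.csv"
    phi.to_csv(ppath)
    record("phi_matrix", ppath)

    counts = threat_counts(threats)
    risk_nd = apply_scenario(risk, "exclude")
    shared = counts.index.intersection(risk_nd.index)
    ranks = risk_rank(risk_nd.loc[shared])
    stats: dict = {}

    proximities = {"phylogenetic": build_proximity("phylogenetic", tree)}
    if areas is not None:
        proximities["geographic"] = build_proximity("geographic", areas)
    if habitats is not None:
        proximities["habitat"] = build_proximity("habitat", habitats)

    for kind, W in proximities.items():
        res = morans_i(counts, W.loc[counts.index, counts.index],
                       n_perm=config.n_perm_moran, seed=seed_of["moran"])
        stats[f"moran_{kind}"] = res.to_dict()

    filters = {
        "all": shared,
        "no_LC": shared[risk_nd.loc[shared] != "LC"],
        "with_threats": shared[counts.loc[shared] > 0],
    }
    for fname, idx in filters.items():
        if len(idx) < 3 or counts.loc[idx].std() == 0 or ranks.loc[idx].std() == 0:
            continue
        for kind, W in proximities.items():
            res = corrected_rank_correlation(
                counts.loc[idx], ranks.loc[idx], W.loc[idx, idx],
                n_perm=config.n_perm_corrected, seed=seed_of["corrected"],
            )
            stats[f"corrected_rank_{fname}_{kind}"] = {**res.to_dict(), "filter": fname}

    for low, high in zip(IUCN_CATEGORIES, IUCN_CATEGORIES[1:]):
        sub = shared[risk_nd.loc[shared].isin([low, high])]
        if (risk_nd.loc[sub] == low).sum() == 0 or (risk_nd.loc[sub] == high).sum() == 0:
            continue
        for kind, W in proximities.items():
            res = mean_shift_test(
                counts.loc[sub], risk_nd.loc[sub], low=low, high=high,
                w=W.loc[sub, sub], n_perm=config.n_perm_corrected,
                seed=seed_of["meanshift"],
            )
            stats[f"mean_shift_{low}_to_{high}_{kind}"] = res.to_dict()

    if clades and pdloss_by_clade_default is not None and len(clades) >= 3:
        mean_counts = pd.Series(
            {c: counts.loc[counts.index.intersection(list(m))].mean()
             for c, m in clades.items()}
        )
        try:
            stats["order_level_correlation"] = order_level_correlation(
                mean_counts, pdloss_by_clade_default
            )
        except ValueError as exc:
            stats["order_level_correlation"] = {"error": str(exc)}

    tpath = out / "threat_stats.json"
    tpath.write_text(json.dumps(stats, indent=2))
    record("threat_stats", tpath)

    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=2))
    return summary


def _write_ordination(res, out: Path, name: str, record) -> None:
    rpath = out / f"{name}_rows.csv"
    cpath = out / f"{name}_cols.csv"
    epath = out / f"{name}_eigen.json"
    res.row_coords.rename_axis("label").to_csv(rpath)
    res.col_coords.rename_axis("label").to_csv(cpath)
    epath.write_text(json.dumps({
        "eigenvalues": [float(x) for x in res.eigenvalues],
        "proportions": [float(x) for x in res.proportions],
        "total_inertia": float(res.total_inertia),
    }, indent=2))
    record(f"{name}_rows", rpath)
    record(f"{name}_cols", cpath)
    record(f"{name}_eigen", epath)
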