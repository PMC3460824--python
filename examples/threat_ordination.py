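"""Which threats affect which parts of the phylogeny, and where.

DPCoA orders threat types by the phylogenetic positions of the species they
affect: threats whose species sets occupy distinct clades separate along
the leading axes, and each axis's share of the between-threat phylogenetic
inertia is reported. The correspondence analysis then ordinates threats
against geographic areas; its total inertia is the chi-square statistic of
the threats × areas table divided by the number of (species, area) records.
"""

from phylothreat import (
    SyntheticConfig, build_threat_by_label_table, correspondence_analysis,
    dpcoa, generate_dataset,
)

ds = generate_dataset(SyntheticConfig(n_species=60, seed=31))

res = dpcoa(ds.threats, ds.tree.patristic_matrix())
print("DPCoA of threats on the phylogeny")
print(f"  axes retained: {res.n_axes}")
print(f"  leading axes explain "
      f"{100 * res.proportions[0]:.0f}% and {100 * res.proportions[1]:.0f}% "
      "of the between-threat phylogenetic differences")
print("  threat coordinates on the first two axes:")
print(res.col_coords.iloc[:, :2].round(3).to_string())

table = build_threat_by_label_table(ds.threats, ds.areas)
ca = correspondence_analysis(table)
print("\nCorrespondence analysis, threats x geographic areas")
print(f"  total inertia (chi-square / N): {ca.total_inertia:.4f}")
print(f"  first axis explains {100 * ca.proportions[0]:.0f}% of the association")
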