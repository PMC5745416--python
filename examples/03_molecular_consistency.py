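"""Compare hard vs soft homoplasy on an independent reference tree.

The hard partition is simulated off the reference topology while the
soft partition follows it, mimicking a clade whose fossilizable
characters are the less reliable ones.  Retention indices on the
reference tree and a Mann-Whitney-Wilcoxon test quantify the contrast.
"""

import phylopart as pp
from phylopart import simulate

dataset = simulate.simulate_dataset(
    simulate.SimulationConfig(
        n_taxa=12, n_hard=25, n_soft=25,
        incongruence=5, reference_distortion=0, rate=0.5, seed=11,
    )
)
res = pp.consistency_test(dataset.matrix, dataset.reference)

print(f"taxa used: {res.n_taxa_used} "
      f"(excluded: {res.n_excluded_taxa} taxa, "
      f"{res.n_excluded_characters} uninformative characters)")
print(f"ensemble RI hard = {res.RI_hard:.3f}, soft = {res.RI_soft:.3f}")
print(f"MWW two-sided p = {res.mww_p:.4f}")
print("RI_soft > RI_hard means the soft characters track the reference "
      "tree more faithfully, as constructed here")
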