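"""Normalized trans->cis distance changes on toy trajectory ensembles.

Builds paired trans/cis toy two-helix trajectories carrying a
pseudo-azobenzene at K-chain position 9, measures per-residue minimum
heavy-atom distances to the three moieties (diazene, ring 1, ring 2),
and reports the normalized change with the 0.2 significance cutoff.
"""

import warnings

from azocoil import synthetic, trajectory as tj

trans, cis, moieties, truth = synthetic.gen_toy_trajectory()
print(f"ensembles: {trans.n_replicas} replicas x "
      f"{trans.replicas[0].shape[0]} frames per state")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    t_tbl = tj.chain_moiety_distances(trans, "E", moieties)
    c_tbl = tj.chain_moiety_distances(cis, "E", moieties)
table = tj.normalized_distance_change(t_tbl, c_tbl, cutoff=0.2)

register = tj.assign_heptad_register(synthetic.E3_SEQUENCE,
                                     synthetic.E3_REGISTER_OFFSET)
sig = table[table.significant].copy()
sig["heptad"] = sig.residue_index.map(lambda i: register[i - 1])
print(f"{len(sig)} of {len(table)} residue/moiety pairs significant "
      "(|delta| >= 0.2):")
for _, row in sig.iterrows():
    print(f"  {row.residue_name}{row.residue_index:<2d} ({row.heptad})  "
          f"{row.moiety:>7s}: {row.mean_trans:5.2f} -> "
          f"{row.mean_cis:5.2f} A  (delta_norm {row.delta_norm:+.2f})")
print("-> positive values mean the moiety sits farther from chain E "
      "in the cis state, as constructed.")
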