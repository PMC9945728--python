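"""Faith's phylogenetic diversity of each tick species/stage host set.

PD is the branch length of the minimal subtree spanning the host families a
species uses at a given stage; it rises either with many families or with a
few distantly related ones, which is why family richness is reported next to
it rather than instead of it.
"""

from ixonet import SimulationConfig, faith_pd, generate_records, generate_tree, pd_profiles
from ixonet.pd import profiles_to_frame
from ixonet.trees import tree_from_string

toy = tree_from_string("((A:1,B:1):1,C:2);")
print("toy tree ((A:1,B:1):1,C:2);")
print("  PD({A,B})   =", faith_pd(toy, {"A", "B"}), " (two sisters + root path)")
print("  PD({A,B,C}) =", faith_pd(toy, {"A", "B", "C"}), "(the whole tree)")

cfg = SimulationConfig(n_tick_species=30, n_host_families=40, n_host_orders=10,
                       n_modules=4, seed=3)
records, _ = generate_records(cfg)
tree = generate_tree(40, seed=3)
frame = profiles_to_frame(pd_profiles(records, tree), sort_by_adult_pd=True)
print("\ntop species by adult-stage PD:")
print(frame.head(9).to_string(index=False))
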