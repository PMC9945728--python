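"""Compute the full structure-index row of one network.

NODF measures nestedness (0-100), Fisher's alpha the diversity/redundancy of
realized interactions, partner diversity the weighted mean Shannon breadth of
host use, functional complementarity how little the ticks' host profiles
overlap, and the extinction slope how robust the tick community is to random
host loss (larger = more robust).
"""

from ixonet import SimulationConfig, build_network, generate_records, network_report

records, _ = generate_records(SimulationConfig(seed=1))
net = build_network(records)
rep = network_report(net, seed=1, n_replicates=100)

for key, value in rep.to_dict().items():
    print(f"{key:>28}: {value:.4f}" if isinstance(value, float) else f"{key:>28}: {value}")
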