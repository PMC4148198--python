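"""Build the anatomically constrained local granule-cell-layer network.

Places MF rosettes and granule cells at their measured densities inside a
40-um-radius ball and wires each GC to four rosettes with ~15-um dendrites,
then prints the connectivity statistics that characterize the circuit.
"""

import numpy as np

from gclnet import AnatomyParams, build_local_network, summarize

params = AnatomyParams(seed=1)  # defaults: 1.9e6 GCs/mm^3, 6.6e5 rosettes/mm^3
net = build_local_network(params)
stats = summarize(net)

print(f"granule cells:            {stats.n_gc}")
print(f"rosettes (central field): {stats.n_rosette}")
print(f"expansion ratio:          {stats.expansion_ratio:.2f}")
print(f"mean GCs per rosette:     {stats.mean_gcs_per_rosette:.1f}")
print(f"median dendrite length:   {np.median(net.edge_length):.1f} um")
print(f"dendrites over 20 um:     {(net.edge_length > 20).mean() * 100:.1f} %")

# The expansion ratio (~2.9 GCs per rosette) and the ~12 distinct GCs each
# rosette contacts are the anatomical constants the binary and spiking
# network models inherit.
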