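"""Binary threshold networks: how connectivity and threshold shape activity.

Builds a uniform binary network (random bipartite graph), applies different
threshold policies and compares the granule-cell activation probability with
its closed form, the binomial tail P(Binom(d, p) >= phi).
"""

import numpy as np

from gclnet import (
    ThresholdPolicy,
    build_uniform_graph,
    p_gc_analytic,
    threshold_at,
    transform,
)

graph = build_uniform_graph(n_mf=176, n_gc=509, d=4, seed=0)
fixed = ThresholdPolicy(kind="fixed_relative")  # phi = ceil(0.75 d)
nadt = ThresholdPolicy(kind="nadt", nadt_scale=2.0)

rng = np.random.default_rng(0)
print(" p(MF)  phi(fixed)  phi(NADT=2)  p(GC) analytic  p(GC) empirical")
for p in (0.1, 0.3, 0.5, 0.8):
    phi = threshold_at(fixed, graph.d, p)
    patterns = (rng.random((4000, graph.n_mf)) < p).astype(np.uint8)
    empirical = transform(graph, phi, patterns).mean()
    print(
        f"  {p:.1f}       {phi}           {threshold_at(nadt, graph.d, p)}"
        f"          {p_gc_analytic(graph.d, phi, p):.4f}          {empirical:.4f}"
    )

# With the fixed relative threshold (3 of 4 inputs) the GC population is much
# sparser than its input at low-to-mid p(MF); the NADT policy instead raises
# the threshold with network activity, keeping activity closer to one half.
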