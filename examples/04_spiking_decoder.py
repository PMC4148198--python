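"""Reduced-scale spiking network with the decoder-based MI pipeline.

Drives the anatomically constrained network with Poisson realizations of
binary MF patterns (80 Hz active / 10 Hz inactive), decodes 30-ms GC spike
count vectors with a k-means classifier fitted on separate realizations, and
reports mutual information and Treves-Rolls population sparseness.
"""

from gclnet.cli import run_spiking_figure

table = run_spiking_figure(
    {
        "d_list": [4, 16],
        "p_grid": [0.2],
        "n_patterns": 16,
        "trials_train": 5,
        "trials_test": 5,
        "seed": 0,
    },
    "scratch/example_spiking",
)
print(table[["d", "p_mf", "mi_corrected_bits", "sparseness"]].to_string(index=False))
print(f"\nmaximum recoverable MI: log2(16) = 4 bits")

# At low MF activity the d=4 network recovers far more of the pattern
# information than d=16 (whose GCs almost never reach threshold), while the
# d=16 population is the sparser one: the binary-model trade-off carries
# over to the biophysical model.
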