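"""Encode one window under every feature representation.

Shows the per-encoding feature dimensions and a few values of each
representation for a single 41-nt window.
"""

import numpy as np

from sixma.encoders import (
    build_knn_reference,
    encode_dataset,
    encode_dbe_lpf,
    encode_mbe,
    encode_num,
    encode_rfhc,
    similarity_score,
)
from sixma.simdata import generate, strong_signal_config

data = generate(strong_signal_config(n_pos=100, n_neg=100, seed=2))
window = data[0].seq
print(f"window: {window}")

num = encode_num(window)
print(f"NUM     ({num.size:4d} features): first 5 = {np.round(num[:5], 2)}")
mbe = encode_mbe(window)
print(f"MBE     ({mbe.size:4d} features): first block = {mbe[:4]} (one-hot {window[0]})")
dl = encode_dbe_lpf(window)
print(f"DBE_LPF ({dl.size:4d} features): dinucleotide {window[:2]} -> {dl[:4]}, "
      f"first frequency = {dl[160]:.2f}")
rfhc = encode_rfhc(window)
print(f"RFHC    ({rfhc.size:4d} features): position 1 -> {rfhc[:4]} "
      "(ring/hbond/amino/density)")

# KNN features need a labeled reference (here: the rest of the dataset)
ref = build_knn_reference(data.subset(range(1, len(data))))
knn = encode_dataset(data.subset([0]), "KNN", ref=ref)
print(f"KNN     ({knn.dim:4d} features): positive fractions = {knn.values[0]}")
print(f"self-similarity score of the window: {similarity_score(window, window)}")
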