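"""Recover full detector data from compressed measurements.

Per-group 2-sparse signals are measured through the designed 48x64
block-diagonal matrix; the equality-constrained l1 solver recovers all
64 channels from 48 measurement rows.
"""

import numpy as np

from cspapi import (
    CSStructure, SparseSignalSpec, TVSettings, make_group_sparse_signals,
    relative_l2_error, replicate_group, tv_solve_batch, validated_design,
)

design = validated_design(CSStructure(m0=12), s=2, n_iter=100, seed=1)
A = replicate_group(design.best_matrix, 4).entries.astype(float)

signals = make_group_sparse_signals(
    SparseSignalSpec(s=2, mode="entry", seed=7), q=128
)
H_true = signals.values            # 64 sensors x 128 radius samples
Y = A @ H_true                     # 48 measurement channels

H_rec = tv_solve_batch(
    A, Y, reg_weight=1.0,
    settings=TVSettings(fidelity="exact", diff_mode="identity", max_iter=3000),
)

print(f"measurements:   {Y.shape} (compressed from {H_true.shape})")
print(f"recovery error: {relative_l2_error(H_rec, H_true):.2e} relative l2")
print("An error at solver precision means the 48 structured measurements")
print("determine the 64-channel per-group 2-sparse data exactly, as the")
print("positive 2-SIN of the designed matrix guarantees.")
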