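"""Seeded generators for test inputs and their audit checks.

Everything downstream assumes particular structure in the data: the
two-step reconstruction assumes the transformed detector signals have
sparse gradients across each 16-sensor group, and the sparse-recovery
theory assumes strictly per-group s-sparse signals.  The generators here
produce inputs that *provably* satisfy those assumptions (audited post
hoc where placement is random), so tests bind to properties rather than
to any particular phantom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wave_model import (
    DetectorData,
    Disk,
    DiskPhantom,
    SensorGeometry,
    TimeGrid,
    circular_means,
)

__all__ = [
    "NoiseSpec",
    "SparseSignalSpec",
    "make_disk_phantom",
    "make_group_sparse_signals",
    "add_noise",
    "entry_sparsity_audit",
    "gradient_sparsity_audit",
    "sparse_phantom_audit",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise at a controlled relative l2 level."""

    level: float = 0.09
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be >= 0")


@dataclass(frozen=True)
class SparseSignalSpec:
    """Per-group sparse detector-domain signals.

    ``entry`` mode: each column restricted to each group has exactly ``s``
    nonzero entries.  ``gradient`` mode: each group column consists of
    ``s/2`` disjoint constant arcs on a zero background, giving exactly
    ``s`` nonzero cyclic differences (``s`` must be even; a cyclic signal
    cannot have an odd number of jumps without level changes between
    segments, and arcs-on-background is the structure the transformed
    detector data of localized sources actually has).
    Amplitudes are uniform on [0.5, 1.5] with random sign, avoiding
    near-cancellation degeneracies while exercising sign recovery.
    """

    group_size: int = 16
    num_groups: int = 4
    s: int = 2
    mode: str = "entry"
    amp_range: tuple[float, float] = (0.5, 1.5)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.s <= self.group_size:
            raise ValueError("need 0 <= s <= group_size")
        if self.mode not in ("entry", "gradient"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "gradient" and self.s % 2:
            raise ValueError("gradient mode needs an even jump count s")


def entry_sparsity_audit(values: np.ndarray, group_size: int, s: int) -> bool:
    """True iff every column of every group has at most ``s`` nonzeros."""
    n, q = values.shape
    groups = values.reshape(n // group_size, group_size, q)
    return bool(((np.abs(groups) > 0).sum(axis=1) <= s).all())


def gradient_sparsity_audit(
    values: np.ndarray,
    group_size: int,
    s: int,
    rel_threshold: float = 0.02,
) -> tuple[bool, np.ndarray]:
    """Check per-group cyclic-gradient sparsity of sensors x samples data.

    A jump is *significant* when its magnitude exceeds ``rel_threshold``
    times the global maximum magnitude.  Returns (pass, jump counts per
    group per column).
    """
    n, q = values.shape
    if n % group_size:
        raise ValueError("sensor count must be a multiple of group_size")
    groups = values.reshape(n // group_size, group_size, q)
    jumps = np.abs(np.roll(groups, -1, axis=1) - groups)
    scale = np.abs(values).max()
    if scale == 0:
        return True, np.zeros((n // group_size, q), dtype=int)
    counts = (jumps > rel_threshold * scale).sum(axis=1)
    return bool((counts <= s).all()), counts


def sparse_phantom_audit(
    values: np.ndarray,
    group_size: int = 16,
    s: int = 2,
    rel_threshold: float = 0.2,
    max_violation_frac: float = 0.15,
) -> tuple[bool, float]:
    """Approximate per-group gradient-sparsity check for disk sources.

    Circular means of a disk ramp smoothly across the sensors that see it,
    so the strict "at most s significant jumps everywhere" property cannot
    hold exactly; what a localized source delivers is the approximate
    version: the fraction of (group, radius) cells with more than ``s``
    jumps above ``rel_threshold`` times the global maximum stays small.
    Returns (pass, violating fraction).
    """
    _, counts = gradient_sparsity_audit(values, group_size, s, rel_threshold)
    frac = float((counts > s).mean())
    return frac <= max_violation_frac, frac


def make_disk_phantom(
    kind: str,
    seed: int | None = None,
    R: float = 1.0,
    max_retries: int = 200,
) -> DiskPhantom:
    """Random disk phantom of one of two characters.

    ``piecewise``: 3-6 disks of mixed radii and amplitudes inside 0.8 R —
    piecewise-smooth but not sparse in the per-group sense.  ``sparse``:
    1-2 small disks (radius <= 0.1 R) placed so that, per 16-sensor group
    and per radius sample, the transformed detector signals have at most 2
    significant cyclic jumps; placement is audited post hoc and redrawn on
    failure.
    """
    rng = np.random.default_rng(seed)
    if kind == "piecewise":
        n_disks = int(rng.integers(3, 7))
        disks = []
        for _ in range(n_disks):
            radius = rng.uniform(0.08, 0.25) * R
            rho = rng.uniform(0.0, 0.8 * R - radius)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            disks.append(
                Disk(
                    center=(rho * math.cos(ang), rho * math.sin(ang)),
                    radius=radius,
                    amplitude=float(rng.uniform(0.5, 1.5)),
                )
            )
        return DiskPhantom(disks)
    if kind != "sparse":
        raise ValueError(f"unknown phantom kind {kind!r}")

    geometry = SensorGeometry(R=R, n=64)
    audit_grid = TimeGrid(q=256, R=R)
    for _ in range(max_retries):
        n_disks = int(rng.integers(1, 3))
        disks = []
        for _ in range(n_disks):
            radius = rng.uniform(0.04, 0.1) * R
            rho = rng.uniform(0.25 * R, 0.7 * R - radius)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            disks.append(
                Disk(
                    center=(rho * math.cos(ang), rho * math.sin(ang)),
                    radius=radius,
                    amplitude=float(rng.uniform(0.8, 1.2)),
                )
            )
        phantom = DiskPhantom(disks)
        means = circular_means(phantom, geometry, audit_grid)
        ok, _ = sparse_phantom_audit(means.values, 16, 2)
        if ok:
            return phantom
    raise RuntimeError(
        f"could not place a per-group gradient-sparse phantom in {max_retries} tries"
    )


def make_group_sparse_signals(
    spec: SparseSignalSpec, q: int, R: float = 1.0
) -> DetectorData:
    """Strictly per-group sparse sensors x samples signals.

    Supports (entry mode) or jump positions and levels (gradient mode) are
    drawn independently per column from the seeded generator.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.group_size * spec.num_groups
    vals = np.zeros((n, q))
    lo, hi = spec.amp_range
    if spec.s > 0:
        for g in range(spec.num_groups):
            base = g * spec.group_size
            for col in range(q):
                if spec.mode == "entry":
                    support = rng.choice(spec.group_size, size=spec.s, replace=False)
                    amps = rng.uniform(lo, hi, size=spec.s) * rng.choice(
                        (-1.0, 1.0), size=spec.s
                    )
                    vals[base + support, col] = amps
                else:
                    # s/2 disjoint, non-wrapping constant arcs on a zero
                    # background: exactly s nonzero differences both for
                    # the cyclic and for the zero-boundary operator
                    n_arcs = spec.s // 2
                    seg = np.zeros(spec.group_size)
                    while True:
                        widths = rng.integers(1, 4, size=n_arcs)
                        starts = np.array(
                            [rng.integers(0, spec.group_size - w + 1) for w in widths]
                        )
                        idx = [
                            st + np.arange(w) for st, w in zip(starts, widths)
                        ]
                        flat = np.concatenate(idx)
                        # arcs must not touch (also not across the cyclic seam)
                        grown = np.unique(
                            np.concatenate([flat, (flat + 1) % spec.group_size])
                        )
                        if len(np.unique(flat)) == flat.size and grown.size == len(
                            np.unique(flat)
                        ) + n_arcs:
                            break
                    for arc in idx:
                        seg[arc] = rng.uniform(lo, hi) * rng.choice((-1.0, 1.0))
                    vals[base : base + spec.group_size, col] = seg
    geometry = SensorGeometry(R=R, n=n)
    return DetectorData("circular_means", vals, geometry, TimeGrid(q=q, R=R))


def add_noise(data, spec: NoiseSpec):
    """Add Gaussian noise rescaled to the exact target relative l2 level.

    Accepts a raw array, DetectorData or CSData; returns (noisy object of
    the same type, realized relative error).
    """
    values = data.values if hasattr(data, "values") else np.asarray(data, dtype=float)
    if spec.level == 0:
        return data, 0.0
    norm = np.linalg.norm(values)
    if norm == 0:
        raise ValueError("cannot set a relative noise level on zero data")
    rng = np.random.default_rng(spec.seed)
    g = rng.standard_normal(values.shape)
    noise = spec.level * norm * g / np.linalg.norm(g)
    noisy_values = values + noise
    realized = float(np.linalg.norm(noisy_values - values) / norm)
    if hasattr(data, "values"):
        import copy

        out = copy.copy(data)
        out.values = noisy_values
        return out, realized
    return noisy_values, realized
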