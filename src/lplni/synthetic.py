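"""Synthetic bipartite drug-target networks with planted block structure.

Drugs and targets are partitioned into blocks; a drug interacts with a
target of its own block with probability ``p_in`` and with any other target
with probability ``p_out``.  This planted co-clustering is exactly the
"similar drugs hit similar targets" regularity that neighborhood-based
propagation exploits, so ``p_in - p_out`` acts as a clean signal-strength
dial for testing.  A companion fingerprint view encodes block membership as
a one-hot pattern tiled to the requested width, corrupted by independent
bit flips at rate ``noise_flip``.

All draws are reproducible from ``spec.seed``: the interaction network uses
the substream keyed (seed, 0) and the fingerprint view the substream keyed
(seed, 1), so either can be regenerated independently of the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import FeatureMatrix, InteractionMatrix
from .errors import ParameterError

__all__ = [
    "BlockNetworkSpec",
    "generate_network",
    "generate_fingerprint_view",
    "generate_dataset",
]


@dataclass(frozen=True)
class BlockNetworkSpec:
    """Parameters of the planted-block bipartite generator."""

    nd: int = 60
    nt: int = 40
    n_blocks: int = 3
    p_in: float = 0.5
    p_out: float = 0.02
    noise_flip: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nd < 2 or self.nt < 1:
            raise ParameterError("need nd >= 2 drugs and nt >= 1 targets")
        if self.n_blocks < 1 or self.n_blocks > min(self.nd, self.nt):
            raise ParameterError(
                f"n_blocks must lie in [1, min(nd, nt)] = "
                f"[1, {min(self.nd, self.nt)}], got {self.n_blocks}"
            )
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ParameterError(
                f"need 0 <= p_out <= p_in <= 1, got "
                f"p_in={self.p_in}, p_out={self.p_out}"
            )
        if not 0.0 <= self.noise_flip <= 1.0:
            raise ParameterError("noise_flip must lie in [0, 1]")


def _blocks(n: int, n_blocks: int) -> np.ndarray:
    """Block label per index, sizes as even as possible (first blocks larger)."""
    sizes = np.full(n_blocks, n // n_blocks)
    sizes[: n % n_blocks] += 1
    return np.repeat(np.arange(n_blocks), sizes)


def drug_blocks(spec: BlockNetworkSpec) -> np.ndarray:
    return _blocks(spec.nd, spec.n_blocks)


def target_blocks(spec: BlockNetworkSpec) -> np.ndarray:
    return _blocks(spec.nt, spec.n_blocks)


def generate_network(spec: BlockNetworkSpec) -> InteractionMatrix:
    """Draw the planted-block interaction matrix (deterministic per seed)."""
    rng = np.random.default_rng((spec.seed, 0))
    bd = drug_blocks(spec)
    bt = target_blocks(spec)
    same = bd[:, None] == bt[None, :]
    probs = np.where(same, spec.p_in, spec.p_out)
    values = (rng.random((spec.nd, spec.nt)) < probs).astype(float)
    return InteractionMatrix(
        values=values,
        drug_ids=[f"D{i:04d}" for i in range(spec.nd)],
        target_ids=[f"T{j:04d}" for j in range(spec.nt)],
    )


def generate_fingerprint_view(
    Y: InteractionMatrix, spec: BlockNetworkSpec, width: int | None = None
) -> FeatureMatrix:
    """Binary fingerprints correlated with block membership.

    Each drug's vector is its block's one-hot pattern tiled to ``width``
    bits (default 8 * n_blocks), then each bit flipped independently with
    probability ``noise_flip``.  At noise_flip = 0.5 the view carries no
    block information at all.
    """
    if Y.nd != spec.nd:
        raise ParameterError(
            f"interaction matrix has {Y.nd} drugs, spec says {spec.nd}"
        )
    rng = np.random.default_rng((spec.seed, 1))
    if width is None:
        width = 8 * spec.n_blocks
    bd = drug_blocks(spec)
    onehot = np.eye(spec.n_blocks)[bd]  # nd x n_blocks
    reps = int(np.ceil(width / spec.n_blocks))
    base = np.tile(onehot, (1, reps))[:, :width]
    flips = rng.random((spec.nd, width)) < spec.noise_flip
    values = np.where(flips, 1.0 - base, base)
    return FeatureMatrix(
        values=values, drug_ids=list(Y.drug_ids), feature_kind="fingerprint"
    )


def generate_dataset(
    spec: BlockNetworkSpec, width: int | None = None
) -> tuple[InteractionMatrix, FeatureMatrix]:
    """Network first, then the matching fingerprint view."""
    Y = generate_network(spec)
    X = generate_fingerprint_view(Y, spec, width=width)
    return Y, X
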