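"""Sparse block-diagonal probe-probe correlation matrices.

The Gibbs prior needs within-cluster Pearson correlations only; probes in
different clusters are structurally uncorrelated.  The representation stores
one dense symmetric block per cluster, so memory grows with the sum of
squared block sizes, never with the square of the probe count.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .clustering import ClusterSet
from .io import MethylationMatrix, ValidationError

__all__ = [
    "BlockCorrelationMatrix",
    "ConditioningReport",
    "build_block_correlation",
    "conditioning_report",
    "regularize_blocks",
    "save_blocks",
    "load_blocks",
]


@dataclass(frozen=True)
class BlockCorrelationMatrix:
    """Block-diagonal correlation matrix R.

    ``blocks`` is a list of (probe id list, dense symmetric block); the
    concatenation of the id lists is the canonical probe order.  Entries
    across blocks are structural zeros.
    """

    blocks: list  # [(list[str], np.ndarray)]

    def __post_init__(self):
        for pids, b in self.blocks:
            b = np.asarray(b, float)
            if b.shape != (len(pids), len(pids)):
                raise ValidationError("block shape does not match its probe list")
            if not np.allclose(b, b.T, atol=1e-12):
                raise ValidationError("correlation block not symmetric")
            if not np.allclose(np.diag(b), 1.0, atol=1e-10):
                raise ValidationError("correlation block diagonal must be 1")
            if np.any(np.abs(b) > 1 + 1e-10):
                raise ValidationError("correlation entries must lie in [-1, 1]")

    @property
    def probe_order(self) -> list[str]:
        return [p for pids, _ in self.blocks for p in pids]

    @property
    def n_probes(self) -> int:
        return sum(len(pids) for pids, _ in self.blocks)

    def quadratic_form(self, b: np.ndarray) -> float:
        """b' R b computed blockwise (b in canonical probe order)."""
        out = 0.0
        start = 0
        for pids, blk in self.blocks:
            stop = start + len(pids)
            seg = b[start:stop]
            out += float(seg @ blk @ seg)
            start = stop
        return out

    def to_dense(self) -> np.ndarray:
        """Materialize the full matrix; for diagnostics and small problems only."""
        m = self.n_probes
        out = np.zeros((m, m))
        start = 0
        for pids, blk in self.blocks:
            stop = start + len(pids)
            out[start:stop, start:stop] = blk
            start = stop
        return out


@dataclass(frozen=True)
class ConditioningReport:
    min_eigenvalues: np.ndarray  # per block
    n_flagged: int
    ill_conditioned: bool
    tol: float


def build_block_correlation(mat: MethylationMatrix, cs: ClusterSet) -> BlockCorrelationMatrix:
    """One dense Pearson block per cluster, computed across samples.

    Singleton clusters become 1x1 identity blocks.  Blocks follow cluster-id
    order; probes within a block follow their order in the cluster set.
    A zero-variance probe has no defined correlation and is an error.
    """
    if len(mat.sample_ids) < 3:
        raise ValidationError("need >= 3 samples to estimate correlations")
    if set(cs.assignment) != set(mat.probe_ids):
        raise ValidationError("cluster set does not partition the matrix's probes")
    row_idx = {p: i for i, p in enumerate(mat.probe_ids)}
    sd = mat.values.std(axis=1)
    if np.any(sd == 0):
        bad = mat.probe_ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValidationError(f"zero-variance methylation row for probe {bad!r}")
    blocks = []
    for pids in cs.members():
        rows = mat.values[[row_idx[p] for p in pids]]
        if len(pids) == 1:
            blk = np.ones((1, 1))
        else:
            blk = np.corrcoef(rows)
            np.fill_diagonal(blk, 1.0)
            blk = np.clip((blk + blk.T) / 2.0, -1.0, 1.0)
            np.fill_diagonal(blk, 1.0)
        blocks.append((list(pids), blk))
    return BlockCorrelationMatrix(blocks)


def conditioning_report(R: BlockCorrelationMatrix, tol: float = 1e-8) -> ConditioningReport:
    """Flag blocks whose smallest eigenvalue falls below ``tol``.

    Near-singular blocks are the known failure mode of the sampler: they can
    drive the heritability update negative and the chain into divergence.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    mins = np.array(
        [np.linalg.eigvalsh(blk).min() if len(pids) > 1 else 1.0 for pids, blk in R.blocks]
    )
    n_flagged = int((mins < tol).sum())
    return ConditioningReport(
        min_eigenvalues=mins,
        n_flagged=n_flagged,
        ill_conditioned=n_flagged > 0,
        tol=tol,
    )


def regularize_blocks(R: BlockCorrelationMatrix, shrink: float) -> BlockCorrelationMatrix:
    """Shrink every block toward the identity: B -> (1 - s) B + s I.

    Raises each block's minimum eigenvalue by s * (1 - previous minimum)
    while keeping a unit diagonal.
    """
    if not 0 <= shrink <= 1:
        raise ValueError("shrink must be in [0, 1]")
    blocks = []
    for pids, blk in R.blocks:
        out = (1.0 - shrink) * blk + shrink * np.eye(len(pids))
        blocks.append((list(pids), out))
    return BlockCorrelationMatrix(blocks)


# ---------------------------------------------------------------------------
# optional on-disk cache (runtime artifact; npz keyed by input hashes)


def cache_key(mat: MethylationMatrix, cs: ClusterSet) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mat.values).tobytes())
    h.update("\x00".join(mat.probe_ids).encode())
    h.update(cs.label.encode())
    h.update("\x00".join(f"{p}={c}" for p, c in sorted(cs.assignment.items())).encode())
    return h.hexdigest()[:16]


def save_blocks(R: BlockCorrelationMatrix, path, key: str) -> None:
    arrays = {"__key__": np.array([key])}
    for i, (pids, blk) in enumerate(R.blocks):
        arrays[f"pids_{i}"] = np.array(pids)
        arrays[f"blk_{i}"] = blk
    np.savez_compressed(path, **arrays)


def load_blocks(path, key: str) -> BlockCorrelationMatrix:
    data = np.load(path, allow_pickle=False)
    if str(data["__key__"][0]) != key:
        raise ValidationError("correlation cache key mismatch; rebuild the blocks")
    blocks = []
    i = 0
    while f"blk_{i}" in data:
        blocks.append((list(map(str, data[f"pids_{i}"])), data[f"blk_{i}"]))
        i += 1
    return BlockCorrelationMatrix(blocks)
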