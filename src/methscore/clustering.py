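"""Structural priors: partitions of the probe set into correlation blocks.

Array probes have no linkage-disequilibrium analogue, so the correlation
prior for the Gibbs sampler has to come from some other structure.  Four
constructions are provided, each yielding a :class:`ClusterSet` (a partition
of the annotated probes):

* **co-methylated regions (CMR)** — position-sorted consecutive probes are
  chained when they are close (``maxprbdst``), correlated in methylation
  (``corlo``), and, if a reference CpG map is given, no inter-probe CpG gap
  exceeds ``corlodst``;
* **sliding windows** — proximity-only chaining (gap <= window), the CMR
  construction with the correlation test effectively bypassed;
* **TAD assignment** — each probe goes to the topologically associating
  domain interval containing its position; unassigned probes are singletons;
* **random clusters** — a null model whose cluster-count and cluster-size
  distributions mimic an observed TAD partition (counts ~ Normal(2880, 144),
  sizes ~ LogNormal(log 82, 0.7)) but whose membership is pure chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import (
    IntervalSet,
    MethylationMatrix,
    ProbeAnnotation,
    ValidationError,
    normalize_chrom,
)

__all__ = [
    "ClusterSet",
    "CmrParams",
    "ClusterSummary",
    "sliding_window_clusters",
    "cmr_clusters",
    "tad_clusters",
    "random_clusters",
    "sample_cluster_sizes",
    "sample_cluster_counts",
    "cluster_summary",
    "drop_singletons",
    "write_cluster_assignments",
    "read_cluster_assignments",
    "RANDOM_CLUSTER_COUNT_MEAN",
    "RANDOM_CLUSTER_COUNT_SD",
    "RANDOM_CLUSTER_SIZE_LOG_MEDIAN",
    "RANDOM_CLUSTER_SIZE_LOG_SD",
]

# Null-model distribution parameters, matched to the observed TAD partition
# (2,880 clusters; probes-per-cluster median 82).
RANDOM_CLUSTER_COUNT_MEAN = 2880.0
RANDOM_CLUSTER_COUNT_SD = 144.0
RANDOM_CLUSTER_SIZE_LOG_MEDIAN = 82.0
RANDOM_CLUSTER_SIZE_LOG_SD = 0.7

# A vanishing correlation threshold is the conventional way to turn the CMR
# construction into a pure proximity (sliding-window) chain; thresholds at or
# below this value disable the correlation predicate entirely, so the
# degeneration is exact even where adjacent probes happen to correlate
# negatively.
CORLO_BYPASS = 1e-9


@dataclass(frozen=True)
class CmrParams:
    """Knobs of the co-methylated-region chaining.

    corlo
        Pearson correlation threshold for adjacent probes, in [0, 1].
    maxprbdst
        Maximum genomic distance (bp) between adjacent probes.
    corlodst
        Maximum gap (bp) between consecutive reference CpGs lying between
        the two probes (probe positions included as endpoints); only used
        when a CpG reference map is supplied.
    """

    corlo: float = 0.2
    maxprbdst: int = 100_000
    corlodst: int = 800

    def __post_init__(self):
        if not 0 <= self.corlo <= 1:
            raise ValueError("corlo must be in [0, 1]")
        if self.maxprbdst <= 0 or self.corlodst <= 0:
            raise ValueError("maxprbdst and corlodst must be positive")


@dataclass(frozen=True)
class ClusterSummary:
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    pct_nonsingleton_probes: float
    n_clusters: int
    n_probes: int


@dataclass(frozen=True)
class ClusterSet:
    """A partition of the probe set into clusters with dense ids 0..C-1."""

    assignment: dict  # probe_id -> cluster_id
    n_clusters: int
    label: str

    def __post_init__(self):
        cids = set(self.assignment.values())
        if cids != set(range(self.n_clusters)):
            raise ValidationError(
                f"cluster ids not dense 0..{self.n_clusters - 1} in {self.label!r}"
            )

    @classmethod
    def from_labels(cls, probe_ids, labels, label: str) -> "ClusterSet":
        """Build from arbitrary per-probe labels, densifying cluster ids.

        Dense ids follow first appearance in probe order, so the same
        labelling always produces the same ClusterSet.
        """
        remap: dict = {}
        assignment = {}
        for pid, lab in zip(probe_ids, labels):
            if lab not in remap:
                remap[lab] = len(remap)
            assignment[pid] = remap[lab]
        return cls(assignment=assignment, n_clusters=len(remap), label=label)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.assignment)

    def members(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_clusters)]
        for pid, cid in self.assignment.items():
            out[cid].append(pid)
        return out

    def sizes(self) -> np.ndarray:
        counts = np.zeros(self.n_clusters, dtype=int)
        for cid in self.assignment.values():
            counts[cid] += 1
        return counts

    def __len__(self) -> int:
        return len(self.assignment)


# ---------------------------------------------------------------------------
# constructions


def _per_chrom_sorted(ann: ProbeAnnotation):
    df = ann.frame.copy()
    df["_c"] = df["chrom"].map(normalize_chrom)
    for chrom, sub in df.groupby("_c", sort=True):
        sub = sub.sort_values(["pos", "probe_id"], kind="mergesort")
        yield chrom, sub["probe_id"].tolist(), sub["pos"].to_numpy(int)


def sliding_window_clusters(ann: ProbeAnnotation, window: int) -> ClusterSet:
    """Chain position-sorted probes whose gap is at most ``window`` bp.

    Per chromosome, maximal runs of consecutive probes with pairwise gap
    <= window form one cluster each.  Standard window sizes in this setting
    are 5 kb, 10 kb, 20 kb, 100 kb, 500 kb and 1 Mb.
    """
    if window < 1:
        raise ValueError("window must be >= 1 bp")
    probe_ids: list[str] = []
    labels: list[int] = []
    next_label = 0
    for _, pids, pos in _per_chrom_sorted(ann):
        for i, pid in enumerate(pids):
            if i > 0 and pos[i] - pos[i - 1] > window:
                next_label += 1
            probe_ids.append(pid)
            labels.append(next_label)
        next_label += 1
    return ClusterSet.from_labels(probe_ids, labels, f"window:{window}")


def cmr_clusters(
    ann: ProbeAnnotation,
    mat: MethylationMatrix,
    params: CmrParams,
    cpg_positions: dict | None = None,
) -> ClusterSet:
    """Chain probes into co-methylated regions.

    Adjacent probes (position-sorted per chromosome) join one cluster iff

    1. their genomic gap is <= ``maxprbdst``;
    2. the Pearson correlation of their methylation rows is >= ``corlo``
       (skipped entirely when ``corlo`` <= :data:`CORLO_BYPASS`, e.g. the
       conventional bypass value 1e-10);
    3. if ``cpg_positions`` (normalized chrom -> sorted reference CpG
       positions) is given, every gap between consecutive reference CpGs
       between the two probes — with the probe positions themselves as
       endpoints — is <= ``corlodst``.

    Clusters are the maximal chains under this adjacency.  A zero-variance
    methylation row makes the correlation undefined; such pairs fail
    predicate 2 (conservative: the probes stay unlinked).

    With ``corlo`` <= 1e-9 and ``corlodst = maxprbdst = w`` and no CpG map
    this degenerates exactly to :func:`sliding_window_clusters` with
    window ``w``.
    """
    if len(mat.sample_ids) < 3:
        raise ValidationError("CMR construction needs >= 3 samples for correlations")
    row_idx = {p: i for i, p in enumerate(mat.probe_ids)}
    missing = [p for p in ann.probe_ids if p not in row_idx]
    if missing:
        raise ValidationError(f"matrix lacks annotated probe {missing[0]!r}")
    probe_ids: list[str] = []
    labels: list[int] = []
    next_label = 0
    for chrom, pids, pos in _per_chrom_sorted(ann):
        cpgs = None
        if cpg_positions is not None:
            cpgs = np.asarray(
                cpg_positions.get(chrom, cpg_positions.get(f"chr{chrom}", [])), dtype=int
            )
        for i, pid in enumerate(pids):
            if i > 0:
                corr_ok = params.corlo <= CORLO_BYPASS or (
                    _pearson(mat.values[row_idx[pids[i - 1]]], mat.values[row_idx[pid]])
                    >= params.corlo
                )
                linked = (
                    pos[i] - pos[i - 1] <= params.maxprbdst
                    and corr_ok
                    and _cpg_gaps_ok(pos[i - 1], pos[i], cpgs, params.corlodst)
                )
                if not linked:
                    next_label += 1
            probe_ids.append(pid)
            labels.append(next_label)
        next_label += 1
    label = f"cmr:corlo={params.corlo},maxprbdst={params.maxprbdst},corlodst={params.corlodst}"
    return ClusterSet.from_labels(probe_ids, labels, label)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:  # zero-variance row: undefined, treated as no correlation
        return -np.inf
    return float((xc @ yc) / denom)


def _cpg_gaps_ok(p1: int, p2: int, cpgs: np.ndarray | None, corlodst: int) -> bool:
    if cpgs is None:
        return True
    inner = cpgs[(cpgs > p1) & (cpgs < p2)]
    pts = np.concatenate(([p1], inner, [p2]))
    return bool(np.all(np.diff(pts) <= corlodst))


def tad_clusters(ann: ProbeAnnotation, tads: IntervalSet) -> ClusterSet:
    """Assign each probe to the TAD interval containing it.

    Containment uses the 0-based half-open interval convention against the
    probe's 0-based position (1-based position minus one).  Probes covered by
    no interval become singleton clusters; probes covered by several go to
    the interval with the smallest start (ties: smallest end).
    """
    trees: dict[str, IntervalTree] = {}
    for rec in tads.frame.itertuples(index=False):
        trees.setdefault(normalize_chrom(rec.chrom), IntervalTree()).addi(
            rec.start, rec.end, rec.interval_id
        )
    probe_ids: list[str] = []
    labels: list[str] = []
    for _, row in ann.frame.iterrows():
        pid = row["probe_id"]
        tree = trees.get(normalize_chrom(row["chrom"]))
        p0 = int(row["pos"]) - 1
        hits = sorted(tree[p0], key=lambda iv: (iv.begin, iv.end)) if tree else []
        probe_ids.append(pid)
        labels.append(f"tad::{hits[0].data}" if hits else f"singleton::{pid}")
    return ClusterSet.from_labels(probe_ids, labels, "tad")


def sample_cluster_sizes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Raw (un-rounded) draws from the null-model cluster-size distribution.

    Sizes follow LogNormal with log-scale mean log(82) and log-scale SD 0.7,
    so the analytic median is 82 probes.
    """
    return rng.lognormal(
        mean=np.log(RANDOM_CLUSTER_SIZE_LOG_MEDIAN),
        sigma=RANDOM_CLUSTER_SIZE_LOG_SD,
        size=n,
    )


def sample_cluster_counts(n: int, rng: np.random.Generator) -> np.ndarray:
    """Raw (un-rounded) draws from the null-model cluster-count distribution."""
    return rng.normal(RANDOM_CLUSTER_COUNT_MEAN, RANDOM_CLUSTER_COUNT_SD, size=n)


def random_clusters(ann: ProbeAnnotation, n_sets: int, seed: int) -> list[ClusterSet]:
    """Draw ``n_sets`` random partitions as a structural null model.

    For each set, the cluster count C is a rounded Normal(2880, 144) draw
    (non-positive rounded draws are resampled) and each cluster's target
    size a rounded LogNormal(log 82, 0.7) draw clamped to >= 1.  A single
    random permutation of the probes is partitioned according to the drawn
    sizes; if the drawn sizes overshoot the probe total the tail clusters
    are truncated or dropped, and any probes left over become singletons.
    Chromosome coherence is deliberately not enforced — the null model must
    carry no genomic structure.

    Each set uses its own seeded stream (``seed + set index``), so individual
    sets are reproducible in isolation.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    out = []
    probe_arr = np.array(ann.probe_ids)
    m = len(probe_arr)
    for k in range(n_sets):
        rng = np.random.default_rng(seed + k)
        c = 0
        while c < 1:
            c = int(np.rint(sample_cluster_counts(1, rng)[0]))
        sizes = np.maximum(1, np.rint(sample_cluster_sizes(c, rng)).astype(int))
        perm = rng.permutation(m)
        labels = np.empty(m, dtype=int)
        start = 0
        cid = 0
        for s in sizes:
            if start >= m:
                break
            stop = min(start + int(s), m)
            labels[perm[start:stop]] = cid
            cid += 1
            start = stop
        while start < m:  # undershoot: leftovers become singletons
            labels[perm[start]] = cid
            cid += 1
            start += 1
        out.append(
            ClusterSet.from_labels(probe_arr.tolist(), labels.tolist(), f"random:{k}")
        )
    return out


# ---------------------------------------------------------------------------
# summaries and filters


def cluster_summary(cs: ClusterSet) -> ClusterSummary:
    """Five-number summary (plus mean) of probes-per-cluster, and the
    percentage of probes that sit in non-singleton clusters."""
    sizes = cs.sizes()
    if sizes.size == 0:
        raise ValidationError("empty cluster set")
    q1, med, q3 = np.percentile(sizes, [25, 50, 75])
    n_probes = int(sizes.sum())
    nonsingleton = int(sizes[sizes >= 2].sum())
    return ClusterSummary(
        min=float(sizes.min()),
        q1=float(q1),
        median=float(med),
        mean=float(sizes.mean()),
        q3=float(q3),
        max=float(sizes.max()),
        pct_nonsingleton_probes=100.0 * nonsingleton / n_probes,
        n_clusters=cs.n_clusters,
        n_probes=n_probes,
    )


def drop_singletons(cs: ClusterSet) -> tuple[ClusterSet, int]:
    """Remove probes in singleton clusters; returns (new set, removed count)."""
    sizes = cs.sizes()
    keep_pids = [pid for pid, cid in cs.assignment.items() if sizes[cid] >= 2]
    n_dropped = len(cs) - len(keep_pids)
    if not keep_pids:
        raise ValidationError("dropping singletons leaves no probes")
    labels = [cs.assignment[p] for p in keep_pids]
    return (
        ClusterSet.from_labels(keep_pids, labels, cs.label + ",nosingleton"),
        n_dropped,
    )


def write_cluster_assignments(cs: ClusterSet, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        {"probe_id": list(cs.assignment), "cluster_id": list(cs.assignment.values())}
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_cluster_assignments(path, label: str = "from-file") -> ClusterSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ClusterSet.from_labels(
        df["probe_id"].astype(str).tolist(), df["cluster_id"].tolist(), label
    )
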