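"""Readers, writers and validated in-memory containers for every on-disk artifact.

The pipeline touches five kinds of files: MWAS summary statistics (TSV),
individual-level methylation matrices (probes x samples, TSV/CSV of
residualized beta values), probe annotations (probe -> chromosome, 1-based
position), TAD scaffolds (BED, 0-based half-open), and binary phenotype
tables.  Each reader validates strictly and raises :class:`FormatError` or
:class:`ValidationError` with enough context (row, probe, line) to locate the
offending record.

Chromosome labels are normalized to a single internal form (no ``chr``
prefix) so mixed manifest/BED dialects interoperate.  Probe positions are
1-based (array-manifest convention); BED intervals stay 0-based half-open and
the containment test converts probe position ``p`` to ``p - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ProbeAnnotation",
    "SummaryStatsTable",
    "MethylationMatrix",
    "IntervalSet",
    "PhenotypeTable",
    "normalize_chrom",
    "read_summary_stats",
    "write_summary_stats",
    "read_methylation_matrix",
    "write_methylation_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_tad_scaffold",
    "read_phenotypes",
    "write_phenotypes",
    "read_scores",
    "write_scores",
    "intersect_probes",
]


class FormatError(ValueError):
    """A file does not conform to its declared layout (columns, delimiters)."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant (range, uniqueness)."""


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label by stripping any ``chr``/``Chr`` prefix."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def _read_table(path) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    try:
        return pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe genomic coordinates: probe id -> (chromosome, 1-based position)."""

    frame: pd.DataFrame  # columns: probe_id, chrom, pos

    def __post_init__(self):
        df = self.frame
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe id in annotation: {dup!r}")
        if (df["pos"] < 1).any():
            bad = df.loc[df["pos"] < 1, "probe_id"].iloc[0]
            raise ValidationError(f"position < 1 for probe {bad!r}")

    @property
    def probe_ids(self) -> list[str]:
        return self.frame["probe_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)

    def sorted(self) -> "ProbeAnnotation":
        """Canonical (chrom, pos, probe_id) order; ties broken lexically."""
        df = self.frame.copy()
        df["_c"] = df["chrom"].map(normalize_chrom)
        df = df.sort_values(["_c", "pos", "probe_id"], kind="mergesort")
        return ProbeAnnotation(df.drop(columns="_c").reset_index(drop=True))

    def subset(self, probe_ids) -> "ProbeAnnotation":
        keep = set(probe_ids)
        return ProbeAnnotation(
            self.frame[self.frame["probe_id"].isin(keep)].reset_index(drop=True)
        )


@dataclass(frozen=True)
class SummaryStatsTable:
    """Per-probe marginal MWAS statistics: effect, SE, sample size, p-value."""

    frame: pd.DataFrame  # columns: probe_id, beta, se, n, p

    def __post_init__(self):
        df = self.frame
        required = {"probe_id", "beta", "se", "n", "p"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"summary stats missing columns: {sorted(missing)}")
        for col in ("beta", "se", "n", "p"):
            na = df[col].isna()
            if na.any():
                row = int(np.flatnonzero(na.to_numpy())[0])
                raise ValidationError(
                    f"missing {col!r} at row {row} (probe {df['probe_id'].iloc[row]!r})"
                )
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe id in summary stats: {dup!r}")
        bad_se = df["se"] <= 0
        if bad_se.any():
            row = int(np.flatnonzero(bad_se.to_numpy())[0])
            raise ValidationError(
                f"se <= 0 at row {row} (probe {df['probe_id'].iloc[row]!r})"
            )
        if ((df["p"] <= 0) | (df["p"] > 1)).any():
            bad = df.loc[(df["p"] <= 0) | (df["p"] > 1), "probe_id"].iloc[0]
            raise ValidationError(f"p-value outside (0, 1] for probe {bad!r}")
        if (df["n"] < 2).any():
            bad = df.loc[df["n"] < 2, "probe_id"].iloc[0]
            raise ValidationError(f"n < 2 for probe {bad!r}")

    @property
    def probe_ids(self) -> list[str]:
        return self.frame["probe_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, probe_ids) -> "SummaryStatsTable":
        order = {p: i for i, p in enumerate(probe_ids)}
        df = self.frame[self.frame["probe_id"].isin(order)].copy()
        df = df.sort_values("probe_id", key=lambda s: s.map(order), kind="mergesort")
        return SummaryStatsTable(df.reset_index(drop=True))


@dataclass(frozen=True)
class MethylationMatrix:
    """Residualized methylation levels, probes x samples."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {v.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            seen = set()
            dup = next(p for p in self.probe_ids if p in seen or seen.add(p))
            raise ValidationError(f"duplicate probe id in matrix: {dup!r}")
        if np.isnan(v).any():
            i, j = map(int, np.argwhere(np.isnan(v))[0])
            raise ValidationError(
                f"NaN methylation value at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_ids.index(probe_id)]

    def subset(self, probe_ids) -> "MethylationMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [idx[p] for p in probe_ids]
        return MethylationMatrix(list(probe_ids), self.sample_ids, self.values[rows])

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return MethylationMatrix(self.probe_ids, list(sample_ids), self.values[:, cols])


@dataclass(frozen=True)
class IntervalSet:
    """Genomic intervals (BED convention: 0-based, half-open)."""

    frame: pd.DataFrame  # columns: chrom, start, end, interval_id
    n_overlaps: int = 0  # overlapping same-chromosome pairs found at load

    def __post_init__(self):
        df = self.frame
        required = {"chrom", "start", "end", "interval_id"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"interval set missing columns: {sorted(missing)}")
        bad = df["start"] >= df["end"]
        if bad.any():
            b = df[bad].iloc[0]
            raise ValidationError(
                f"interval start >= end: {b['chrom']}:{b['start']}-{b['end']}"
            )

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class PhenotypeTable:
    """Binary phenotype per sample (1 = case, 0 = control)."""

    frame: pd.DataFrame  # columns: sample_id, y

    def __post_init__(self):
        df = self.frame
        required = {"sample_id", "y"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not set(df["y"].unique()).issubset({0, 1}):
            raise ValidationError("phenotype values must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, sample_ids) -> "PhenotypeTable":
        order = {s: i for i, s in enumerate(sample_ids)}
        df = self.frame[self.frame["sample_id"].isin(order)].copy()
        df = df.sort_values("sample_id", key=lambda s: s.map(order), kind="mergesort")
        return PhenotypeTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# readers / writers


def read_summary_stats(path) -> SummaryStatsTable:
    """Read a summary-statistics TSV/CSV with columns probe_id, beta, se, n, p.

    Column order is free; optional chrom/pos columns are carried through
    untouched.  Delimiter is sniffed from the header line.
    """
    df = _read_table(path)
    return SummaryStatsTable(df)


def write_summary_stats(stats: SummaryStatsTable, path, header_comment: str | None = None) -> None:
    _write_tsv(stats.frame, path, header_comment)


def read_methylation_matrix(path) -> MethylationMatrix:
    """Read a probes x samples matrix; first column probe ids, header sample ids."""
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, comment="#", float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return MethylationMatrix(
        [str(p) for p in df.index], [str(s) for s in df.columns], df.to_numpy(float)
    )


def write_methylation_matrix(mat: MethylationMatrix, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(mat.values, index=mat.probe_ids, columns=mat.sample_ids)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index_label="probe_id")  # default str() is the shortest round-trip repr


def read_probe_annotation(path) -> ProbeAnnotation:
    df = _read_table(path)
    df["chrom"] = df["chrom"].astype(str)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path, header_comment: str | None = None) -> None:
    _write_tsv(ann.frame, path, header_comment)


def read_tad_scaffold(path) -> IntervalSet:
    """Read a BED3/BED4 scaffold of intervals (e.g. consensus TAD calls).

    The optional 4th column is the interval id; otherwise ids are generated
    as ``chrom:start-end``.  Overlapping intervals are permitted but counted,
    and a warning reports how many same-chromosome pairs overlap.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            iid = parts[3] if len(parts) >= 4 else f"{chrom}:{start}-{end}"
            records.append((chrom, start, end, iid))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "interval_id"])
    n_overlaps = _count_overlapping_pairs(df)
    if n_overlaps:
        warnings.warn(f"{n_overlaps} overlapping interval pair(s) in {path}", stacklevel=2)
    return IntervalSet(df, n_overlaps=n_overlaps)


def _count_overlapping_pairs(df: pd.DataFrame) -> int:
    """Count same-chromosome interval pairs that overlap (half-open)."""
    total = 0
    for _, sub in df.groupby(df["chrom"].map(normalize_chrom)):
        ivals = sorted(zip(sub["start"], sub["end"]))
        # sweep: compare each interval against actives whose end > start
        for i, (s, e) in enumerate(ivals):
            for s2, e2 in ivals[i + 1:]:
                if s2 >= e:
                    break
                total += 1
    return total


def read_phenotypes(path) -> PhenotypeTable:
    df = _read_table(path)
    if "y" not in df.columns and "status" in df.columns:
        df = df.rename(columns={"status": "y"})
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path, header_comment: str | None = None) -> None:
    _write_tsv(pheno.frame, path, header_comment)


def read_scores(path) -> pd.DataFrame:
    df = _read_table(path)
    if not {"sample_id", "score"}.issubset(df.columns):
        raise FormatError("scores file must have columns sample_id, score")
    return df


def write_scores(scores: pd.DataFrame, path, header_comment: str | None = None) -> None:
    _write_tsv(scores, path, header_comment)


def _write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)  # default str() is the shortest round-trip repr


# ---------------------------------------------------------------------------
# probe intersection


@dataclass(frozen=True)
class DropReport:
    """How many probes each input lost when restricting to the common set."""

    n_common: int
    dropped_from_stats: int
    dropped_from_matrix: int
    dropped_from_annotation: int


def intersect_probes(
    stats: SummaryStatsTable,
    mat: MethylationMatrix,
    ann: ProbeAnnotation,
) -> tuple[SummaryStatsTable, MethylationMatrix, ProbeAnnotation, DropReport]:
    """Restrict all three inputs to their common probes in canonical order.

    Only probes common to the training-side statistics and the test-side
    matrix (and annotated) enter the analysis.  The canonical order is
    (normalized chromosome, position, probe_id), a deterministic function of
    the annotation alone, so shuffled inputs yield identical outputs.
    """
    common = set(stats.probe_ids) & set(mat.probe_ids) & set(ann.probe_ids)
    if not common:
        raise ValidationError("no probes common to summary stats, matrix and annotation")
    ann_out = ann.subset(common).sorted()
    order = ann_out.probe_ids
    report = DropReport(
        n_common=len(common),
        dropped_from_stats=len(stats) - len(common),
        dropped_from_matrix=len(mat.probe_ids) - len(common),
        dropped_from_annotation=len(ann) - len(common),
    )
    return stats.subset(order), mat.subset(order), ann_out, report
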