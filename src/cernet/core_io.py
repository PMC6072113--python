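"""Domain types and readers/writers for the tabular formats used by the pipeline.

All genomic coordinates are 1-based and inclusive on both ends (GTF
convention).  Matrices are features x samples.  Delimiters are
auto-detected between tab and comma on read; all output is tab-delimited.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

FEATURE_KINDS = {"miRNA", "mRNA", "lncRNA", "mixed"}
UNITS = {"raw_count", "cpm", "rpkm", "log2", "zscore", "beta", "cna", "arbitrary"}
REGULATOR_KINDS = {"miRNA", "TF"}

__all__ = [
    "ExpressionMatrix",
    "InteractionTable",
    "GeneAnnotation",
    "ProbeAnnotation",
    "SegmentTable",
    "GeneSetCollection",
    "read_matrix",
    "write_matrix",
    "read_interactions",
    "write_interactions",
    "read_gmt",
    "write_gmt",
    "read_gene_annotation",
    "read_probe_annotation",
    "read_segments",
]


class FormatError(ValueError):
    """Raised on malformed input files or invariant violations."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    counts = pd.Series(list(ids)).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise FormatError(f"duplicate {what}: {sorted(dups)}")


@dataclass
class ExpressionMatrix:
    """A feature-by-sample numeric matrix with unit and kind metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
    feature_kind
        One of ``miRNA``, ``mRNA``, ``lncRNA``, ``mixed``.
    unit
        One of ``raw_count``, ``cpm``, ``rpkm``, ``log2``, ``zscore``,
        ``beta``, ``cna``, ``arbitrary``.
    sample_groups
        Optional map sample id -> ``normal`` | ``tumor``.
    """

    values: pd.DataFrame
    feature_kind: str = "mixed"
    unit: str = "arbitrary"
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise FormatError(f"unknown feature_kind {self.feature_kind!r}")
        if self.unit not in UNITS:
            raise FormatError(f"unknown unit {self.unit!r}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if np.isnan(arr).any():
            rows, cols = np.nonzero(np.isnan(arr))
            raise FormatError(
                f"missing value at feature {self.values.index[rows[0]]!r}, "
                f"sample {self.values.columns[cols[0]]!r}"
            )
        if self.unit == "raw_count" and (arr < 0).any():
            raise FormatError("raw_count matrix contains negative entries")
        if self.unit == "beta" and ((arr < 0) | (arr > 1)).any():
            raise FormatError("beta values must lie in [0, 1]")
        if self.unit == "zscore" and arr.shape[1] > 1:
            mu = arr.mean(axis=1)
            sd = arr.std(axis=1, ddof=0)
            if (np.abs(mu) > 1e-8).any() or (np.abs(sd - 1) > 1e-8).any():
                bad = self.values.index[
                    (np.abs(mu) > 1e-8) | (np.abs(sd - 1) > 1e-8)
                ][0]
                raise FormatError(
                    f"zscore matrix row {bad!r} is not standardized (mean 0, sd 1)"
                )
        bad_groups = {g for g in self.sample_groups.values()} - {"normal", "tumor"}
        if bad_groups:
            raise FormatError(f"unknown sample groups: {sorted(bad_groups)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_groups.get(s) == group]

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [f for f in feature_ids]
        missing = set(ids) - set(self.values.index)
        if missing:
            raise KeyError(f"features not in matrix: {sorted(missing)}")
        return ExpressionMatrix(
            self.values.loc[ids], self.feature_kind, self.unit, dict(self.sample_groups)
        )

    def row(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy(dtype=float)


@dataclass
class InteractionTable:
    """Directed regulator -> target pairs with provenance.

    ``table`` has columns ``regulator``, ``target``, ``regulator_kind``,
    ``source``.  Duplicate (regulator, target, kind) triples are merged,
    joining their source tags with ``;``.
    """

    table: pd.DataFrame

    COLUMNS = ("regulator", "target", "regulator_kind", "source")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"interaction table missing columns: {sorted(missing)}")
        bad = set(self.table["regulator_kind"]) - REGULATOR_KINDS
        if bad:
            raise FormatError(f"unknown regulator kinds: {sorted(bad)}")
        self.table = _dedupe_interactions(self.table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["regulator"], self.table["target"]))

    def regulators_of(self, target: str) -> set[str]:
        t = self.table
        return set(t.loc[t["target"] == target, "regulator"])

    def targets_of(self, regulator: str) -> set[str]:
        t = self.table
        return set(t.loc[t["regulator"] == regulator, "target"])

    def targets_to_regulators(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for reg, tgt in zip(self.table["regulator"], self.table["target"]):
            out.setdefault(tgt, set()).add(reg)
        return out

    def union(self, other: "InteractionTable") -> "InteractionTable":
        return InteractionTable(pd.concat([self.table, other.table], ignore_index=True))


def _dedupe_interactions(df: pd.DataFrame) -> pd.DataFrame:
    def join_sources(s: pd.Series) -> str:
        seen: list[str] = []
        for tag in s:
            for part in str(tag).split(";"):
                if part and part not in seen:
                    seen.append(part)
        return ";".join(seen)

    out = (
        df.groupby(["regulator", "target", "regulator_kind"], sort=True, as_index=False)
        .agg(source=("source", join_sources))
    )
    return out[["regulator", "target", "regulator_kind", "source"]].reset_index(drop=True)


@dataclass
class GeneAnnotation:
    """Gene coordinates with strand-aware transcription start sites.

    1-based inclusive coordinates; tss = start on '+' strand, end on '-'.
    """

    table: pd.DataFrame  # gene_id, chromosome, start, end, strand, tss

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t["gene_id"], "gene ids")
        if (t["start"] > t["end"]).any():
            bad = t.loc[t["start"] > t["end"], "gene_id"].iloc[0]
            raise FormatError(f"gene {bad!r} has start > end")
        bad_strand = set(t["strand"]) - {"+", "-"}
        if bad_strand:
            raise FormatError(f"unknown strand values: {sorted(bad_strand)}")
        if "tss" not in t.columns:
            t = t.assign(tss=np.where(t["strand"] == "+", t["start"], t["end"]))
            self.table = t
        else:
            expect = np.where(t["strand"] == "+", t["start"], t["end"])
            if (t["tss"].to_numpy() != expect).any():
                raise FormatError("tss inconsistent with strand convention")

    def get(self, gene_id: str):
        t = self.table
        hit = t[t["gene_id"] == gene_id]
        return None if hit.empty else hit.iloc[0]


@dataclass
class ProbeAnnotation:
    table: pd.DataFrame  # probe_id, chromosome, position

    def __post_init__(self) -> None:
        _check_unique(self.table["probe_id"], "probe ids")


@dataclass
class SegmentTable:
    """Per-sample copy-number segments; overlap within a sample is an error."""

    table: pd.DataFrame  # sample_id, chromosome, start, end, segment_mean

    def __post_init__(self) -> None:
        t = self.table
        if (t["start"] > t["end"]).any():
            raise FormatError("segment with start > end")
        for (sample, chrom), grp in t.groupby(["sample_id", "chromosome"]):
            g = grp.sort_values("start")
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            if (starts[1:] <= ends[:-1]).any():
                raise FormatError(
                    f"overlapping segments for sample {sample!r} on {chrom!r}"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets, as carried by GMT files."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(
    path: str | Path,
    unit: str = "arbitrary",
    feature_kind: str = "mixed",
    sample_groups: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a delimited feature-by-sample matrix.

    First column holds feature ids, header row holds sample ids.  Any
    non-numeric or missing cell raises :class:`FormatError` naming the
    offending row and column.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    _check_unique(df.index, "feature ids")
    _check_unique(df.columns, "sample ids")
    try:
        # Python float() is correctly rounded; pandas' default parser is not
        num = df.apply(lambda col: col.map(float))
    except (ValueError, TypeError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise FormatError(
                    f"non-numeric cell at feature {df.index[bad.argmax()]!r}, "
                    f"sample {col!r}"
                ) from None
        raise
    return ExpressionMatrix(
        num.astype(float), feature_kind, unit, dict(sample_groups or {})
    )


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    # %.17g round-trips float64 exactly
    m.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")


def read_interactions(
    path: str | Path, regulator_kind: str = "miRNA", source_tag: str = ""
) -> InteractionTable:
    """Read a two-column (regulator, target) list; dedupe; attach provenance."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.empty:
        raise FormatError(f"empty interaction file: {path}")
    # tolerate a header line naming the columns
    if str(df.iloc[0, 0]).lower() in {"regulator", "mirna", "tf"}:
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise FormatError(f"interaction file needs >= 2 columns: {path}")
    out = pd.DataFrame(
        {
            "regulator": df.iloc[:, 0].astype(str),
            "target": df.iloc[:, 1].astype(str),
            "regulator_kind": regulator_kind,
            "source": source_tag or path.stem,
        }
    )
    return InteractionTable(out)


def write_interactions(t: InteractionTable, path: str | Path) -> None:
    t.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name TAB description TAB member...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            if not members:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(c: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in c.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def _read_annotation_frame(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = set(columns) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    df = _read_annotation_frame(
        path, ["gene_id", "chromosome", "start", "end", "strand"]
    )
    return GeneAnnotation(df)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = _read_annotation_frame(path, ["probe_id", "chromosome", "position"])
    return ProbeAnnotation(df)


def read_segments(path: str | Path) -> SegmentTable:
    df = _read_annotation_frame(
        path, ["sample_id", "chromosome", "start", "end", "segment_mean"]
    )
    return SegmentTable(df)
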