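"""Canonical data types and file formats.

All coordinates are 0-based half-open. A CpG site is identified by the
position of its plus-strand cytosine. Tables are kept sorted by
``(chrom, pos)`` with unique positions, so downstream window arithmetic can
rely on row order.

Formats
-------
count table          TSV ``chrom  pos  c  t`` (header optional)
reference methylome  bedGraph ``chrom  start  end  value`` with end = start+1
methylation map      bedGraph, missing sites omitted; optional ``.var`` track
annotations          BED6 (name/score/strand columns optional on input)
cohort manifest      YAML list or TSV of sample records
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError

__all__ = [
    "CpGCountTable",
    "ReferenceMethylome",
    "MethylationMap",
    "GenomicIntervalSet",
    "SampleRecord",
    "read_count_table",
    "read_reference_methylome",
    "write_methylation_map",
    "read_methylation_map",
    "make_promoter_intervals",
    "read_manifest",
    "write_manifest",
]


def _sort_key(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)


def _check_sorted_unique(df: pd.DataFrame, what: str) -> None:
    dup = df.duplicated(["chrom", "pos"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate position in {what}: {row['chrom']}:{int(row['pos'])}"
        )


@dataclass(frozen=True)
class CpGCountTable:
    """Per-sample (or pooled) cytosine/thymine counts at CpG positions.

    ``df`` has columns ``chrom`` (str), ``pos`` (int, plus-strand cytosine),
    ``c`` and ``t`` (non-negative ints). Coverage ``n = c + t`` is derived.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = {"chrom", "pos", "c", "t"} - set(df.columns)
        if missing:
            raise ValidationError(f"count table missing columns: {sorted(missing)}")
        df = df[["chrom", "pos", "c", "t"]].copy()
        df["chrom"] = df["chrom"].astype(str)
        for col in ("pos", "c", "t"):
            vals = pd.to_numeric(df[col], errors="raise")
            if (np.asarray(vals) % 1 != 0).any():
                raise ValidationError(f"non-integer value in column {col!r}")
            df[col] = vals.astype(np.int64)
        if (df["c"] < 0).any() or (df["t"] < 0).any():
            raise ValidationError("negative count in count table")
        if (df["pos"] < 0).any():
            raise ValidationError("negative position in count table")
        df = _sort_key(df)
        _check_sorted_unique(df, "count table")
        object.__setattr__(self, "df", df)

    @property
    def n(self) -> pd.Series:
        """Coverage per site."""
        return self.df["c"] + self.df["t"]

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read(cls, path: str | Path) -> "CpGCountTable":
        return read_count_table(path)

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, header=False)


def read_count_table(path: str | Path) -> CpGCountTable:
    """Read a TSV count table (``chrom  pos  c  t``; header optional)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["chrom", "pos"]:
                continue
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 fields")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), int(parts[3])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["chrom", "pos", "c", "t"])
    return CpGCountTable(df)


@dataclass(frozen=True)
class ReferenceMethylome:
    """Measured methylation in [0, 1] per CpG (e.g. WGBS of modern bone)."""

    df: pd.DataFrame  # columns chrom, pos, m

    def __post_init__(self) -> None:
        df = self.df[["chrom", "pos", "m"]].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["m"] = df["m"].astype(float)
        if ((df["m"] < 0) | (df["m"] > 1)).any():
            raise ValidationError("reference methylation outside [0, 1]")
        df = _sort_key(df)
        _check_sorted_unique(df, "reference methylome")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read(cls, path: str | Path) -> "ReferenceMethylome":
        return read_reference_methylome(path)

    def write(self, path: str | Path) -> None:
        out = self.df.assign(end=self.df["pos"] + 1)
        out[["chrom", "pos", "end", "m"]].to_csv(
            path, sep="\t", index=False, header=False, float_format="%.6f"
        )


def read_reference_methylome(path: str | Path) -> ReferenceMethylome:
    """Read a per-CpG bedGraph (``chrom  start  end  value``, end = start+1)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 fields")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if end != start + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected single-base interval"
                )
            rows.append((parts[0], start, value))
    return ReferenceMethylome(pd.DataFrame(rows, columns=["chrom", "pos", "m"]))


@dataclass(frozen=True)
class MethylationMap:
    """Reconstructed methylation per CpG.

    Columns: ``chrom``, ``pos``, ``m_hat`` (NaN = missing), ``var`` (NaN where
    undefined) and ``n_window`` (total window coverage behind the estimate).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (("var", np.nan), ("n_window", np.nan)):
            if col not in df.columns:
                df[col] = default
        df = df[["chrom", "pos", "m_hat", "var", "n_window"]]
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        m = df["m_hat"].astype(float)
        ok = m.isna() | ((m >= 0) & (m <= 1))
        if not ok.all():
            raise ValidationError("m_hat outside [0, 1]")
        v = df["var"].astype(float)
        if ((v < 0) & v.notna()).any():
            raise ValidationError("negative variance")
        df = _sort_key(df)
        _check_sorted_unique(df, "methylation map")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def present(self) -> pd.DataFrame:
        """Rows with a defined estimate."""
        return self.df[self.df["m_hat"].notna()]

    def write(self, path: str | Path, var_path: str | Path | None = None) -> None:
        write_methylation_map(self, path, var_path)

    @classmethod
    def read(cls, path: str | Path) -> "MethylationMap":
        return read_methylation_map(path)


def write_methylation_map(
    map_: MethylationMap, path: str | Path, var_path: str | Path | None = None
) -> None:
    """bedGraph output; sites without an estimate are omitted."""
    present = map_.present
    out = present.assign(end=present["pos"] + 1)
    out[["chrom", "pos", "end", "m_hat"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6f"
    )
    if var_path is not None:
        with_var = present[present["var"].notna()]
        out = with_var.assign(end=with_var["pos"] + 1)
        out[["chrom", "pos", "end", "var"]].to_csv(
            var_path, sep="\t", index=False, header=False, float_format="%.6g"
        )


def read_methylation_map(path: str | Path) -> MethylationMap:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "end", "m_hat"],
        dtype={"chrom": str},
    )
    if len(df) == 0:
        df = pd.DataFrame(columns=["chrom", "pos", "m_hat"])
    return MethylationMap(df[["chrom", "pos", "m_hat"]])


@dataclass(frozen=True)
class GenomicIntervalSet:
    """BED-style intervals (0-based half-open) with optional name/strand."""

    df: pd.DataFrame  # columns chrom, start, end, name, strand

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "name" not in df.columns:
            df["name"] = "."
        if "strand" not in df.columns:
            df["strand"] = "."
        df = df[["chrom", "start", "end", "name", "strand"]]
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValidationError("interval with start >= end")
        bad = ~df["strand"].isin(["+", "-", "."])
        if bad.any():
            raise ValidationError(f"unknown strand {df['strand'][bad].iloc[0]!r}")
        df = df.sort_values(["chrom", "start", "end"], ignore_index=True)
        object.__setattr__(self, "df", df)
        object.__setattr__(self, "_merged", None)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_bed(cls, path: str | Path) -> "GenomicIntervalSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        df = df.iloc[:, : min(6, df.shape[1])]
        names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
        df.columns = names
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        keep = [c for c in ("chrom", "start", "end", "name", "strand") if c in df]
        return cls(df[keep])

    def write_bed(self, path: str | Path) -> None:
        out = self.df.assign(score=0)
        out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            path, sep="\t", index=False, header=False
        )

    def _merged_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        # overlap-merged intervals per chromosome, for membership queries
        if self.__dict__.get("_merged") is None:
            merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, sub in self.df.groupby("chrom", sort=False):
                starts, ends = [], []
                for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                    if starts and s <= ends[-1]:
                        ends[-1] = max(ends[-1], e)
                    else:
                        starts.append(s)
                        ends.append(e)
                merged[chrom] = (np.asarray(starts), np.asarray(ends))
            object.__setattr__(self, "_merged", merged)
        return self.__dict__["_merged"]

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside any interval."""
        pos = np.asarray(pos)
        merged = self._merged_by_chrom().get(str(chrom))
        if merged is None:
            return np.zeros(pos.shape, dtype=bool)
        starts, ends = merged
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < ends[idx[ok]]
        return out

    def mask(self, chrom: pd.Series, pos: pd.Series) -> np.ndarray:
        """Vectorised ``contains`` over a (chrom, pos) frame."""
        out = np.zeros(len(pos), dtype=bool)
        frame = pd.DataFrame({"chrom": np.asarray(chrom), "pos": np.asarray(pos)})
        for c, sub in frame.groupby("chrom", sort=False):
            out[sub.index] = self.contains(c, sub["pos"].to_numpy())
        return out


def make_promoter_intervals(tss: pd.DataFrame, upstream: int = 5000,
                            downstream: int = 1000) -> GenomicIntervalSet:
    """Promoter intervals around transcription start sites.

    A promoter spans ``upstream`` bases upstream to ``downstream`` bases
    downstream of the TSS, oriented by strand and clipped at zero.
    """
    req = {"chrom", "pos", "strand"}
    if not req <= set(tss.columns):
        raise ValidationError(f"TSS frame needs columns {sorted(req)}")
    strand = tss["strand"].astype(str)
    if (~strand.isin(["+", "-"])).any():
        raise ValidationError("TSS strand must be '+' or '-'")
    pos = tss["pos"].astype(np.int64)
    plus = strand == "+"
    start = np.where(plus, pos - upstream, pos - downstream)
    end = np.where(plus, pos + downstream, pos + upstream)
    start = np.clip(start, 0, None)
    df = pd.DataFrame({
        "chrom": tss["chrom"].astype(str),
        "start": start,
        "end": end,
        "name": tss["name"] if "name" in tss.columns else ".",
        "strand": strand,
    })
    return GenomicIntervalSet(df)


@dataclass
class SampleRecord:
    """One cohort member: count-table path plus screening metadata."""

    sample_id: str
    path: str = ""
    autosomal_snp_hits: int = 0
    sex: str = "unknown"
    skeletal_element: str = ""

    def __post_init__(self) -> None:
        if self.autosomal_snp_hits < 0:
            raise ValidationError("autosomal_snp_hits must be >= 0")
        if self.sex not in ("F", "M", "unknown"):
            raise ValidationError(f"sex must be F, M or unknown, got {self.sex!r}")


_MANIFEST_FIELDS = ["sample_id", "path", "autosomal_snp_hits", "sex",
                    "skeletal_element"]


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Cohort manifest from YAML (list of mappings) or TSV with header."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(text) or []
    else:
        df = pd.read_csv(io.StringIO(text), sep="\t")
        raw = df.to_dict("records")
    records = []
    for entry in raw:
        entry = {k: v for k, v in entry.items() if k in _MANIFEST_FIELDS}
        entry["autosomal_snp_hits"] = int(entry.get("autosomal_snp_hits", 0))
        records.append(SampleRecord(**entry))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in manifest")
    return records


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {f: getattr(r, f) for f in _MANIFEST_FIELDS} for r in records
    ]
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(rows, sort_keys=False))
    else:
        pd.DataFrame(rows, columns=_MANIFEST_FIELDS).to_csv(path, sep="\t",
                                                            index=False)
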