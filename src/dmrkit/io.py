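"""Readers and writers for the file formats the pipeline touches.

The central in-memory container is :class:`MethylomeTrack`, a per-sample table
of per-cytosine methylation calls in the Bismark cytosine-report dialect::

    chrom  pos(1-based)  strand  n_meth  n_unmeth  context[  trinucleotide]

Coordinates are 1-based in report files and inside tracks (matching the
extraction output); every *interval* handled by the package (annotation
features, bins, DMRs, BED output) is 0-based half-open.

Strands are never collapsed: the two cytosines of a symmetric CG dyad remain
separate records, as in the extraction output.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    ConsistencyError,
    FormatError,
    ParseError,
    ValidationError,
)

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")
FEATURE_CLASSES = ("gene", "TEG", "TE")

#: column schema of ``MethylomeTrack.data``
TRACK_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]

#: column schema of ``FeatureAnnotation.data``
ANNOTATION_COLUMNS = ["chrom", "start", "end", "feature_class", "feature_id"]


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's methylation evidence in one sample."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"bad context {self.context!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValidationError("negative read count")


def _normalise_track_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, TRACK_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    df["strand"] = df["strand"].astype(str)
    df["context"] = df["context"].astype(str)
    df["n_meth"] = df["n_meth"].astype(np.int64)
    df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        raise ValidationError(
            f"unknown context symbol(s): {sorted(df.loc[bad_ctx, 'context'].unique())}"
        )
    bad_strand = ~df["strand"].isin(STRANDS)
    if bad_strand.any():
        raise ValidationError(
            f"unknown strand symbol(s): {sorted(df.loc[bad_strand, 'strand'].unique())}"
        )
    if (df[["n_meth", "n_unmeth"]].to_numpy() < 0).any():
        raise ValidationError("negative read counts")
    df = df.sort_values(["chrom", "pos", "strand"], kind="stable", ignore_index=True)
    dup = df.duplicated(["chrom", "pos", "strand"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ConsistencyError(
            f"duplicate record at {row.chrom}:{row.pos}({row.strand})"
        )
    return df


@dataclass
class MethylomeTrack:
    """A sample's position-sorted collection of cytosine records.

    ``data`` columns follow :data:`TRACK_COLUMNS`; rows are sorted by
    (chrom, pos, strand) and unique on that key.
    """

    data: pd.DataFrame
    sample_id: str = ""
    cell_type: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        self.data = _normalise_track_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def coverage(self) -> pd.Series:
        return self.data["n_meth"] + self.data["n_unmeth"]

    def filter_coverage(self, min_coverage: int) -> "MethylomeTrack":
        """Return a track retaining records with coverage >= ``min_coverage``."""
        if min_coverage < 0:
            raise ValidationError("min_coverage must be >= 0")
        keep = self.data[self.coverage >= min_coverage].reset_index(drop=True)
        return MethylomeTrack(keep, self.sample_id, self.cell_type, self.replicate)

    def records(self) -> Iterable[CytosineRecord]:
        for row in self.data.itertuples(index=False):
            yield CytosineRecord(
                row.chrom, int(row.pos), row.strand, row.context,
                int(row.n_meth), int(row.n_unmeth),
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[CytosineRecord | tuple],
        sample_id: str = "",
        cell_type: str = "",
        replicate: int = 1,
    ) -> "MethylomeTrack":
        rows = [
            (r.chrom, r.pos, r.strand, r.context, r.n_meth, r.n_unmeth)
            if isinstance(r, CytosineRecord) else tuple(r)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
        if not rows:
            df = _empty_track_frame()
        return cls(df, sample_id, cell_type, replicate)


def _empty_track_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype=np.int64),
            "n_unmeth": pd.Series(dtype=np.int64),
        }
    )


def read_cytosine_report(
    path: str | Path,
    min_coverage: int = 0,
    sample_id: str | None = None,
    cell_type: str = "",
    replicate: int = 1,
) -> MethylomeTrack:
    """Read a Bismark-style cytosine report into a :class:`MethylomeTrack`.

    Expected columns: chrom, pos (1-based), strand, count-methylated,
    count-unmethylated, context; a seventh trinucleotide column, if present,
    is ignored (the context column is authoritative). Records with coverage
    below ``min_coverage`` are dropped. An empty file yields an empty track.
    """
    path = Path(path)
    if min_coverage < 0:
        raise ValidationError("min_coverage must be >= 0")
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return MethylomeTrack(
            _empty_track_frame(), sample_id or path.stem, cell_type, replicate
        )
    if raw.shape[1] == 1:  # whitespace-delimited variant
        raw = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if raw.shape[1] < 6:
        raise ParseError(f"{path}: expected >= 6 columns, found {raw.shape[1]}")
    raw = raw.iloc[:, :6]
    raw.columns = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]

    for col in ("pos", "n_meth", "n_unmeth"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise ParseError(
                f"{path}: line {lineno}: non-numeric value {raw.loc[bad.idxmax(), col]!r}"
                f" in column {col}"
            )
        raw[col] = converted.astype(np.int64)
    bad_ctx = ~raw["context"].isin(CONTEXTS)
    if bad_ctx.any():
        lineno = int(bad_ctx.idxmax()) + 1
        raise ParseError(
            f"{path}: line {lineno}: unknown context symbol"
            f" {raw.loc[bad_ctx.idxmax(), 'context']!r}"
        )
    bad_strand = ~raw["strand"].isin(STRANDS)
    if bad_strand.any():
        lineno = int(bad_strand.idxmax()) + 1
        raise ParseError(
            f"{path}: line {lineno}: unknown strand"
            f" {raw.loc[bad_strand.idxmax(), 'strand']!r}"
        )
    track = MethylomeTrack(raw, sample_id or path.stem, cell_type, replicate)
    if min_coverage > 0:
        track = track.filter_coverage(min_coverage)
    return track


def write_cytosine_report(track: MethylomeTrack, path: str | Path) -> None:
    """Write a track back to the tab-separated cytosine-report dialect."""
    cols = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]
    track.data[cols].to_csv(path, sep="\t", header=False, index=False)


def pool_replicates(tracks: Sequence[MethylomeTrack]) -> MethylomeTrack:
    """Combine biological replicates by summing read counts per cytosine.

    A position present in only one input appears with that input's counts.
    Pooling precedes any coverage filtering in the pipeline, so that loci
    reaching the coverage floor only jointly are retained.
    """
    if not tracks:
        raise ValidationError("pool_replicates needs at least one track")
    cell_types = {t.cell_type for t in tracks}
    if len(cell_types) > 1:
        raise ValidationError(f"tracks mix cell types: {sorted(cell_types)}")
    cell_type = tracks[0].cell_type
    if len(tracks) == 1:
        t = tracks[0]
        return MethylomeTrack(t.data.copy(), f"{t.sample_id}_pooled", cell_type, 0)
    cat = pd.concat([t.data for t in tracks], ignore_index=True)
    ctx = cat.groupby(["chrom", "pos", "strand"], sort=True)["context"].agg(
        ["first", "nunique"]
    )
    conflict = ctx["nunique"] > 1
    if conflict.any():
        key = ctx.index[conflict.to_numpy().argmax()]
        raise ConsistencyError(f"conflicting contexts at {key[0]}:{key[1]}({key[2]})")
    counts = cat.groupby(["chrom", "pos", "strand"], sort=True)[
        ["n_meth", "n_unmeth"]
    ].sum()
    pooled = counts.join(ctx["first"].rename("context")).reset_index()
    sample_id = f"{cell_type or 'sample'}_pooled"
    return MethylomeTrack(pooled[TRACK_COLUMNS], sample_id, cell_type, 0)


# ---------------------------------------------------------------------------
# Annotation


@dataclass
class FeatureAnnotation:
    """Genomic feature intervals (gene / TEG / TE), 0-based half-open.

    ``data`` columns follow :data:`ANNOTATION_COLUMNS`.
    """

    data: pd.DataFrame
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.data.loc[:, ANNOTATION_COLUMNS].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["feature_class"] = df["feature_class"].astype(str)
        df["feature_id"] = df["feature_id"].astype(str)
        bad = df["end"] <= df["start"]
        if bad.any():
            row = df.loc[bad.idxmax()]
            raise FormatError(
                f"interval end <= start at {row.chrom}:{row.start}-{row.end}"
            )
        unknown = ~df["feature_class"].isin(FEATURE_CLASSES)
        if unknown.any():
            raise FormatError(
                "unknown feature class(es): "
                f"{sorted(df.loc[unknown, 'feature_class'].unique())}"
            )
        self.data = df.sort_values(["chrom", "start", "end"], ignore_index=True)
        self._trees = {}

    def __len__(self) -> int:
        return len(self.data)

    def tree(self, chrom: str):
        """Interval tree of features on one chromosome (lazily built)."""
        from intervaltree import IntervalTree

        if chrom not in self._trees:
            sub = self.data[self.data["chrom"] == chrom]
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(r.start), int(r.end), (r.feature_class, r.feature_id))
                for r in sub.itertuples(index=False)
            )
        return self._trees[chrom]

    def overlapping(self, chrom: str, start: int, end: int):
        """Features overlapping [start, end) as (start, end, class, id) tuples."""
        return sorted(
            (iv.begin, iv.end, iv.data[0], iv.data[1])
            for iv in self.tree(chrom).overlap(start, end)
        )

    @classmethod
    def empty(cls) -> "FeatureAnnotation":
        return cls(pd.DataFrame(columns=ANNOTATION_COLUMNS))


_GFF3_CLASS_MAP = {
    "gene": "gene",
    "mRNA": "gene",
    "transposable_element_gene": "TEG",
    "transposable_element": "TE",
    "repeat_region": "TE",
}


def _parse_gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


def read_annotation(
    path: str | Path,
    dialect: str | None = None,
    class_map: Mapping[str, str] | None = None,
) -> FeatureAnnotation:
    """Read gene/TEG/TE intervals from a BED or GFF3 file.

    Coordinates are normalised to 0-based half-open. For BED input the name
    column supplies the feature id; the feature class comes from ``class_map``
    (feature_id -> class) or, failing that, from a ``CLASS:id`` name prefix.
    For GFF3 the type column is mapped through the standard SO terms
    (``transposable_element_gene`` -> TEG etc.), overridable via ``class_map``
    keyed by GFF3 type.
    """
    path = Path(path)
    if dialect is None:
        dialect = "GFF3" if path.suffix.lower() in {".gff", ".gff3"} else "BED"
    dialect = dialect.upper()
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return FeatureAnnotation.empty()

    rows = []
    if dialect == "BED":
        if raw.shape[1] < 4:
            raise ParseError(f"{path}: BED annotation needs >= 4 columns")
        for i, r in enumerate(raw.itertuples(index=False), start=1):
            chrom, start, end, name = r[0], int(r[1]), int(r[2]), str(r[3])
            if class_map is not None and name in class_map:
                cls, fid = class_map[name], name
            elif ":" in name and name.split(":", 1)[0] in FEATURE_CLASSES:
                cls, fid = name.split(":", 1)
            else:
                raise ParseError(
                    f"{path}: line {i}: cannot determine feature class for {name!r}"
                )
            rows.append((chrom, start, end, cls, fid))
    elif dialect == "GFF3":
        if raw.shape[1] < 9:
            raise ParseError(f"{path}: GFF3 needs 9 columns")
        mapping = dict(_GFF3_CLASS_MAP)
        if class_map:
            mapping.update(class_map)
        for i, r in enumerate(raw.itertuples(index=False), start=1):
            ftype = str(r[2])
            if ftype not in mapping:
                continue
            start, end = int(r[3]) - 1, int(r[4])  # GFF3 is 1-based inclusive
            fid = _parse_gff3_attr(str(r[8]), "ID") or f"{ftype}_{i}"
            rows.append((str(r[0]), start, end, mapping[ftype], fid))
    else:
        raise ValidationError(f"unknown annotation dialect {dialect!r}")

    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    if df.empty:
        return FeatureAnnotation.empty()
    return FeatureAnnotation(df)


def write_annotation_bed(annotation: FeatureAnnotation, path: str | Path) -> None:
    """Write an annotation as BED4 with ``CLASS:id`` names (round-trippable)."""
    df = annotation.data.copy()
    df["name"] = df["feature_class"] + ":" + df["feature_id"]
    df[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bed(regions, path: str | Path) -> None:
    """Write scored intervals as sorted 6-column BED (0-based half-open).

    ``regions`` is a DataFrame with at least chrom/start/end (name, score and
    strand default to ".", 0 and ".") or an iterable of tuples in BED order.
    """
    if isinstance(regions, pd.DataFrame):
        df = regions.copy()
    else:
        rows = [tuple(r) for r in regions]
        cols = ["chrom", "start", "end", "name", "score", "strand"]
        df = pd.DataFrame(rows, columns=cols[: len(rows[0])] if rows else cols)
    if df.empty:
        Path(path).write_text("")
        return
    if "name" not in df:
        df["name"] = "."
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df = df[["chrom", "start", "end", "name", "score", "strand"]]
    df = df.sort_values(["chrom", "start", "end"], kind="stable")
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Sample manifest


@dataclass
class SampleManifest:
    """Maps (cell_type, replicate) to a cytosine-report path."""

    entries: dict
    genotype: str = "WT"
    base_dir: Path | None = None

    def __post_init__(self) -> None:
        paths = list(self.entries.values())
        if len(set(map(str, paths))) != len(paths):
            raise ConfigurationError("manifest references the same path twice")

    @property
    def cell_types(self) -> list[str]:
        return sorted({ct for ct, _ in self.entries})

    def replicates(self, cell_type: str) -> list[int]:
        reps = sorted(r for ct, r in self.entries if ct == cell_type)
        if not reps:
            raise ConfigurationError(f"no samples for cell type {cell_type!r}")
        return reps

    def path(self, cell_type: str, replicate: int) -> Path:
        p = Path(self.entries[(cell_type, replicate)])
        if self.base_dir is not None and not p.is_absolute():
            p = self.base_dir / p
        return p

    def load_tracks(self, cell_type: str, min_coverage: int = 0) -> list[MethylomeTrack]:
        return [
            read_cytosine_report(
                self.path(cell_type, rep),
                min_coverage=min_coverage,
                cell_type=cell_type,
                replicate=rep,
            )
            for rep in self.replicates(cell_type)
        ]

    def load_pooled(self, cell_type: str) -> MethylomeTrack:
        return pool_replicates(self.load_tracks(cell_type))


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a YAML/JSON manifest listing sample files, cell types, replicates."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or "samples" not in doc:
        raise ConfigurationError(f"{path}: manifest must contain a 'samples' list")
    entries = {}
    for i, s in enumerate(doc["samples"]):
        try:
            key = (str(s["cell_type"]), int(s.get("replicate", 1)))
            entries[key] = s["path"]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"{path}: bad sample entry #{i}: {exc}") from exc
    return SampleManifest(
        entries, genotype=str(doc.get("genotype", "WT")), base_dir=path.parent
    )


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    doc = {
        "genotype": manifest.genotype,
        "samples": [
            {"cell_type": ct, "replicate": rep, "path": str(manifest.entries[(ct, rep)])}
            for ct, rep in sorted(manifest.entries)
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
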