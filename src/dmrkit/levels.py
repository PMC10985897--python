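"""Per-cytosine and bin-level methylation quantification.

The core statistic is the *bin methylation level*: the genome is tiled from
coordinate 0 into fixed-width non-overlapping windows (default 100 bp), and a
bin's level is the **unweighted mean of per-cytosine methylation fractions**
over the context cytosines in the bin — not the ratio of pooled read counts.
Averaging fractions first keeps a single deeply covered cytosine from
dominating the window.

A cytosine contributes only if its coverage reaches ``min_coverage`` (the
pipeline default is 5 reads). Bins with fewer than ``min_cytosines``
contributing cytosines are still emitted but flagged ineligible; bins with no
contributing cytosine carry an undefined (NaN) level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedValueError, ValidationError
from .io import CONTEXTS, FeatureAnnotation, MethylomeTrack

#: column schema of the bin-level table
BIN_COLUMNS = [
    "chrom", "start", "end", "context", "level",
    "n_cytosines", "n_meth_total", "n_unmeth_total", "eligible",
]


def cytosine_level(record) -> float:
    """Methylation fraction n_meth / (n_meth + n_unmeth) of one cytosine.

    Raises :class:`UndefinedValueError` at zero coverage: an unsequenced
    cytosine has no level and never contributes to a bin.
    """
    cov = record.n_meth + record.n_unmeth
    if cov == 0:
        raise UndefinedValueError("cytosine has zero coverage; level undefined")
    return record.n_meth / cov


def _segment_sequential_sums(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    # Strict left-to-right accumulation per segment: the bin level is defined
    # as the plain running mean a per-cytosine loop would produce, so vector
    # pairwise summation (numpy's default) is deliberately avoided.
    if len(values) == 0:
        return np.zeros(0)
    ends = np.append(starts[1:], len(values))
    out = np.empty(len(starts))
    vals = values.tolist()
    idx = 0
    for i, end in enumerate(ends):
        total = 0.0
        while idx < end:
            total += vals[idx]
            idx += 1
        out[i] = total
    return out


def bin_levels(
    track: MethylomeTrack,
    context: str,
    bin_width: int = 100,
    min_coverage: int = 5,
    min_cytosines: int = 5,
) -> pd.DataFrame:
    """Tile the genome into bins and compute per-bin methylation levels.

    Returns a DataFrame with :data:`BIN_COLUMNS`, one row per bin containing
    at least one record of ``context`` (any coverage). ``level`` is the mean
    of per-cytosine fractions over cytosines with coverage >= max(1,
    ``min_coverage``); ``n_meth_total``/``n_unmeth_total`` pool the read
    counts of those same cytosines (the integers later fed to Fisher's test).
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if min_coverage < 0 or min_cytosines < 0:
        raise ValidationError("min_coverage/min_cytosines must be >= 0")

    sub = track.data[track.data["context"] == context]
    if sub.empty:
        return pd.DataFrame(columns=BIN_COLUMNS)

    chrom = sub["chrom"].to_numpy()
    bins = (sub["pos"].to_numpy() - 1) // bin_width
    n_meth = sub["n_meth"].to_numpy(dtype=np.int64)
    n_unmeth = sub["n_unmeth"].to_numpy(dtype=np.int64)
    cov = n_meth + n_unmeth

    # all emitted bins: any record of the context (rows are pre-sorted)
    chrom_codes, chrom_uniques = pd.factorize(chrom, sort=False)
    key = chrom_codes.astype(np.int64) * (bins.max() + 1) + bins
    new_bin = np.ones(len(key), dtype=bool)
    new_bin[1:] = key[1:] != key[:-1]
    bin_idx = np.flatnonzero(new_bin)
    out_chrom = chrom[bin_idx]
    out_bin = bins[bin_idx]
    out_key = key[bin_idx]

    eff_min = max(min_coverage, 1)
    qmask = cov >= eff_min
    qkey = key[qmask]
    qlevels = n_meth[qmask] / cov[qmask]
    qstarts = np.flatnonzero(
        np.concatenate(([True], qkey[1:] != qkey[:-1])) if len(qkey) else np.zeros(0, bool)
    )
    if len(qkey):
        seg_key = qkey[qstarts]
        seg_n = np.diff(np.append(qstarts, len(qkey)))
        seg_level_sum = _segment_sequential_sums(qlevels, qstarts)
        seg_meth = np.add.reduceat(n_meth[qmask], qstarts)
        seg_unmeth = np.add.reduceat(n_unmeth[qmask], qstarts)
    else:
        seg_key = np.zeros(0, dtype=np.int64)
        seg_n = seg_level_sum = seg_meth = seg_unmeth = np.zeros(0)

    # map qualifying segments onto the emitted-bin rows
    pos_in_out = pd.Series(np.arange(len(out_key)), index=out_key)
    n_cyt = np.zeros(len(out_key), dtype=np.int64)
    meth_tot = np.zeros(len(out_key), dtype=np.int64)
    unmeth_tot = np.zeros(len(out_key), dtype=np.int64)
    level_sum = np.zeros(len(out_key))
    if len(seg_key):
        rows = pos_in_out.loc[seg_key].to_numpy()
        n_cyt[rows] = seg_n
        meth_tot[rows] = seg_meth
        unmeth_tot[rows] = seg_unmeth
        level_sum[rows] = seg_level_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(n_cyt > 0, level_sum / np.maximum(n_cyt, 1), np.nan)
    level[n_cyt == 0] = np.nan

    out = pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": out_bin * bin_width,
            "end": (out_bin + 1) * bin_width,
            "context": context,
            "level": level,
            "n_cytosines": n_cyt,
            "n_meth_total": meth_tot,
            "n_unmeth_total": unmeth_tot,
            "eligible": n_cyt >= min_cytosines,
        }
    )
    return out.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def all_context_bin_levels(
    track: MethylomeTrack,
    bin_width: int = 100,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Bin levels pooling all three contexts (used for 'total' methylation).

    Same mean-of-cytosine-fractions formula, but every covered cytosine in the
    bin contributes regardless of context. Emitted bins require at least one
    qualifying cytosine; no eligibility minimum is applied.
    """
    tmp = MethylomeTrack(
        track.data.assign(context="CHH"),  # collapse contexts for binning
        track.sample_id, track.cell_type, track.replicate,
    )
    out = bin_levels(tmp, "CHH", bin_width, min_coverage, min_cytosines=1)
    out = out[out["n_cytosines"] > 0].reset_index(drop=True)
    return out.drop(columns=["context"])


def global_level(
    track: MethylomeTrack,
    context: str,
    annotation: FeatureAnnotation | None = None,
    feature_class: str | None = None,
    bin_width: int = 100,
    min_coverage: int = 5,
    min_cytosines: int = 5,
) -> float:
    """Overall methylation: unweighted mean of eligible bin levels.

    With ``annotation``/``feature_class`` set, the mean is restricted to bins
    overlapping at least one feature of that class.
    """
    table = bin_levels(track, context, bin_width, min_coverage, min_cytosines)
    table = table[table["eligible"] & table["level"].notna()]
    if feature_class is not None:
        if annotation is None:
            raise ValidationError("feature_class requires an annotation")
        keep = [
            bool(annotation.tree(r.chrom).overlap(r.start, r.end)
                 and any(iv.data[0] == feature_class
                         for iv in annotation.tree(r.chrom).overlap(r.start, r.end)))
            for r in table.itertuples(index=False)
        ]
        table = table[np.asarray(keep, dtype=bool)] if len(table) else table
    if table.empty:
        raise UndefinedValueError("no eligible bins for global level")
    return float(table["level"].mean())


def write_bedgraph(bins: pd.DataFrame, path) -> None:
    """Export eligible bin levels as bedGraph (chrom, start, end, level)."""
    sub = bins[bins["eligible"] & bins["level"].notna()]
    sub[["chrom", "start", "end", "level"]].to_csv(
        path, sep="\t", header=False, index=False
    )
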