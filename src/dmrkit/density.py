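"""Frequency distribution of methylation differences in small windows.

For a pair of samples, the genome is tiled into 50-bp windows and the
fractional methylation difference (B - A) is collected for every window that
is informative in both samples and appreciably methylated in at least one:

* >= 20 informative sequenced cytosines of the context in each sample, where
  "informative" means covered by at least one read (the stricter 5x floor
  applies to bins and DMRs, not here);
* window level >= 0.7 (CG), 0.3 (CHG) or 0.1 (CHH) in either sample.

Window levels use the same mean-of-cytosine-fractions formula as 100-bp bins.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import MethylomeTrack
from .levels import bin_levels

DEFAULT_WINDOW = 50
DEFAULT_MIN_INFORMATIVE = 20
MIN_LEVELS = {"CG": 0.7, "CHG": 0.3, "CHH": 0.1}

WINDOW_COLUMNS = [
    "chrom", "start", "end", "context",
    "n_informative_a", "n_informative_b", "level_a", "level_b", "difference",
]


def density_differences(
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    context: str,
    window: int = DEFAULT_WINDOW,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    min_level: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Emit the per-window methylation differences passing the census filters."""
    levels_floor = dict(MIN_LEVELS)
    if min_level:
        levels_floor.update(min_level)
    if context not in levels_floor:
        raise ValidationError(f"unknown context {context!r}")
    wa = bin_levels(track_a, context, window, min_coverage=1, min_cytosines=min_informative)
    wb = bin_levels(track_b, context, window, min_coverage=1, min_cytosines=min_informative)
    merged = wa.merge(
        wb, on=["chrom", "start", "end", "context"], suffixes=("_a", "_b")
    )
    if merged.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    informative = (merged["n_cytosines_a"] >= min_informative) & (
        merged["n_cytosines_b"] >= min_informative
    )
    methylated = (
        np.fmax(merged["level_a"], merged["level_b"]) >= levels_floor[context]
    )
    keep = merged[informative & methylated]
    out = pd.DataFrame(
        {
            "chrom": keep["chrom"],
            "start": keep["start"],
            "end": keep["end"],
            "context": context,
            "n_informative_a": keep["n_cytosines_a"],
            "n_informative_b": keep["n_cytosines_b"],
            "level_a": keep["level_a"],
            "level_b": keep["level_b"],
            "difference": keep["level_b"] - keep["level_a"],
        }
    )
    return out.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def difference_histogram(
    differences: Sequence[float] | pd.Series,
    bin_edges: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Frequency table of fractional differences over strictly increasing
    edges covering [-1, 1]; counts sum to the number of emitted windows."""
    edges = np.asarray(
        bin_edges if bin_edges is not None else np.linspace(-1.0, 1.0, 41),
        dtype=float,
    )
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValidationError("bin_edges must be strictly increasing")
    if edges[0] > -1.0 or edges[-1] < 1.0:
        raise ValidationError("bin_edges must cover [-1, 1]")
    values = np.asarray(differences, dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
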