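"""Differential methylation region (DMR) calling between two methylomes.

A DMR is a 100-bp bin whose methylation level differs between two pooled
samples by a context-specific margin (0.5 for CG, 0.3 for CHG, 0.1 for CHH)
with Fisher's exact test p < 0.01 on the pooled read counts of the bin;
neighbouring same-direction calls within 200 bp are merged. The effect-size
criterion uses the mean-of-cytosine-fractions bin level, while the test uses
the pooled integer counts — the test needs counts, the level formula does not
provide them.

Feature classification follows an exclusive priority: a DMR overlapping a
transposable element longer than 500 bp is "TE"; otherwise a TE-related gene
makes it "TEG"; otherwise a gene makes it "gene"; otherwise "intergenic".
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CONTEXTS, FeatureAnnotation, MethylomeTrack
from .levels import bin_levels

#: the context-specific absolute methylation-difference thresholds
DELTA_THRESHOLDS = {"CG": 0.5, "CHG": 0.3, "CHH": 0.1}
DEFAULT_ALPHA = 0.01
DEFAULT_MERGE_GAP = 200
DEFAULT_MIN_TE_LENGTH = 500
DEFAULT_DMG_MIN_FRACTION = 0.8

COMPARISON_COLUMNS = [
    "chrom", "start", "end", "context", "level_a", "level_b", "delta",
    "n_meth_a", "n_unmeth_a", "n_meth_b", "n_unmeth_b", "p_value",
]
DMR_COLUMNS = [
    "chrom", "start", "end", "context", "direction",
    "min_p", "mean_delta", "n_bins",
]

_REL_TOL = 1e-7  # relative slack on the "<= observed pmf" tie comparison

_logfact_cache = np.zeros(2)


def _logfact(n: int) -> np.ndarray:
    """log(k!) for k = 0..n, cached and grown on demand."""
    global _logfact_cache
    if n >= len(_logfact_cache):
        m = max(n + 1, 2 * len(_logfact_cache))
        ext = np.empty(m)
        ext[: len(_logfact_cache)] = _logfact_cache
        k = np.arange(len(_logfact_cache), m, dtype=np.float64)
        ext[len(_logfact_cache):] = np.cumsum(np.log(k)) + _logfact_cache[-1]
        _logfact_cache = ext
    return _logfact_cache


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact probability of a 2x2 count table.

    The p-value sums the hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed the observed table's
    (ties judged with 1e-7 relative slack). A table with a zero margin carries
    no information and returns 1.0.
    """
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    if min(a, b, c, d) < 0:
        raise ValidationError("negative counts in Fisher table")
    n1, n2, k_obs = a + b, c + d, a + c
    n = n1 + n2
    if n1 == 0 or n2 == 0 or k_obs == 0 or k_obs == n:
        return 1.0
    kmin = max(0, k_obs - n2)
    kmax = min(k_obs, n1)
    k = np.arange(kmin, kmax + 1)
    lf = _logfact(int(n))
    log_pmf = (
        lf[n1] - lf[k] - lf[n1 - k]
        + lf[n2] - lf[k_obs - k] - lf[n2 - k_obs + k]
        + lf[k_obs] + lf[n - k_obs] - lf[n]
    )
    log_pmf -= log_pmf.max()  # guards exp underflow; cancels in the comparison
    pmf = np.exp(log_pmf)
    p = float(pmf[pmf <= pmf[a - kmin] * (1.0 + _REL_TOL)].sum() / pmf.sum())
    return min(p, 1.0)


def compare_bins(
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    context: str,
    bin_width: int = 100,
    min_coverage: int = 5,
    min_cytosines: int = 5,
) -> pd.DataFrame:
    """Per-bin comparison of two (replicate-pooled) methylomes.

    Only bins eligible in *both* samples are compared (no imputation).
    ``delta`` is level_b - level_a; ``p_value`` is Fisher's exact test on the
    2x2 table of pooled bin read counts [[meth_a, unmeth_a], [meth_b,
    unmeth_b]].
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    ba = bin_levels(track_a, context, bin_width, min_coverage, min_cytosines)
    bb = bin_levels(track_b, context, bin_width, min_coverage, min_cytosines)
    ba = ba[ba["eligible"]]
    bb = bb[bb["eligible"]]
    merged = ba.merge(
        bb, on=["chrom", "start", "end", "context"], suffixes=("_a", "_b")
    )
    if merged.empty:
        return pd.DataFrame(columns=COMPARISON_COLUMNS)
    p = [
        fisher_exact([[ma, ua], [mb, ub]])
        for ma, ua, mb, ub in zip(
            merged["n_meth_total_a"], merged["n_unmeth_total_a"],
            merged["n_meth_total_b"], merged["n_unmeth_total_b"],
        )
    ]
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "start": merged["start"],
            "end": merged["end"],
            "context": context,
            "level_a": merged["level_a"],
            "level_b": merged["level_b"],
            "delta": merged["level_b"] - merged["level_a"],
            "n_meth_a": merged["n_meth_total_a"],
            "n_unmeth_a": merged["n_unmeth_total_a"],
            "n_meth_b": merged["n_meth_total_b"],
            "n_unmeth_b": merged["n_unmeth_total_b"],
            "p_value": p,
        }
    )
    return out.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def call_dmr_bins(
    comparisons: pd.DataFrame,
    delta_thresholds: Mapping[str, float] | None = None,
    alpha: float = DEFAULT_ALPHA,
    correction: str | None = None,
) -> pd.DataFrame:
    """Single-bin DMR calls: |delta| >= context threshold and p < alpha.

    ``direction`` is "hyper" when sample B exceeds sample A. ``correction``
    may be "bh" to apply Benjamini-Hochberg before the alpha cut (off by
    default; the standard rule uses raw p-values).
    """
    thresholds = dict(DELTA_THRESHOLDS)
    if delta_thresholds:
        thresholds.update(delta_thresholds)
    if comparisons.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    df = comparisons.copy()
    p = df["p_value"].to_numpy(dtype=float)
    if correction == "bh":
        from scipy.stats import false_discovery_control

        p = false_discovery_control(p, method="bh")
    elif correction is not None:
        raise ValidationError(f"unknown correction {correction!r}")
    thr = df["context"].map(thresholds).to_numpy(dtype=float)
    keep = (df["delta"].abs().to_numpy() >= thr) & (p < alpha)
    df = df[keep]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "context": df["context"],
            "direction": np.where(df["delta"] > 0, "hyper", "hypo"),
            "min_p": df["p_value"],
            "mean_delta": df["delta"],
            "n_bins": 1,
        }
    )
    return out.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def merge_dmrs(dmrs: pd.DataFrame, max_gap: int = DEFAULT_MERGE_GAP) -> pd.DataFrame:
    """Merge neighbouring same-context, same-direction DMRs within ``max_gap``.

    The gap is measured end-to-start on half-open intervals and a gap of
    exactly ``max_gap`` still merges. Merging is transitive; ``min_p`` is the
    smallest constituent p, ``mean_delta`` the bin-count-weighted mean (so
    re-merging is idempotent), ``n_bins`` the constituent total.
    """
    if dmrs.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    pieces = []
    for (chrom, context, direction), grp in dmrs.groupby(
        ["chrom", "context", "direction"], sort=True
    ):
        grp = grp.sort_values("start", kind="stable")
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        new_cluster = np.ones(len(grp), dtype=bool)
        new_cluster[1:] = start[1:] - np.maximum.accumulate(end)[:-1] > max_gap
        cluster = np.cumsum(new_cluster)
        g = grp.assign(_cluster=cluster).groupby("_cluster")
        w = g.apply(
            lambda x: np.average(x["mean_delta"], weights=x["n_bins"]),
            include_groups=False,
        )
        merged = pd.DataFrame(
            {
                "chrom": chrom,
                "start": g["start"].min(),
                "end": g["end"].max(),
                "context": context,
                "direction": direction,
                "min_p": g["min_p"].min(),
                "mean_delta": w,
                "n_bins": g["n_bins"].sum(),
            }
        )
        pieces.append(merged)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(
        ["chrom", "start", "context", "direction"], kind="stable", ignore_index=True
    )


def annotate_dmrs(
    dmrs: pd.DataFrame,
    annotation: FeatureAnnotation,
    min_te_length: int = DEFAULT_MIN_TE_LENGTH,
) -> pd.DataFrame:
    """Assign each DMR one feature class: TE (> ``min_te_length`` bp) > TEG >
    gene > intergenic.

    Within the winning class the feature with the largest overlap (leftmost on
    ties) supplies ``feature_id``.
    """
    df = dmrs.copy()
    classes = []
    ids = []
    for r in df.itertuples(index=False):
        hits = annotation.overlapping(r.chrom, int(r.start), int(r.end))
        best_class, best_id = "intergenic", "."
        for want in ("TE", "TEG", "gene"):
            cands = [
                h for h in hits
                if h[2] == want and (want != "TE" or h[1] - h[0] > min_te_length)
            ]
            if cands:
                overlaps = [
                    (min(h[1], r.end) - max(h[0], r.start), -h[0], h[3]) for h in cands
                ]
                best_id = max(overlaps)[2]
                best_class = want
                break
        classes.append(best_class)
        ids.append(best_id)
    df["feature_class"] = classes
    df["feature_id"] = ids
    return df


def identify_dmgs(
    dmrs: pd.DataFrame,
    annotation: FeatureAnnotation,
    min_fraction: float = DEFAULT_DMG_MIN_FRACTION,
) -> pd.DataFrame:
    """Differentially methylated genes: genes covering > ``min_fraction`` of a
    DMR's length.

    Each DMR nominates at most one gene — the one with the greatest overlap —
    and only when overlap / DMR length strictly exceeds the threshold.
    Returns one row per (DMR, gene) nomination.
    """
    rows = []
    for r in dmrs.itertuples(index=False):
        length = int(r.end) - int(r.start)
        genes = [
            h for h in annotation.overlapping(r.chrom, int(r.start), int(r.end))
            if h[2] == "gene"
        ]
        if not genes:
            continue
        overlaps = [
            (min(h[1], r.end) - max(h[0], r.start), -h[0], h[3]) for h in genes
        ]
        best = max(overlaps)
        frac = best[0] / length
        if frac > min_fraction:
            rows.append(
                (best[2], r.chrom, int(r.start), int(r.end),
                 getattr(r, "context", "."), getattr(r, "direction", "."),
                 int(best[0]), frac)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "context", "direction",
            "overlap_bp", "overlap_fraction",
        ],
    )


def dmg_gene_map(dmgs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mapping gene_id -> DMR rows nominating it."""
    return {gid: grp.reset_index(drop=True) for gid, grp in dmgs.groupby("gene_id")}


def intersect_gene_sets(set_a: Iterable[str], set_b: Iterable[str]) -> dict:
    """Overlap summary of two gene-id collections (e.g. DMGs vs DE genes)."""
    a, b = set(set_a), set(set_b)
    shared = sorted(a & b)
    return {"n_a": len(a), "n_b": len(b), "n_shared": len(shared), "shared": shared}
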