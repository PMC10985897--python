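"""Sexual-lineage hypermethylation (SLH) and sexual-lineage-specific
methylation (SLM) classification.

Male sex-cell methylomes (meiocyte, microspore, sperm) are compared against a
somatic reference (seedling) in 100-bp bins. The sex-cell average (SexAV) is
the unweighted mean of cell-type bin levels — over all three cell types for
mCG and mCHH, but over meiocyte and microspore only for mCHG, because sperm
loses CHG methylation and would dilute the signal. With
Diff = SexAV - Seedling per context, a bin is an SLH locus when

* Fisher's exact test on total (all-context pooled) methylated/unmethylated
  counts, sex average vs somatic, gives p < 0.01;
* every sex-cell replicate's total methylation level exceeds every somatic
  replicate's; and
* Diff_CG > 0, Diff_CHG > 0.05, Diff_CHH > 0.1 and their sum > 0.4.

SLH loci split into SLM (somatic mCHH < 0.05 AND mCHG < 0.1 — methylation
arising de novo in the sexual lineage) versus canonical SLH (already carrying
non-CG methylation in soma). Boundary values go to canonical SLH because the
SLM definition is strict.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmr import annotate_dmrs, fisher_exact
from .errors import ConfigurationError
from .io import CONTEXTS, FeatureAnnotation, MethylomeTrack, pool_replicates
from .levels import all_context_bin_levels, bin_levels

#: cell types contributing to the sex average, per context
SEX_CELLS = {
    "CG": ("meiocyte", "microspore", "sperm"),
    "CHG": ("meiocyte", "microspore"),
    "CHH": ("meiocyte", "microspore", "sperm"),
}
REQUIRED_SEX_CELLS = ("meiocyte", "microspore", "sperm")

SLH_COLUMNS = [
    "chrom", "start", "end",
    "sexav_cg", "sexav_chg", "sexav_chh",
    "somatic_cg", "somatic_chg", "somatic_chh",
    "diff_cg", "diff_chg", "diff_chh", "diff_sum", "p_value",
]


@dataclass
class SlhParams:
    """Thresholds of the SLH/SLM criteria (defaults as published)."""

    min_diff_cg: float = 0.0
    min_diff_chg: float = 0.05
    min_diff_chh: float = 0.1
    min_diff_sum: float = 0.4
    alpha: float = 0.01
    slm_max_somatic_chh: float = 0.05
    slm_max_somatic_chg: float = 0.1
    bin_width: int = 100
    min_coverage: int = 5
    min_cytosines: int = 1
    sex_cells: Mapping[str, tuple] = field(default_factory=lambda: dict(SEX_CELLS))


def _celltype_bin_tables(
    pooled: Mapping[str, MethylomeTrack], context: str, params: SlhParams
) -> dict[str, pd.DataFrame]:
    out = {}
    for ct, track in pooled.items():
        tbl = bin_levels(
            track, context, params.bin_width, params.min_coverage, params.min_cytosines
        )
        out[ct] = tbl[tbl["eligible"] & tbl["level"].notna()]
    return out


def sex_average(
    tracks_by_celltype: Mapping[str, MethylomeTrack],
    context: str,
    params: SlhParams | None = None,
) -> pd.DataFrame:
    """Per-bin sex-cell average level (SexAV) for one context.

    Bins missing in any contributing cell type are skipped. Returns columns
    chrom/start/end/level plus the per-cell-type bin counts used by the
    total-count Fisher test.
    """
    params = params or SlhParams()
    cells = params.sex_cells.get(context, SEX_CELLS[context])
    missing = [ct for ct in cells if ct not in tracks_by_celltype]
    if missing:
        raise ConfigurationError(f"missing sex cell type(s) {missing} for {context}")
    tables = _celltype_bin_tables(
        {ct: tracks_by_celltype[ct] for ct in cells}, context, params
    )
    merged = None
    for ct in cells:
        t = tables[ct][["chrom", "start", "end", "level", "n_meth_total", "n_unmeth_total"]]
        t = t.rename(
            columns={
                "level": f"level_{ct}",
                "n_meth_total": f"n_meth_{ct}",
                "n_unmeth_total": f"n_unmeth_{ct}",
            }
        )
        merged = t if merged is None else merged.merge(t, on=["chrom", "start", "end"])
    level_cols = [f"level_{ct}" for ct in cells]
    merged["level"] = merged[level_cols].mean(axis=1)
    merged["n_meth_sex"] = merged[[f"n_meth_{ct}" for ct in cells]].sum(axis=1)
    merged["n_unmeth_sex"] = merged[[f"n_unmeth_{ct}" for ct in cells]].sum(axis=1)
    return merged.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def _replicate_ordering_mask(
    bins: pd.DataFrame,
    sex_tracks: Mapping[str, Sequence[MethylomeTrack]],
    somatic_tracks: Sequence[MethylomeTrack],
    params: SlhParams,
) -> np.ndarray:
    """True where min over sex-replicate total levels > max over somatic ones.

    Levels are all-context bin levels per replicate; a bin where any replicate
    lacks a defined level fails the condition (no evidence, no call).
    """
    key = bins[["chrom", "start", "end"]]

    def rep_levels(track: MethylomeTrack) -> pd.Series:
        tbl = all_context_bin_levels(track, params.bin_width, params.min_coverage)
        m = key.merge(tbl, on=["chrom", "start", "end"], how="left")
        return m["level"]

    sex_levels = [
        rep_levels(t) for ct in sorted(sex_tracks) for t in sex_tracks[ct]
    ]
    som_levels = [rep_levels(t) for t in somatic_tracks]
    sex_min = pd.concat(sex_levels, axis=1).min(axis=1, skipna=False)
    som_max = pd.concat(som_levels, axis=1).max(axis=1, skipna=False)
    return (sex_min > som_max).fillna(False).to_numpy()


def identify_slh(
    sex_tracks: Mapping[str, Sequence[MethylomeTrack]],
    somatic_tracks: Sequence[MethylomeTrack],
    params: SlhParams | None = None,
) -> pd.DataFrame:
    """Identify 100-bp SLH loci from replicate-resolved tracks.

    ``sex_tracks`` maps cell type (meiocyte, microspore, sperm) to its
    replicate tracks; ``somatic_tracks`` is the somatic (seedling) replicate
    list. Returns an :data:`SLH_COLUMNS` table of loci passing all criteria
    (not yet classified; see :func:`split_slh`).
    """
    params = params or SlhParams()
    missing = [ct for ct in REQUIRED_SEX_CELLS if not sex_tracks.get(ct)]
    if missing:
        raise ConfigurationError(f"missing required sex cell type(s): {missing}")
    if not somatic_tracks:
        raise ConfigurationError("at least one somatic track is required")

    pooled_sex = {ct: pool_replicates(list(ts)) for ct, ts in sex_tracks.items()}
    pooled_som = pool_replicates(list(somatic_tracks))

    per_context = {}
    for context in CONTEXTS:
        sav = sex_average(pooled_sex, context, params)
        som = bin_levels(
            pooled_som, context, params.bin_width, params.min_coverage,
            params.min_cytosines,
        )
        som = som[som["eligible"] & som["level"].notna()]
        lc = context.lower()
        som = som[["chrom", "start", "end", "level", "n_meth_total", "n_unmeth_total"]]
        som = som.rename(
            columns={
                "level": "level_som",
                "n_meth_total": "n_meth_total_som",
                "n_unmeth_total": "n_unmeth_total_som",
            }
        )
        m = sav.merge(som, on=["chrom", "start", "end"])
        per_context[context] = pd.DataFrame(
            {
                "chrom": m["chrom"],
                "start": m["start"],
                "end": m["end"],
                f"sexav_{lc}": m["level"],
                f"somatic_{lc}": m["level_som"],
                f"n_meth_sex_{lc}": m["n_meth_sex"],
                f"n_unmeth_sex_{lc}": m["n_unmeth_sex"],
                f"n_meth_som_{lc}": m["n_meth_total_som"],
                f"n_unmeth_som_{lc}": m["n_unmeth_total_som"],
            }
        )
    bins = per_context["CG"]
    for context in ("CHG", "CHH"):
        bins = bins.merge(per_context[context], on=["chrom", "start", "end"])
    if bins.empty:
        return pd.DataFrame(columns=SLH_COLUMNS)

    for lc in ("cg", "chg", "chh"):
        bins[f"diff_{lc}"] = bins[f"sexav_{lc}"] - bins[f"somatic_{lc}"]
    bins["diff_sum"] = bins["diff_cg"] + bins["diff_chg"] + bins["diff_chh"]

    diff_ok = (
        (bins["diff_cg"] > params.min_diff_cg)
        & (bins["diff_chg"] > params.min_diff_chg)
        & (bins["diff_chh"] > params.min_diff_chh)
        & (bins["diff_sum"] > params.min_diff_sum)
    )
    bins = bins[diff_ok].reset_index(drop=True)
    if bins.empty:
        return pd.DataFrame(columns=SLH_COLUMNS)

    # total (all-context) count Fisher test, sex pooled per-context cell sets
    m_sex = sum(bins[f"n_meth_sex_{lc}"] for lc in ("cg", "chg", "chh"))
    u_sex = sum(bins[f"n_unmeth_sex_{lc}"] for lc in ("cg", "chg", "chh"))
    m_som = sum(bins[f"n_meth_som_{lc}"] for lc in ("cg", "chg", "chh"))
    u_som = sum(bins[f"n_unmeth_som_{lc}"] for lc in ("cg", "chg", "chh"))
    bins["p_value"] = [
        fisher_exact([[a, b], [c, d]]) for a, b, c, d in zip(m_sex, u_sex, m_som, u_som)
    ]
    bins = bins[bins["p_value"] < params.alpha].reset_index(drop=True)
    if bins.empty:
        return pd.DataFrame(columns=SLH_COLUMNS)

    order_ok = _replicate_ordering_mask(bins, sex_tracks, somatic_tracks, params)
    bins = bins[order_ok].reset_index(drop=True)
    return bins[SLH_COLUMNS]


def split_slh(loci: pd.DataFrame, params: SlhParams | None = None) -> pd.DataFrame:
    """Classify SLH loci as SLM vs canonical SLH from somatic non-CG levels.

    SLM requires somatic mCHH strictly below 0.05 AND somatic mCHG strictly
    below 0.1; everything else is canonical SLH. Loci with an undefined
    somatic level are unclassifiable and are dropped with a warning.
    """
    params = params or SlhParams()
    if loci.empty:
        out = loci.copy()
        out["classification"] = pd.Series(dtype=str)
        return out
    df = loci.copy()
    undefined = df["somatic_chh"].isna() | df["somatic_chg"].isna()
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} SLH locus/loci lack a somatic non-CG level "
            "and were excluded from classification",
            stacklevel=2,
        )
        df = df[~undefined]
    is_slm = (df["somatic_chh"] < params.slm_max_somatic_chh) & (
        df["somatic_chg"] < params.slm_max_somatic_chg
    )
    df = df.assign(classification=np.where(is_slm, "SLM", "canonical_SLH"))
    return df.reset_index(drop=True)


def slh_feature_summary(
    loci: pd.DataFrame,
    annotation: FeatureAnnotation,
    min_te_length: int = 500,
) -> pd.DataFrame:
    """Counts of classified loci per (classification x feature class)."""
    classes = ["TE", "TEG", "gene", "intergenic"]
    labels = ["canonical_SLH", "SLM"]
    if loci.empty:
        return pd.DataFrame(0, index=labels, columns=classes)
    annotated = annotate_dmrs(loci, annotation, min_te_length)
    table = (
        annotated.groupby(["classification", "feature_class"])
        .size()
        .unstack(fill_value=0)
    )
    return table.reindex(index=labels, columns=classes, fill_value=0)
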