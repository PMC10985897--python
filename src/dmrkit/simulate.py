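"""Synthetic multi-cell-type methylome generator with known ground truth.

The generator builds a random nucleotide genome, derives cytosine positions
and CG/CHG/CHH contexts from the actual trinucleotides on both strands, lays
down a gene/TEG/TE annotation, and simulates per-cytosine read counts:
coverage is Poisson with a chosen mean and the methylated count is binomial
around a truth methylation level. A symmetric error rate folds bisulfite
non-conversion and sequencing error into one parameter, since the downstream
analysis never separates them.

Ground truth is carried by a :class:`TruthProfile`: per-cell-type baseline
levels per context, planted differential regions (one cell type's level
shifted by a chosen delta), and planted sexual-lineage loci with designed
sex/somatic target levels and an intended SLM / canonical-SLH label.

Planted DMRs are aligned to the 100-bp analysis grid and only placed where
every spanned bin holds at least five cytosines of the target context: a
differential region without measurable context sites is not a meaningful
truth label. Planted SLH loci likewise require a minimum number of sites of
every context in their bin.

Everything is deterministic given a seed; replicate tracks differ only by
sampling noise.
"""

from __future__ import annotations

import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .io import (
    ANNOTATION_COLUMNS,
    TRACK_COLUMNS,
    FeatureAnnotation,
    MethylomeTrack,
    SampleManifest,
    write_annotation_bed,
    write_cytosine_report,
    write_manifest,
)

SEX_CELL_TYPES = ("meiocyte", "microspore", "sperm")
SOMATIC_CELL_TYPES = ("seedling",)

#: genome-wide baseline methylation per context (plant-typical magnitudes)
DEFAULT_BASELINES = {"CG": 0.5, "CHG": 0.25, "CHH": 0.05}

_BASES = np.array(list("ACGT"))
_A, _C, _G, _T = 0, 1, 2, 3


@dataclass
class AnnotationParams:
    """Controls the simulated gene/TEG/TE annotation.

    ``density`` scales the number of features (0 disables annotation).
    TE lengths deliberately straddle the 500-bp feature-class boundary.
    """

    density: float = 1.0
    mean_gap: int = 600
    class_weights: Mapping[str, float] = field(
        default_factory=lambda: {"gene": 0.45, "TEG": 0.15, "TE": 0.40}
    )
    length_ranges: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "gene": (1000, 3000),
            "TEG": (800, 2000),
            "TE": (150, 1500),
        }
    )


@dataclass
class SyntheticGenome:
    chrom_sizes: dict
    sequences: dict  # chrom -> int8 array, ACGT = 0..3
    cytosines: dict  # chrom -> DataFrame(pos 1-based, strand, context)
    annotation: FeatureAnnotation

    def sequence_string(self, chrom: str) -> str:
        return "".join(_BASES[self.sequences[chrom]])


@dataclass
class PlantedRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    context: str
    cell_type: str
    delta: float


@dataclass
class PlantedSlhLocus:
    chrom: str
    start: int
    end: int
    sex_levels: dict  # context -> level in all sex cell types
    somatic_levels: dict  # context -> level in somatic cell types
    intended: str  # "SLM" or "canonical_SLH"


@dataclass
class TruthProfile:
    """Ground-truth methylation levels for a set of cell types."""

    baselines: dict  # cell_type -> {context: level}
    planted_regions: list = field(default_factory=list)
    planted_slh: list = field(default_factory=list)
    sex_cell_types: tuple = SEX_CELL_TYPES
    somatic_cell_types: tuple = SOMATIC_CELL_TYPES

    @classmethod
    def uniform(
        cls,
        cell_types: Sequence[str],
        baselines: Mapping[str, float] | None = None,
        **kwargs,
    ) -> "TruthProfile":
        base = dict(DEFAULT_BASELINES)
        if baselines:
            base.update(baselines)
        return cls({ct: dict(base) for ct in cell_types}, **kwargs)

    def levels_for(self, genome: SyntheticGenome, cell_type: str, chrom: str) -> np.ndarray:
        """Truth level per cytosine of ``chrom`` for one cell type."""
        cyt = genome.cytosines[chrom]
        base = self.baselines[cell_type]
        levels = cyt["context"].map(base).to_numpy(dtype=float)
        pos0 = cyt["pos"].to_numpy() - 1
        for reg in self.planted_regions:
            if reg.chrom != chrom or reg.cell_type != cell_type:
                continue
            mask = (
                (pos0 >= reg.start)
                & (pos0 < reg.end)
                & (cyt["context"].to_numpy() == reg.context)
            )
            levels[mask] = np.clip(levels[mask] + reg.delta, 0.0, 1.0)
        if cell_type in self.sex_cell_types or cell_type in self.somatic_cell_types:
            which = "sex_levels" if cell_type in self.sex_cell_types else "somatic_levels"
            for locus in self.planted_slh:
                if locus.chrom != chrom:
                    continue
                targets = getattr(locus, which)
                span = (pos0 >= locus.start) & (pos0 < locus.end)
                for context, level in targets.items():
                    mask = span & (cyt["context"].to_numpy() == context)
                    levels[mask] = level
        return levels


def _rng(seed: int, *labels) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, str):
            entropy.append(zlib.crc32(lab.encode()))
        else:
            entropy.append(int(lab) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _contexts_from_sequence(seq: np.ndarray) -> pd.DataFrame:
    """Cytosine positions/strands/contexts by the trinucleotide rule.

    Plus-strand: C followed by G -> CG; C,H,G -> CHG; C,H,H -> CHH.
    Minus-strand cytosines appear as G in the reference, read right-to-left
    with complemented neighbours. Cytosines too close to a chromosome end to
    have a full trinucleotide are skipped.
    """
    n = len(seq)
    rows = []
    plus = np.flatnonzero(seq[: n - 2] == _C)
    if len(plus):
        n1, n2 = seq[plus + 1], seq[plus + 2]
        ctx = np.where(n1 == _G, "CG", np.where(n2 == _G, "CHG", "CHH"))
        rows.append(pd.DataFrame({"pos": plus + 1, "strand": "+", "context": ctx}))
    minus = np.flatnonzero(seq == _G)
    minus = minus[minus >= 2]
    if len(minus):
        n1, n2 = seq[minus - 1], seq[minus - 2]
        ctx = np.where(n1 == _C, "CG", np.where(n2 == _C, "CHG", "CHH"))
        rows.append(pd.DataFrame({"pos": minus + 1, "strand": "-", "context": ctx}))
    if not rows:
        return pd.DataFrame({"pos": [], "strand": [], "context": []})
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable", ignore_index=True)


def _simulate_annotation(
    rng: np.random.Generator, chrom: str, size: int, params: AnnotationParams
) -> list[tuple]:
    if params.density <= 0:
        return []
    classes = sorted(params.class_weights)
    weights = np.array([params.class_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()
    mean_gap = max(params.mean_gap / params.density, 1.0)
    rows = []
    pos = int(rng.exponential(mean_gap))
    i = 0
    while pos < size:
        cls = classes[rng.choice(len(classes), p=weights)]
        lo, hi = params.length_ranges[cls]
        length = int(rng.integers(lo, hi + 1))
        end = min(pos + length, size)
        if end - pos >= 50:
            i += 1
            rows.append((chrom, pos, end, cls, f"{cls}_{chrom}_{i:05d}"))
        pos = end + int(rng.exponential(mean_gap)) + 1
    return rows


def build_genome(
    seed: int,
    chrom_sizes: Mapping[str, int] | None = None,
    gc_content: float = 0.44,
    annotation_params: AnnotationParams | None = None,
) -> SyntheticGenome:
    """Simulate a genome: sequence, cytosine layout, and feature annotation."""
    chrom_sizes = dict(chrom_sizes or {"chr1": 1_000_000})
    if any(s <= 0 for s in chrom_sizes.values()):
        raise ValidationError("chromosome sizes must be positive")
    if not 0.0 < gc_content < 1.0:
        raise ValidationError("gc_content must be in (0, 1)")
    params = annotation_params or AnnotationParams()
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    sequences, cytosines, ann_rows = {}, {}, []
    for chrom in sorted(chrom_sizes):
        rng = _rng(seed, "genome", chrom)
        seq = rng.choice(4, size=chrom_sizes[chrom], p=p).astype(np.int8)
        sequences[chrom] = seq
        cytosines[chrom] = _contexts_from_sequence(seq)
        ann_rows.extend(_simulate_annotation(rng, chrom, chrom_sizes[chrom], params))
    annotation = (
        FeatureAnnotation(pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS))
        if ann_rows
        else FeatureAnnotation.empty()
    )
    return SyntheticGenome(chrom_sizes, sequences, cytosines, annotation)


def simulate_track(
    genome: SyntheticGenome,
    truth: TruthProfile,
    cell_type: str,
    replicate: int,
    coverage_mean: float = 30.0,
    error_rate: float = 0.005,
    seed: int = 0,
) -> MethylomeTrack:
    """Simulate one replicate's cytosine report for one cell type.

    Coverage ~ Poisson(``coverage_mean``); methylated reads ~ Binomial with
    success probability level*(1-e) + (1-level)*e, folding non-conversion and
    sequencing error into the symmetric rate ``e``. Deterministic per
    (seed, cell_type, replicate).
    """
    if coverage_mean <= 0:
        raise ValidationError("coverage_mean must be positive")
    if not 0.0 <= error_rate <= 0.05:
        raise ValidationError("error_rate must be in [0, 0.05]")
    if cell_type not in truth.baselines:
        raise ValidationError(f"no truth baselines for cell type {cell_type!r}")
    frames = []
    for chrom in sorted(genome.chrom_sizes):
        cyt = genome.cytosines[chrom]
        if cyt.empty:
            continue
        rng = _rng(seed, "track", cell_type, replicate, chrom)
        levels = truth.levels_for(genome, cell_type, chrom)
        p_eff = levels * (1 - error_rate) + (1 - levels) * error_rate
        coverage = rng.poisson(coverage_mean, size=len(cyt))
        n_meth = rng.binomial(coverage, p_eff)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": cyt["pos"].to_numpy(),
                    "strand": cyt["strand"].to_numpy(),
                    "context": cyt["context"].to_numpy(),
                    "n_meth": n_meth,
                    "n_unmeth": coverage - n_meth,
                }
            )
        )
    data = (
        pd.concat(frames, ignore_index=True)[TRACK_COLUMNS]
        if frames
        else pd.DataFrame(columns=TRACK_COLUMNS)
    )
    return MethylomeTrack(
        data, sample_id=f"{cell_type}_r{replicate}", cell_type=cell_type,
        replicate=replicate,
    )


def _candidate_bins(
    genome: SyntheticGenome, chrom: str, context: str, bin_width: int, min_sites: int
) -> np.ndarray:
    cyt = genome.cytosines[chrom]
    sub = cyt[cyt["context"] == context]
    n_bins = -(-genome.chrom_sizes[chrom] // bin_width)
    counts = np.bincount((sub["pos"].to_numpy() - 1) // bin_width, minlength=n_bins)
    return counts >= min_sites


def plant_dmrs(
    genome: SyntheticGenome,
    truth: TruthProfile,
    n_regions: int,
    context: str,
    delta: float,
    cell_type: str,
    seed: int = 0,
    lengths: Sequence[int] = (100, 200, 300, 400),
    bin_width: int = 100,
    min_sites_per_bin: int = 5,
) -> TruthProfile:
    """Plant non-overlapping differential regions into one cell type's truth.

    Regions are grid-aligned runs of 1-4 bins whose every bin carries at
    least ``min_sites_per_bin`` cytosines of the target context, separated by
    at least one guard bin. Raises :class:`GenerationError` when the genome
    cannot host the request.
    """
    base = truth.baselines[cell_type][context]
    if not 0.0 <= base + delta <= 1.0:
        raise ValidationError(f"baseline {base} + delta {delta} leaves [0, 1]")
    if any(length % bin_width != 0 or length <= 0 for length in lengths):
        raise ValidationError("planted lengths must be positive bin multiples")
    if n_regions == 0:
        return truth
    rng = _rng(seed, "plant_dmrs", context, cell_type)
    placements = []
    free = {
        chrom: _candidate_bins(genome, chrom, context, bin_width, min_sites_per_bin)
        for chrom in sorted(genome.chrom_sizes)
    }
    chroms = sorted(genome.chrom_sizes)
    order = [
        (chrom, b) for chrom in chroms for b in np.flatnonzero(free[chrom])
    ]
    rng.shuffle(order)
    length_choices = rng.choice(list(lengths), size=n_regions)
    placed = 0
    for chrom, b in order:
        if placed >= n_regions:
            break
        n_bins = int(length_choices[placed]) // bin_width
        window = free[chrom][b: b + n_bins]
        if len(window) < n_bins or not window.all():
            continue
        placements.append(
            PlantedRegion(
                chrom, int(b * bin_width), int((b + n_bins) * bin_width),
                context, cell_type, float(delta),
            )
        )
        lo = max(0, b - 1)  # guard bin on each side
        free[chrom][lo: b + n_bins + 1] = False
        placed += 1
    if placed < n_regions:
        raise GenerationError(
            f"could only place {placed}/{n_regions} regions; genome too small "
            "or context sites too sparse"
        )
    out = TruthProfile(
        {ct: dict(levels) for ct, levels in truth.baselines.items()},
        planted_regions=list(truth.planted_regions) + placements,
        planted_slh=list(truth.planted_slh),
        sex_cell_types=truth.sex_cell_types,
        somatic_cell_types=truth.somatic_cell_types,
    )
    return out


#: designed SLH truth levels: somatic profiles sit clearly on either side of
#: the SLM boundary (mCHH 0.05 / mCHG 0.1); sex levels satisfy every Diff
#: threshold with >= 0.1 margin.
SLM_SOMATIC_LEVELS = {"CG": 0.2, "CHG": 0.02, "CHH": 0.01}
CANONICAL_SOMATIC_LEVELS = {"CG": 0.2, "CHG": 0.3, "CHH": 0.15}
SLM_SEX_LEVELS = {"CG": 0.45, "CHG": 0.35, "CHH": 0.3}
CANONICAL_SEX_LEVELS = {"CG": 0.45, "CHG": 0.6, "CHH": 0.45}


def plant_slh_loci(
    genome: SyntheticGenome,
    truth: TruthProfile,
    n_loci: int,
    seed: int = 0,
    slm_fraction: float = 0.5,
    bin_width: int = 100,
    min_sites_per_context: int = 3,
) -> TruthProfile:
    """Plant 100-bp sexual-lineage hypermethylation loci with known labels.

    Each locus is one analysis bin holding at least ``min_sites_per_context``
    cytosines of every context; a fraction ``slm_fraction`` receives the
    SLM-type somatic profile (essentially unmethylated non-CG soma), the rest
    the canonical profile.
    """
    if n_loci == 0:
        return truth
    rng = _rng(seed, "plant_slh")
    candidates = []
    for chrom in sorted(genome.chrom_sizes):
        ok = None
        for context in ("CG", "CHG", "CHH"):
            c = _candidate_bins(genome, chrom, context, bin_width, min_sites_per_context)
            ok = c if ok is None else (ok & c)
        candidates.extend((chrom, b) for b in np.flatnonzero(ok))
    if len(candidates) < n_loci:
        raise GenerationError(
            f"only {len(candidates)} candidate bins for {n_loci} SLH loci"
        )
    idx = rng.choice(len(candidates), size=n_loci, replace=False)
    n_slm = int(round(n_loci * slm_fraction))
    labels = np.array(["SLM"] * n_slm + ["canonical_SLH"] * (n_loci - n_slm))
    rng.shuffle(labels)
    loci = []
    for (chrom, b), label in zip((candidates[i] for i in sorted(idx)), labels):
        sex = SLM_SEX_LEVELS if label == "SLM" else CANONICAL_SEX_LEVELS
        som = SLM_SOMATIC_LEVELS if label == "SLM" else CANONICAL_SOMATIC_LEVELS
        loci.append(
            PlantedSlhLocus(
                chrom, int(b * bin_width), int((b + 1) * bin_width),
                dict(sex), dict(som), str(label),
            )
        )
    return TruthProfile(
        {ct: dict(levels) for ct, levels in truth.baselines.items()},
        planted_regions=list(truth.planted_regions),
        planted_slh=list(truth.planted_slh) + loci,
        sex_cell_types=truth.sex_cell_types,
        somatic_cell_types=truth.somatic_cell_types,
    )


def truth_regions_frame(truth: TruthProfile) -> pd.DataFrame:
    """Planted differential regions as a table (for recovery scoring/export)."""
    return pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.context, r.cell_type, r.delta)
            for r in truth.planted_regions
        ],
        columns=["chrom", "start", "end", "context", "cell_type", "delta"],
    )


def truth_slh_frame(truth: TruthProfile) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.chrom, l.start, l.end, l.intended) for l in truth.planted_slh],
        columns=["chrom", "start", "end", "intended"],
    )


def write_dataset(
    out_dir: str | Path,
    genome: SyntheticGenome,
    truth: TruthProfile,
    cell_types: Mapping[str, int],
    coverage_mean: float = 30.0,
    error_rate: float = 0.005,
    seed: int = 0,
) -> SampleManifest:
    """Write cytosine reports, annotation BED, truth tables and a manifest.

    ``cell_types`` maps cell type to its replicate count. Returns the
    manifest (also written to ``manifest.yaml``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for cell_type in sorted(cell_types):
        for rep in range(1, cell_types[cell_type] + 1):
            track = simulate_track(
                genome, truth, cell_type, rep, coverage_mean, error_rate, seed
            )
            fname = f"{cell_type}_rep{rep}.cx.tsv"
            write_cytosine_report(track, out_dir / fname)
            entries[(cell_type, rep)] = fname
    manifest = SampleManifest(entries, base_dir=out_dir)
    write_manifest(manifest, out_dir / "manifest.yaml")
    write_annotation_bed(genome.annotation, out_dir / "annotation.bed")
    truth_regions_frame(truth).to_csv(
        out_dir / "truth_regions.tsv", sep="\t", index=False
    )
    truth_slh_frame(truth).to_csv(out_dir / "truth_slh.tsv", sep="\t", index=False)
    return manifest
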