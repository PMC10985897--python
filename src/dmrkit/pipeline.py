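"""Configuration-driven orchestration of the full analysis.

A :class:`RunConfig` names the sample manifest, the annotation, the pairwise
comparisons to run and every threshold (all defaulting to the published
values). :func:`run_comparison` produces bin comparisons, DMR calls
(raw-bin and merged), DMG tables and density histograms for one cell-type
pair; :func:`run_slm` produces the SLH/SLM classification. Both write a
machine-readable run log recording parameters and input checksums, and both
are deterministic: identical config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import density, dmr, slm
from .errors import ConfigurationError
from .io import SampleManifest, read_annotation, read_manifest, write_bed
from .io import CONTEXTS, FeatureAnnotation

logger = logging.getLogger("dmrkit")


@dataclass
class RunConfig:
    manifest: Path
    annotation: Path | None = None
    comparisons: list = field(default_factory=list)  # [(cell_type_a, cell_type_b)]
    out_dir: Path = Path("dmrkit_out")
    seed: int = 0

    bin_width: int = 100
    min_coverage: int = 5
    min_cytosines: int = 5
    delta_thresholds: dict = field(default_factory=lambda: dict(dmr.DELTA_THRESHOLDS))
    alpha: float = dmr.DEFAULT_ALPHA
    merge_gap: int = dmr.DEFAULT_MERGE_GAP
    min_te_length: int = dmr.DEFAULT_MIN_TE_LENGTH
    dmg_min_fraction: float = dmr.DEFAULT_DMG_MIN_FRACTION

    density_window: int = density.DEFAULT_WINDOW
    density_min_informative: int = density.DEFAULT_MIN_INFORMATIVE
    density_min_level: dict = field(default_factory=lambda: dict(density.MIN_LEVELS))

    somatic_cell_type: str = "seedling"
    slh: slm.SlhParams = field(default_factory=slm.SlhParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text()) or {}
        slh = slm.SlhParams(**doc.pop("slh", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        manifest = Path(doc.pop("manifest", "manifest.yaml"))
        cfg = cls(manifest=manifest, **{**doc, "slh": slh})
        cfg.manifest = _resolve(path.parent, cfg.manifest)
        if cfg.annotation is not None:
            cfg.annotation = _resolve(path.parent, cfg.annotation)
        cfg.out_dir = _resolve(path.parent, cfg.out_dir)
        cfg.comparisons = [tuple(c) for c in cfg.comparisons]
        return cfg


def _resolve(base: Path, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate(config: RunConfig, cell_types) -> SampleManifest:
    manifest = read_manifest(config.manifest)
    missing = [ct for ct in cell_types if ct not in manifest.cell_types]
    if missing:
        raise ConfigurationError(
            f"manifest lacks cell type(s) {missing}; has {manifest.cell_types}"
        )
    for ct in cell_types:
        for rep in manifest.replicates(ct):
            p = manifest.path(ct, rep)
            if not p.exists():
                raise ConfigurationError(f"input file missing: {p}")
    return manifest


def _load_annotation(config: RunConfig) -> FeatureAnnotation | None:
    if config.annotation is None:
        return None
    return read_annotation(config.annotation)


def _input_checksums(manifest: SampleManifest, cell_types) -> dict:
    return {
        f"{ct}_rep{rep}": _sha256(manifest.path(ct, rep))
        for ct in cell_types
        for rep in manifest.replicates(ct)
    }


def _write_log(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def run_comparison(config: RunConfig, comparison: tuple) -> dict:
    """Run the DMR/DMG/density analysis for one (A, B) cell-type pair.

    Returns {output name: path}. Replicates are pooled before the coverage
    filter; the filter itself acts per cytosine inside the bin computations.
    """
    ct_a, ct_b = comparison
    manifest = _validate(config, [ct_a, ct_b])
    annotation = _load_annotation(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{ct_b}_vs_{ct_a}"
    logger.info("comparison %s: loading and pooling replicates", stem)
    track_a = manifest.load_pooled(ct_a)
    track_b = manifest.load_pooled(ct_b)
    logger.info("pooled %d (A) and %d (B) cytosine records", len(track_a), len(track_b))

    outputs = {}
    counts = {}
    for context in CONTEXTS:
        comp = dmr.compare_bins(
            track_a, track_b, context,
            config.bin_width, config.min_coverage, config.min_cytosines,
        )
        comp.to_csv(out_dir / f"{stem}.{context}.bins.tsv", sep="\t", index=False)
        outputs[f"bins_{context}"] = out_dir / f"{stem}.{context}.bins.tsv"

        raw = dmr.call_dmr_bins(comp, config.delta_thresholds, config.alpha)
        merged = dmr.merge_dmrs(raw, config.merge_gap)
        if annotation is not None:
            merged = dmr.annotate_dmrs(merged, annotation, config.min_te_length)
        merged.to_csv(out_dir / f"{stem}.{context}.dmrs.tsv", sep="\t", index=False)
        bed = merged.assign(
            name=merged["context"] + "_" + merged["direction"],
            score=merged["n_bins"],
            strand=".",
        )[["chrom", "start", "end", "name", "score", "strand"]]
        write_bed(bed, out_dir / f"{stem}.{context}.dmrs.bed")
        outputs[f"dmrs_{context}"] = out_dir / f"{stem}.{context}.dmrs.tsv"
        counts[context] = {
            "bins_compared": int(len(comp)),
            "dmr_bins": int(len(raw)),
            "dmrs_merged": int(len(merged)),
            "hyper": int((merged["direction"] == "hyper").sum()) if len(merged) else 0,
            "hypo": int((merged["direction"] == "hypo").sum()) if len(merged) else 0,
        }
        logger.info("%s %s: %s", stem, context, counts[context])

        if annotation is not None:
            dmgs = dmr.identify_dmgs(merged, annotation, config.dmg_min_fraction)
            dmgs.to_csv(out_dir / f"{stem}.{context}.dmgs.tsv", sep="\t", index=False)
            outputs[f"dmgs_{context}"] = out_dir / f"{stem}.{context}.dmgs.tsv"
            counts[context]["dmgs"] = int(dmgs["gene_id"].nunique()) if len(dmgs) else 0

        wins = density.density_differences(
            track_a, track_b, context,
            config.density_window, config.density_min_informative,
            config.density_min_level,
        )
        wins.to_csv(out_dir / f"{stem}.{context}.density.tsv", sep="\t", index=False)
        hist = density.difference_histogram(wins["difference"])
        hist.to_csv(out_dir / f"{stem}.{context}.density_hist.tsv", sep="\t", index=False)
        outputs[f"density_{context}"] = out_dir / f"{stem}.{context}.density.tsv"
        counts[context]["density_windows"] = int(len(wins))

    log_path = out_dir / f"{stem}.run_log.json"
    _write_log(
        log_path,
        {
            "task": "comparison",
            "comparison": [ct_a, ct_b],
            "parameters": {
                "bin_width": config.bin_width,
                "min_coverage": config.min_coverage,
                "min_cytosines": config.min_cytosines,
                "delta_thresholds": config.delta_thresholds,
                "alpha": config.alpha,
                "merge_gap": config.merge_gap,
                "min_te_length": config.min_te_length,
                "dmg_min_fraction": config.dmg_min_fraction,
                "density_window": config.density_window,
                "density_min_informative": config.density_min_informative,
                "density_min_level": config.density_min_level,
                "seed": config.seed,
            },
            "inputs": _input_checksums(manifest, [ct_a, ct_b]),
            "counts": counts,
        },
    )
    outputs["run_log"] = log_path
    return outputs


def run_slm(config: RunConfig) -> dict:
    """Run the SLH/SLM classification; needs meiocyte, microspore, sperm and
    the somatic cell type in the manifest."""
    required = list(slm.REQUIRED_SEX_CELLS) + [config.somatic_cell_type]
    manifest = _validate(config, required)
    annotation = _load_annotation(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("slm: loading replicate tracks for %s", required)
    sex_tracks = {
        ct: manifest.load_tracks(ct) for ct in slm.REQUIRED_SEX_CELLS
    }
    somatic_tracks = manifest.load_tracks(config.somatic_cell_type)
    loci = slm.identify_slh(sex_tracks, somatic_tracks, config.slh)
    classified = slm.split_slh(loci, config.slh)
    classified.to_csv(out_dir / "slh.tsv", sep="\t", index=False)
    if len(classified):
        bed = classified.assign(
            name=classified["classification"], score=0, strand="."
        )[["chrom", "start", "end", "name", "score", "strand"]]
    else:
        bed = classified.reindex(columns=["chrom", "start", "end", "name", "score", "strand"])
    write_bed(bed, out_dir / "slh.bed")
    outputs = {"slh_tsv": out_dir / "slh.tsv", "slh_bed": out_dir / "slh.bed"}
    n_slm = int((classified["classification"] == "SLM").sum()) if len(classified) else 0
    counts = {
        "slh_total": int(len(classified)),
        "slm": n_slm,
        "canonical_slh": int(len(classified)) - n_slm,
    }
    if annotation is not None:
        summary = slm.slh_feature_summary(classified, annotation, config.min_te_length)
        summary.to_csv(out_dir / "slh_feature_summary.tsv", sep="\t")
        outputs["feature_summary"] = out_dir / "slh_feature_summary.tsv"
    logger.info("slm: %s", counts)
    log_path = out_dir / "slm.run_log.json"
    _write_log(
        log_path,
        {
            "task": "slm",
            "parameters": {**dataclasses.asdict(config.slh), "seed": config.seed},
            "inputs": _input_checksums(manifest, required),
            "counts": counts,
        },
    )
    outputs["run_log"] = log_path
    return outputs
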