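"""End-to-end pipeline: quantify -> differential -> sequon -> composition ->
enrichment, with a run manifest for reproducibility.

``run_all`` executes the stages in dependency order on the four input files
(peptide table, glycosite table, proteome FASTA, annotation table), writes
every stage's TSV outputs into the run directory, and finishes with a
``manifest.json`` recording input checksums, the configuration, and
per-output row counts.  Identical inputs and configuration produce
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .composition import compare_composition
from .differential import Thresholds, call_differential, call_sets, call_summary, venn_partition
from .enrichment import cluster_heatmap, enrich, localization_summary
from .io_formats import (
    ExperimentDesign,
    read_annotation_table,
    read_fasta,
    read_peptide_table,
    read_site_table,
)
from .quantification import correct_site_ratios, normalize_by_median_ratio, rollup_protein
from .sequon import (
    classify_sites,
    find_sequons,
    occupancy_matrix,
    site_count_distribution,
    split_windows_by_kind,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, thresholds and flags of one pipeline run."""

    peptides: Path
    sites: Path
    proteome: Path
    annotations: Path
    outdir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    design: ExperimentDesign = field(default_factory=ExperimentDesign.default)
    bh_correct: bool = False
    namespaces: tuple[str, ...] = ("BP", "MF", "CC", "KEGG", "DOMAIN")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = Thresholds(
            fold_change=float(raw.get("fold_change", 1.5)),
            alpha=float(raw.get("alpha", 0.05)),
        )
        return cls(
            peptides=Path(raw["peptides"]),
            sites=Path(raw["sites"]),
            proteome=Path(raw["proteome"]),
            annotations=Path(raw["annotations"]),
            outdir=Path(raw["outdir"]),
            thresholds=thresholds,
            bh_correct=bool(raw.get("bh_correct", False)),
        )

    def validate(self) -> None:
        for name in ("peptides", "sites", "proteome", "annotations"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"input {name!r} not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
    manifest["outputs"][path.name] = int(len(df))


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.design
    labels = [design.comparison_label(c) for c in design.comparisons]

    manifest: dict = {
        "version": __version__,
        "inputs": {
            name: {"path": str(getattr(config, name)),
                   "sha256": _sha256(Path(getattr(config, name)))}
            for name in ("peptides", "sites", "proteome", "annotations")
        },
        "config": {
            "fold_change": config.thresholds.fold_change,
            "alpha": config.thresholds.alpha,
            "bh_correct": config.bh_correct,
            "comparisons": labels,
        },
        "stages": [],
        "outputs": {},
    }

    # ---- load ----------------------------------------------------------
    stage = "load"
    try:
        proteome = read_fasta(config.proteome)
        peptides = read_peptide_table(config.peptides, design)
        sites = read_site_table(config.sites, design, proteome=proteome)
        annotations = read_annotation_table(config.annotations)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    manifest["stages"].append(stage)

    # ---- quantify ------------------------------------------------------
    stage = "quantify"
    try:
        matrix = normalize_by_median_ratio(peptides, design)
        proteins = rollup_protein(matrix)
        site_quant = correct_site_ratios(sites, matrix, proteins)
        _write(proteins.table.reset_index(), outdir / "protein_quant.tsv", manifest)
        _write(site_quant.table, outdir / "site_quant.tsv", manifest)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    manifest["stages"].append(stage)

    # ---- differential --------------------------------------------------
    stage = "differential"
    try:
        prot_calls = call_differential(proteins.table, labels, config.thresholds,
                                       bh_correct=config.bh_correct)
        site_calls = call_differential(site_quant.table, labels, config.thresholds,
                                       ratio_prefix="corrected_ratio",
                                       bh_correct=config.bh_correct)
        _write(prot_calls, outdir / "differential_calls.tsv", manifest)
        _write(site_calls, outdir / "site_differential_calls.tsv", manifest)
        _write(call_summary(prot_calls).reset_index(), outdir / "call_summary.tsv",
               manifest)
        if len(labels) >= 3:
            for direction in ("up", "down"):
                sets = [call_sets(prot_calls, lab)[direction] for lab in labels[:3]]
                part = venn_partition(*sets, labels=tuple(labels[:3]))
                _write(part.to_frame(), outdir / f"venn_{direction}.tsv", manifest)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    manifest["stages"].append(stage)

    # ---- sequon / motif ------------------------------------------------
    stage = "sequon"
    try:
        sequon_rows = [
            {"accession": acc, "position": s.position, "triplet": s.triplet}
            for acc, seq in sorted(proteome.items())
            for s in find_sequons(seq, acc)
        ]
        _write(pd.DataFrame(sequon_rows, columns=["accession", "position", "triplet"]),
               outdir / "sequons.tsv", manifest)
        canonical, noncanonical = classify_sites(sites, proteome)
        if noncanonical:
            logger.warning("%d observed site(s) are non-canonical (no N-X-S/T)",
                           len(noncanonical))
        groups = split_windows_by_kind(canonical, proteome)
        windows = groups["N-X-S"] + groups["N-X-T"]
        if windows:
            _write(occupancy_matrix(windows), outdir / "occupancy_matrix.tsv",
                   manifest, index=True)
            dist = site_count_distribution(canonical)
            _write(dist.rename_axis("sites").reset_index(),
                   outdir / "site_count_distribution.tsv", manifest)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    manifest["stages"].append(stage)

    # ---- composition ---------------------------------------------------
    stage = "composition"
    try:
        frames = []
        for lab in labels:
            sets = call_sets(prot_calls, lab)
            up = [proteome[a] for a in sorted(sets["up"]) if a in proteome]
            down = [proteome[a] for a in sorted(sets["down"]) if a in proteome]
            if len(up) >= 2 and len(down) >= 2:
                cmp_df = compare_composition(up, down).reset_index()
                cmp_df.insert(0, "comparison", lab)
                frames.append(cmp_df)
        if frames:
            _write(pd.concat(frames, ignore_index=True),
                   outdir / "composition_up_vs_down.tsv", manifest)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    manifest["stages"].append(stage)

    # ---- enrichment ----------------------------------------------------
    stage = "enrich"
    try:
        background = set(proteins.table.index)
        enr_frames = []
        for lab in labels:
            sets = call_sets(prot_calls, lab)
            for direction in ("up", "down"):
                fg = sets[direction] & background
                if not fg:
                    continue
                for ns in config.namespaces:
                    df = enrich(fg, background, annotations, ns,
                                alpha=config.thresholds.alpha,
                                direction=f"{direction}@{lab}",
                                bh_correct=config.bh_correct)
                    if len(df):
                        enr_frames.append(df)
        if enr_frames:
            all_enr = pd.concat(enr_frames, ignore_index=True)
            _write(all_enr, outdir / "enrichment.tsv", manifest)
            heat = cluster_heatmap(all_enr, alpha=config.thresholds.alpha)
            _write(heat.matrix.rename_axis("category").reset_index(),
                   outdir / "heatmap_matrix.tsv", manifest)
        diff_accs = sorted(
            set(prot_calls.loc[prot_calls["call"].isin(["up", "down"]), "accession"]))
        if diff_accs:
            _write(localization_summary(diff_accs, annotations).reset_index(),
                   outdir / "localization_summary.tsv", manifest)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    manifest["stages"].append(stage)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
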