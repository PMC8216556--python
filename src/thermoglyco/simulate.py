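"""Seeded synthetic TMT glycoproteomics experiments with known ground truth.

The generator emulates the three-temperature (T30/T50/T55), triplicate TMT
design end-to-end: random protein sequences are digested in silico with a
trypsin-like rule, sampled peptides receive log-normal reporter-ion
intensities built as

    intensity = peptide base abundance x channel loading
                x 2^(condition effect) x multiplicative log-normal noise,

and glycosites planted inside valid N-X-S/T sequons receive an additional
occupancy effect independent of their parent protein's abundance effect.
Shared (non-unique) peptides are created by copying a tryptic fragment
from a donor protein into a recipient, mimicking homologs.  Annotation
categories are assigned at a background prevalence except for planted
categories, which preferentially cover the truly upregulated proteins of
the first comparison.

Everything is driven by a single seed; the same seed reproduces the same
dataset byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationTable,
    ExperimentDesign,
    GlycoSiteRecord,
    PeptideRecord,
    write_annotation_table,
    write_fasta,
    write_peptide_table,
    write_site_table,
)

# Approximate natural amino-acid frequencies (UniProt-wide averages).
AA_FREQ = {
    "A": 0.083, "R": 0.055, "N": 0.040, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.096, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.068,
}

LOCATION_PROBS = {
    "nucleus": 0.30, "cytoplasm": 0.22, "mitochondria": 0.20,
    "extracellular": 0.10, "plasma membrane": 0.08,
    "endoplasmic reticulum": 0.05, "Golgi": 0.03, "unknown": 0.02,
}

#: Default distribution of glycosites per glycoprotein (fractions observed
#: in the three-temperature study: 59/22/10/5/4 percent for 1/2/3/4/>=5).
DEFAULT_SITES_PER_GLYCOPROTEIN = {1: 0.59, 2: 0.22, 3: 0.10, 4: 0.05, 5: 0.03, 6: 0.01}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic experiment (defaults mirror the study design)."""

    seed: int = 1
    n_proteins: int = 1000
    peptides_per_protein: tuple[int, int] = (1, 10)
    frac_shared_peptides: float = 0.05
    conditions: tuple[str, ...] = ("T30", "T50", "T55")
    n_replicates: int = 3
    frac_up: float = 0.10
    frac_down: float = 0.10
    effect_size_log2: float = 1.0
    continuous_effects: bool = False  # draw log2 effects ~ N(0, effect_size_log2)
    noise_sd: float = 0.25            # sd of ln(multiplicative noise)
    channel_loading_sd: float = 0.10  # sd of ln(per-channel loading factor)
    n_glycoproteins: int = 200
    sites_per_glycoprotein: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SITES_PER_GLYCOPROTEIN))
    frac_site_regulated: float = 0.20
    site_effect_log2: float = 1.0
    n_categories: int = 50
    planted_enriched_categories: int = 2
    dropout_rate: float = 0.0
    protein_length: tuple[int, int] = (200, 800)

    def __post_init__(self) -> None:
        for name in ("frac_shared_peptides", "frac_up", "frac_down",
                     "frac_site_regulated", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.n_glycoproteins > self.n_proteins:
            raise ValueError("more glycoproteins than proteins")
        if abs(sum(self.sites_per_glycoprotein.values()) - 1.0) > 1e-9:
            raise ValueError("sites_per_glycoprotein must sum to 1")
        if self.noise_sd < 0 or self.effect_size_log2 < 0:
            raise ValueError("noise_sd and effect_size_log2 must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated inputs plus the ground truth they were built from."""

    config: SimulationConfig
    design: ExperimentDesign
    proteome: dict[str, str]
    peptides: list[PeptideRecord]
    sites: list[GlycoSiteRecord]
    annotations: AnnotationTable
    protein_truth: pd.DataFrame   # accession + per comparison log2fc / call
    site_truth: pd.DataFrame      # accession, position + per comparison log2fc / call
    category_truth: pd.DataFrame  # category, namespace, planted


def tryptic_digest(sequence: str, min_len: int = 6, max_len: int = 30) -> list[str]:
    """Fully cleaved trypsin-like fragments (cut after K/R, not before P),
    filtered to a length range typical of identified peptides."""
    frags, start = [], 0
    for i, ch in enumerate(sequence):
        if ch in "KR" and not (i + 1 < len(sequence) and sequence[i + 1] == "P"):
            frags.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        frags.append(sequence[start:])
    return [f for f in frags if min_len <= len(f) <= max_len]


def _true_call(log2fc: float, fold_change: float = 1.5) -> str:
    if 2.0 ** log2fc > fold_change:
        return "up"
    if 2.0 ** log2fc < 1.0 / fold_change:
        return "down"
    return "unchanged"


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic experiment from a config (seeded)."""
    rng = np.random.default_rng(config.seed)
    design = ExperimentDesign.default(config.conditions, config.n_replicates)
    baseline = config.conditions[0]
    accessions = [f"CT{i:04d}" for i in range(1, config.n_proteins + 1)]

    # --- sequences -------------------------------------------------------
    aa = np.array(list(AA_FREQ))
    aa_p = np.array(list(AA_FREQ.values()))
    aa_p = aa_p / aa_p.sum()
    lo, hi = config.protein_length
    seqs: dict[str, list[str]] = {}
    for acc in accessions:
        length = int(rng.integers(lo, hi + 1))
        seqs[acc] = list(rng.choice(aa, size=length, p=aa_p))

    # --- glycosites planted inside valid sequons -------------------------
    glyco_accs = sorted(rng.choice(accessions, size=config.n_glycoproteins,
                                   replace=False))
    site_counts = np.array(sorted(config.sites_per_glycoprotein))
    site_probs = np.array([config.sites_per_glycoprotein[k] for k in site_counts],
                          dtype=float)
    site_probs = site_probs / site_probs.sum()
    non_p = [r for r in AA_FREQ if r != "P"]
    planted_sites: list[tuple[str, int]] = []
    for acc in glyco_accs:
        seq = seqs[acc]
        n_sites = int(rng.choice(site_counts, p=site_probs))
        chosen: list[int] = []
        attempts = 0
        while len(chosen) < n_sites and attempts < 200:
            attempts += 1
            pos = int(rng.integers(1, len(seq) - 1))  # 1-based, needs pos+2 in seq
            if all(abs(pos - c) >= 3 for c in chosen):
                chosen.append(pos)
        for pos in sorted(chosen):
            seq[pos - 1] = "N"
            seq[pos] = str(rng.choice(non_p))
            seq[pos + 1] = "S" if rng.random() < 0.5 else "T"
            planted_sites.append((acc, pos))

    # --- shared peptides: copy a donor fragment into a recipient ---------
    n_shared = int(round(config.frac_shared_peptides * config.n_proteins))
    shared_pairs: list[tuple[str, str, str]] = []  # (donor, recipient, fragment)
    if n_shared and config.n_proteins >= 2:
        recipients = sorted(rng.choice(accessions, size=n_shared, replace=False))
        for rec_acc in recipients:
            for _ in range(20):
                donor = accessions[int(rng.integers(config.n_proteins))]
                if donor == rec_acc:
                    continue
                frags = [f for f in tryptic_digest("".join(seqs[donor]))
                         if f[0] != "P"]
                if frags:
                    frag = frags[int(rng.integers(len(frags)))]
                    if seqs[rec_acc][-1] not in "KR":  # keep the copy a clean fragment
                        seqs[rec_acc].append("K")
                    seqs[rec_acc].extend(frag)  # appended: site positions unshifted
                    shared_pairs.append((donor, rec_acc, frag))
                    break

    proteome = {acc: "".join(s) for acc, s in seqs.items()}

    # --- condition effects (protein abundance) ---------------------------
    effects: dict[str, dict[str, float]] = {}
    for acc in accessions:
        e = {baseline: 0.0}
        for cond in config.conditions[1:]:
            if config.continuous_effects:
                e[cond] = float(rng.normal(0.0, config.effect_size_log2))
            else:
                u = rng.random()
                if u < config.frac_up:
                    e[cond] = config.effect_size_log2
                elif u < config.frac_up + config.frac_down:
                    e[cond] = -config.effect_size_log2
                else:
                    e[cond] = 0.0
        effects[acc] = e

    # --- channel loadings & protein abundances ---------------------------
    loading = {
        ch: float(np.exp(rng.normal(0.0, config.channel_loading_sd)))
        for ch in design.channels
    }
    abundance = {acc: float(10.0 ** rng.normal(6.0, 0.5)) for acc in accessions}

    # --- peptide records --------------------------------------------------
    # Parent map from the final proteome so uniqueness reflects true sharing.
    parents_of: dict[str, set[str]] = {}
    frags_of: dict[str, list[str]] = {}
    for acc in accessions:
        frags = tryptic_digest(proteome[acc])
        frags_of[acc] = frags
        for f in set(frags):
            parents_of.setdefault(f, set()).add(acc)

    p_lo, p_hi = config.peptides_per_protein
    sampled: dict[str, tuple[str, ...]] = {}  # peptide_seq -> sorted parents
    for acc in accessions:
        frags = sorted(set(frags_of[acc]))
        if not frags:
            continue
        k = min(int(rng.integers(p_lo, p_hi + 1)), len(frags))
        take = rng.choice(len(frags), size=k, replace=False)
        for idx in sorted(take):
            seq = frags[idx]
            sampled.setdefault(seq, tuple(sorted(parents_of[seq])))
    for donor, rec_acc, frag in shared_pairs:  # guarantee shared peptides exist
        sampled.setdefault(frag, tuple(sorted(parents_of[frag])))

    peptides: list[PeptideRecord] = []
    for pep_seq in sorted(sampled):
        parents = sampled[pep_seq]
        ionization = float(np.exp(rng.normal(0.0, 1.0)))
        intens: dict[str, float | None] = {}
        for ch in design.channels:
            cond = design.condition_of[ch]
            signal = sum(
                abundance[p] * 2.0 ** effects[p][cond] for p in parents
            )
            value = signal * ionization * loading[ch]
            if config.noise_sd > 0:
                value *= float(np.exp(rng.normal(0.0, config.noise_sd)))
            if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
                intens[ch] = None
            else:
                intens[ch] = value
        peptides.append(PeptideRecord(pep_seq, parents, intens))

    # --- glycosite records with occupancy effects -------------------------
    site_rows = []
    sites: list[GlycoSiteRecord] = []
    for acc, pos in planted_sites:
        regulated = rng.random() < config.frac_site_regulated
        occ = {baseline: 0.0}
        for cond in config.conditions[1:]:
            if regulated:
                occ[cond] = config.site_effect_log2 * (1.0 if rng.random() < 0.5 else -1.0)
            else:
                occ[cond] = 0.0
        site_base = abundance[acc] * 0.5 * float(np.exp(rng.normal(0.0, 0.5)))
        intens: dict[str, float | None] = {}
        for ch in design.channels:
            cond = design.condition_of[ch]
            value = (site_base * 2.0 ** effects[acc][cond]
                     * 2.0 ** occ[cond] * loading[ch])
            if config.noise_sd > 0:
                value *= float(np.exp(rng.normal(0.0, config.noise_sd)))
            if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
                intens[ch] = None
            else:
                intens[ch] = value
        prob = float(rng.uniform(0.75, 1.0))
        sites.append(GlycoSiteRecord(acc, pos, intens, prob))
        row = {"accession": acc, "position": pos}
        for num, den in design.comparisons:
            lab = design.comparison_label((num, den))
            fc = occ[num] - occ[den]
            row[f"log2fc {lab}"] = fc
            row[f"call {lab}"] = _true_call(fc)
        site_rows.append(row)

    # --- protein truth -----------------------------------------------------
    prot_rows = []
    for acc in accessions:
        row = {"accession": acc}
        for num, den in design.comparisons:
            lab = design.comparison_label((num, den))
            fc = effects[acc][num] - effects[acc][den]
            row[f"log2fc {lab}"] = fc
            row[f"call {lab}"] = _true_call(fc)
        prot_rows.append(row)
    protein_truth = pd.DataFrame(prot_rows).set_index("accession")
    site_truth = pd.DataFrame(site_rows)

    # --- annotations -------------------------------------------------------
    annotations = AnnotationTable()
    first_lab = design.comparison_label(design.comparisons[0])
    up_first = set(protein_truth.index[protein_truth[f"call {first_lab}"] == "up"])
    cat_rows = []
    for c in range(config.n_categories):
        cat = f"GO:{7000000 + c:07d}"
        planted = c < config.planted_enriched_categories
        if planted:
            for acc in accessions:
                p_in = 0.5 if acc in up_first else 0.05
                if rng.random() < p_in:
                    annotations.go.setdefault(acc, []).append(("BP", cat))
        else:
            prevalence = float(rng.uniform(0.01, 0.10))
            for acc in accessions:
                if rng.random() < prevalence:
                    annotations.go.setdefault(acc, []).append(("BP", cat))
        cat_rows.append({"category": cat, "namespace": "BP", "planted": planted})
    category_truth = pd.DataFrame(cat_rows)

    kegg = [f"ko{10 + i:05d}" for i in range(10)]
    domains = [f"PF{100 + i:05d}" for i in range(15)]
    loc_names = list(LOCATION_PROBS)
    loc_p = np.array(list(LOCATION_PROBS.values()))
    loc_p = loc_p / loc_p.sum()
    for acc in accessions:
        for pathway in kegg:
            if rng.random() < 0.05:
                annotations.kegg.setdefault(acc, []).append(pathway)
        for dom in domains:
            if rng.random() < 0.04:
                annotations.domains.setdefault(acc, []).append(dom)
        annotations.location[acc] = str(rng.choice(loc_names, p=loc_p))

    return SyntheticDataset(
        config=config,
        design=design,
        proteome=proteome,
        peptides=peptides,
        sites=sites,
        annotations=annotations,
        protein_truth=protein_truth,
        site_truth=site_truth,
        category_truth=category_truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset as the pipeline's input files plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": outdir / "peptides.tsv",
        "sites": outdir / "sites.tsv",
        "proteome": outdir / "proteome.fasta",
        "annotations": outdir / "annotations.tsv",
        "protein_truth": outdir / "truth_proteins.tsv",
        "site_truth": outdir / "truth_sites.tsv",
        "category_truth": outdir / "truth_categories.tsv",
    }
    write_peptide_table(dataset.peptides, paths["peptides"], dataset.design)
    write_site_table(dataset.sites, paths["sites"], dataset.design)
    write_fasta(dataset.proteome, paths["proteome"])
    write_annotation_table(dataset.annotations, paths["annotations"])
    dataset.protein_truth.to_csv(paths["protein_truth"], sep="\t")
    dataset.site_truth.to_csv(paths["site_truth"], sep="\t", index=False)
    dataset.category_truth.to_csv(paths["category_truth"], sep="\t", index=False)
    return paths


def truth_report(
    calls: pd.DataFrame, truth: pd.DataFrame, by_site: bool = False
) -> pd.DataFrame:
    """Confusion summary of differential calls against the planted truth.

    ``calls`` is the long-format output of ``call_differential``; ``truth``
    the corresponding truth frame (``protein_truth`` or ``site_truth``).
    Returns, per comparison and direction (up/down): TP, FP, TN, FN,
    sensitivity and FDR.  Raises if calls mention identifiers absent from
    the truth.
    """
    keys = ["accession", "position"] if by_site else ["accession"]
    truth = truth.reset_index() if truth.index.name == "accession" else truth.copy()
    truth_ids = set(map(tuple, truth[keys].to_numpy()))
    call_ids = set(map(tuple, calls[keys].to_numpy()))
    unknown = call_ids - truth_ids
    if unknown:
        raise ValueError(f"{len(unknown)} identifier(s) in calls missing from truth")

    rows = []
    for lab in sorted(calls["comparison"].unique()):
        sub = calls[calls["comparison"] == lab].set_index(keys)
        tcol = truth.set_index(keys)[f"call {lab}"]
        joined = sub.join(tcol.rename("true_call"), how="left")
        for direction in ("up", "down"):
            pred = joined["call"] == direction
            actual = joined["true_call"] == direction
            tp = int((pred & actual).sum())
            fp = int((pred & ~actual).sum())
            fn = int((~pred & actual).sum())
            tn = int((~pred & ~actual).sum())
            rows.append({
                "comparison": lab,
                "direction": direction,
                "TP": tp, "FP": fp, "TN": tn, "FN": fn,
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "fdr": fp / (tp + fp) if tp + fp else 0.0,
            })
    return pd.DataFrame(rows)
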