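"""Reporter-ion quantitation: normalization, protein rollup, site correction.

The quantitation model
----------------------

For a comparison (numerator condition A, denominator condition B) the datum
is the per-replicate peptide ratio ``r_i = I[A_i] / I[B_i]``, pairing the
two conditions' channels by replicate index so that a triplicate design
yields three ratio observations per peptide.

Normalization is a two-stage median-ratio scheme computed from *unique*
peptides only (shared peptides are carried through but never inform a
normalizer or a protein ratio):

1. per replicate pair, every ratio is divided by the median ratio of all
   unique peptides in that pair — this is the per-sample median-ratio
   correction and makes the result invariant to rescaling any single
   channel;
2. the ratios are then divided by the grand median (over unique peptides)
   of the replicate-averaged ratio, so that after normalization the median
   replicate-averaged ratio over unique peptides is exactly 1.

Replicate averaging is geometric (a mean on the log2 scale), which makes a
reversed comparison map every peptide ratio to its exact reciprocal.
Protein rollup takes the *linear-scale* median of the protein's unique
peptide ratios, with the median of an even-sized set defined as the mean of
the two middle values.

The protein-corrected glycosite ratio divides the site's ratio by its
parent protein's ratio, isolating occupancy change from abundance change;
the reported identity ``corrected x protein = raw`` holds exactly.

Ratios below are stored as log2 internally and reported on the linear
scale.
"""

from __future__ import annotations

import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import student_t_two_tailed
from .io_formats import ExperimentDesign, GlycoSiteRecord, PeptideRecord

logger = logging.getLogger(__name__)


@contextmanager
def _nan_reductions():
    """NaN propagation through empty/all-NaN reductions is intended here."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice", RuntimeWarning)
        warnings.filterwarnings("ignore", "All-NaN slice encountered", RuntimeWarning)
        with np.errstate(invalid="ignore"):
            yield

#: Minimum number of replicate ratios for a peptide/site to enter a comparison.
MIN_REPLICATES = 2


class NormalizationError(ValueError):
    """No unique peptide with enough replicate ratios in a comparison."""


def _log2_intensity_matrix(records: Sequence, design: ExperimentDesign) -> np.ndarray:
    """n_records x n_channels log2 intensities; NaN for missing or zero.

    A measured zero cannot form a ratio, so it behaves like missing in ratio
    space; it is still distinct from missing in the stored records.
    """
    out = np.full((len(records), len(design.channels)), np.nan)
    for i, rec in enumerate(records):
        for j, ch in enumerate(design.channels):
            v = rec.intensities.get(ch)
            if v is not None and v > 0:
                out[i, j] = np.log2(v)
    return out


@dataclass
class NormalizedPeptideMatrix:
    """Peptide-level normalized ratios for every comparison of a design.

    Attributes
    ----------
    design : ExperimentDesign
    peptides : pandas.DataFrame
        Row metadata: ``peptide_seq``, ``accessions`` (';'-joined),
        ``is_unique``.
    log2_ratios : dict
        comparison label -> (n_peptides x n_replicates) array of normalized
        log2 replicate ratios (NaN where a replicate pair is incomplete).
    normalizers : dict
        comparison label -> (per-replicate log2 offsets, grand log2 offset)
        that were subtracted; recorded for provenance.
    log2_intensities : numpy.ndarray
        Raw log2 intensity matrix (peptides x channels), used downstream for
        channel-space significance testing.
    """

    design: ExperimentDesign
    peptides: pd.DataFrame
    log2_ratios: dict[str, np.ndarray]
    normalizers: dict[str, tuple[np.ndarray, float]]
    log2_intensities: np.ndarray
    min_replicates: int = MIN_REPLICATES

    @property
    def unique_mask(self) -> np.ndarray:
        return self.peptides["is_unique"].to_numpy()

    def peptide_ratio(self, comparison_label: str) -> np.ndarray:
        """Linear replicate-averaged (geometric mean) normalized ratio per
        peptide; NaN when fewer than ``min_replicates`` replicate ratios."""
        L = self.log2_ratios[comparison_label]
        n_ok = np.sum(np.isfinite(L), axis=1)
        with _nan_reductions():
            mean_log = np.nanmean(np.where(np.isfinite(L), L, np.nan), axis=1)
        out = np.power(2.0, mean_log)
        out[n_ok < self.min_replicates] = np.nan
        return out

    def ratio_table(self) -> pd.DataFrame:
        """Peptide metadata plus one linear ratio column per comparison."""
        df = self.peptides.copy()
        for comp in self.design.comparisons:
            lab = self.design.comparison_label(comp)
            df[f"ratio {lab}"] = self.peptide_ratio(lab)
        return df


def normalize_by_median_ratio(
    peptides: Sequence[PeptideRecord],
    design: ExperimentDesign,
    min_replicates: int = MIN_REPLICATES,
) -> NormalizedPeptideMatrix:
    """Median-ratio normalization of peptide reporter intensities.

    Raises
    ------
    NormalizationError
        If a comparison has no unique peptide with at least
        ``min_replicates`` replicate ratios.
    """
    meta = pd.DataFrame(
        {
            "peptide_seq": [p.peptide_seq for p in peptides],
            "accessions": [";".join(p.accessions) for p in peptides],
            "is_unique": [p.is_unique for p in peptides],
        }
    )
    logI = _log2_intensity_matrix(peptides, design)
    unique = meta["is_unique"].to_numpy()
    ch_index = {ch: j for j, ch in enumerate(design.channels)}

    log2_ratios: dict[str, np.ndarray] = {}
    normalizers: dict[str, tuple[np.ndarray, float]] = {}
    for comp in design.comparisons:
        lab = design.comparison_label(comp)
        pairs = design.replicate_pairs(comp)
        L = np.column_stack(
            [logI[:, ch_index[num]] - logI[:, ch_index[den]] for num, den in pairs]
        ) if pairs else np.empty((len(peptides), 0))

        # stage 1: per-replicate-pair median over unique peptides
        offsets = np.zeros(L.shape[1])
        for i in range(L.shape[1]):
            col = L[unique, i]
            if np.any(np.isfinite(col)):
                offsets[i] = np.nanmedian(col)
        L = L - offsets

        # stage 2: grand median of replicate-averaged ratios over unique
        # peptides that meet the replicate requirement
        n_ok = np.sum(np.isfinite(L), axis=1)
        eligible = unique & (n_ok >= min_replicates)
        if not np.any(eligible):
            raise NormalizationError(
                f"comparison {lab}: no unique peptide with >= {min_replicates} "
                f"replicate ratios")
        with _nan_reductions():
            mean_log = np.nanmean(L[eligible], axis=1)
        # linear-scale median (even sets: mean of the two middle values) so
        # the post-normalization median replicate-averaged ratio is exactly 1
        grand = float(np.log2(np.median(np.power(2.0, mean_log))))
        L = L - grand

        log2_ratios[lab] = L
        normalizers[lab] = (offsets, grand)

    return NormalizedPeptideMatrix(
        design=design,
        peptides=meta,
        log2_ratios=log2_ratios,
        normalizers=normalizers,
        log2_intensities=logI,
        min_replicates=min_replicates,
    )


# ---------------------------------------------------------------------------
# Protein rollup
# ---------------------------------------------------------------------------


@dataclass
class ProteinQuant:
    """Protein-level quantitation derived from unique peptides.

    ``table`` is indexed by accession with ``n_unique_peptides`` plus, per
    comparison label, ``ratio <label>`` (linear) and ``p_value <label>``.
    ``replicate_log2`` keeps the per-replicate protein log2 ratios used for
    site-level testing.
    """

    design: ExperimentDesign
    table: pd.DataFrame
    replicate_log2: dict[str, pd.DataFrame] = field(default_factory=dict)

    def ratio(self, accession: str, comparison_label: str) -> float:
        if accession not in self.table.index:
            return float("nan")
        return float(self.table.at[accession, f"ratio {comparison_label}"])


def rollup_protein(matrix: NormalizedPeptideMatrix) -> ProteinQuant:
    """Roll unique-peptide ratios up to protein ratios and p-values.

    Per comparison, the protein ratio is the linear-scale median of its
    unique peptides' replicate-averaged normalized ratios.  The p-value is a
    pooled two-sample t-test comparing the protein's log2 channel abundances
    (median over unique peptides of row-centered, channel-median-corrected
    log2 intensities) between the two conditions' replicate channels.

    Proteins without unique peptides are omitted, with a logged count.
    """
    design = matrix.design
    meta = matrix.peptides
    unique = matrix.unique_mask

    acc_of_row = meta["accessions"].to_numpy()
    shared_accs = {a for accs, u in zip(acc_of_row, unique) if not u for a in accs.split(";")}
    rows_of: dict[str, list[int]] = {}
    for i in np.flatnonzero(unique):
        rows_of.setdefault(acc_of_row[i], []).append(i)
    n_only_shared = len(shared_accs - set(rows_of))
    if n_only_shared:
        logger.info("%d protein(s) without unique peptides omitted from rollup",
                    n_only_shared)

    accessions = sorted(rows_of)
    row_idx = {a: k for k, a in enumerate(accessions)}

    # channel-space abundances for significance testing
    v = matrix.log2_intensities.copy()
    with _nan_reductions():
        v = v - np.nanmean(v, axis=1, keepdims=True)          # peptide row-centering
        ch_med = np.nanmedian(v[unique], axis=0)              # per-channel loading
    v = v - ch_med

    table = pd.DataFrame(index=pd.Index(accessions, name="accession"))
    table["n_unique_peptides"] = [len(rows_of[a]) for a in accessions]
    replicate_log2: dict[str, pd.DataFrame] = {}

    ch_index = {ch: j for j, ch in enumerate(design.channels)}
    for comp in design.comparisons:
        lab = design.comparison_label(comp)
        L = matrix.log2_ratios[lab]
        pep_ratio = matrix.peptide_ratio(lab)
        n_rep = L.shape[1]

        ratios = np.full(len(accessions), np.nan)
        pvals = np.full(len(accessions), np.nan)
        rep_log = np.full((len(accessions), n_rep), np.nan)

        num_cols = [ch_index[c] for c in design.channels_of(comp[0])]
        den_cols = [ch_index[c] for c in design.channels_of(comp[1])]

        for acc in accessions:
            k = row_idx[acc]
            rows = rows_of[acc]
            vals = pep_ratio[rows]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                ratios[k] = float(np.median(vals))
            with _nan_reductions():
                for i in range(n_rep):
                    col = L[rows, i]
                    col = col[np.isfinite(col)]
                    if col.size:
                        rep_log[k, i] = float(np.median(col))
                ga = np.nanmedian(v[np.ix_(rows, num_cols)], axis=0)
                gb = np.nanmedian(v[np.ix_(rows, den_cols)], axis=0)
            ga, gb = ga[np.isfinite(ga)], gb[np.isfinite(gb)]
            if ga.size >= 2 and gb.size >= 2 and np.isfinite(ratios[k]):
                pvals[k] = student_t_two_tailed(ga, gb)

        table[f"ratio {lab}"] = ratios
        table[f"p_value {lab}"] = pvals
        replicate_log2[lab] = pd.DataFrame(
            rep_log, index=table.index, columns=[f"rep{i+1}" for i in range(n_rep)]
        )

    return ProteinQuant(design=design, table=table, replicate_log2=replicate_log2)


# ---------------------------------------------------------------------------
# Glycosite correction
# ---------------------------------------------------------------------------


def correct_site_ratio(raw_ratio: float, protein_ratio: float) -> float:
    """Protein-corrected site ratio: raw divided by the parent protein ratio.

    Returns NaN (flagged absent) when the protein ratio is missing or
    non-positive; the correction is never silently skipped.
    """
    if not np.isfinite(protein_ratio) or protein_ratio <= 0:
        return float("nan")
    if not np.isfinite(raw_ratio):
        return float("nan")
    return raw_ratio / protein_ratio


@dataclass
class SiteQuant:
    """Site-level quantitation: raw and protein-corrected ratios.

    ``table`` columns: ``accession``, ``position``, ``parent_quantified``
    plus per comparison ``raw_ratio``, ``corrected_ratio``, ``p_value``.
    """

    design: ExperimentDesign
    table: pd.DataFrame


def correct_site_ratios(
    sites: Sequence[GlycoSiteRecord],
    matrix: NormalizedPeptideMatrix,
    proteins: ProteinQuant,
) -> SiteQuant:
    """Normalize site ratios and divide by the parent protein ratio.

    Site replicate ratios receive the same per-comparison normalizers that
    were derived from the unique peptides.  Significance is a pooled
    two-sample t-test of the site's log2 replicate ratios against the parent
    protein's per-replicate log2 ratios, i.e. a test of occupancy change
    over and above abundance change.
    """
    design = matrix.design
    logI = _log2_intensity_matrix(sites, design)
    ch_index = {ch: j for j, ch in enumerate(design.channels)}

    base = pd.DataFrame(
        {
            "accession": [s.accession for s in sites],
            "position": [s.position for s in sites],
        }
    )
    parent_known = base["accession"].isin(proteins.table.index).to_numpy()
    base["parent_quantified"] = parent_known

    out = base.copy()
    for comp in design.comparisons:
        lab = design.comparison_label(comp)
        pairs = design.replicate_pairs(comp)
        offsets, grand = matrix.normalizers[lab]
        Ls = np.column_stack(
            [logI[:, ch_index[num]] - logI[:, ch_index[den]] for num, den in pairs]
        ) if pairs else np.empty((len(sites), 0))
        Ls = Ls - offsets - grand

        n_ok = np.sum(np.isfinite(Ls), axis=1)
        with _nan_reductions():
            raw = np.power(2.0, np.nanmean(np.where(np.isfinite(Ls), Ls, np.nan), axis=1))
        raw[n_ok < matrix.min_replicates] = np.nan

        corrected = np.full(len(sites), np.nan)
        pvals = np.full(len(sites), np.nan)
        prot_rep = proteins.replicate_log2[lab]
        for i, s in enumerate(sites):
            pr = proteins.ratio(s.accession, lab)
            corrected[i] = correct_site_ratio(raw[i], pr)
            if s.accession in prot_rep.index:
                a = Ls[i][np.isfinite(Ls[i])]
                b = prot_rep.loc[s.accession].to_numpy()
                b = b[np.isfinite(b)]
                if a.size >= 2 and b.size >= 2:
                    pvals[i] = student_t_two_tailed(a, b)

        out[f"raw_ratio {lab}"] = raw
        out[f"corrected_ratio {lab}"] = corrected
        out[f"p_value {lab}"] = pvals

    return SiteQuant(design=design, table=out)
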