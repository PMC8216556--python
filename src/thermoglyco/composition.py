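"""Amino-acid composition profiles of protein sets.

Composition is computed per protein first (percent of each of the 20
standard residues among that protein's standard residues), then averaged
*unweighted* over proteins, so a long protein does not dominate the
profile.  The dispersion reported is the standard error of the mean over
proteins.  Ambiguity codes and selenocysteine (B, Z, X, U) are excluded
from both numerator and denominator.

Two sets are compared residue-by-residue with a pooled two-sample t-test
over the per-protein percentages — e.g. to ask whether proteins
upregulated at high temperature are enriched in charged residues.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import student_t_two_tailed
from .io_formats import AMINO_ACIDS


def _percent_matrix(sequences: Sequence[str]) -> np.ndarray:
    """n_proteins x 20 per-protein percent composition."""
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    mat = np.zeros((len(sequences), len(AMINO_ACIDS)))
    for r, seq in enumerate(sequences):
        counts = np.zeros(len(AMINO_ACIDS))
        for ch in seq:
            i = aa_index.get(ch)
            if i is not None:
                counts[i] += 1
        total = counts.sum()
        if total == 0:
            raise ValueError(f"sequence #{r} has no standard residues")
        mat[r] = 100.0 * counts / total
    return mat


def aa_composition(sequences: Sequence[str]) -> pd.DataFrame:
    """Mean percent composition of a protein set.

    Returns a DataFrame indexed by residue with ``mean_percent``, ``sem``
    and ``n_proteins``; the means sum to 100.
    """
    if not sequences:
        raise ValueError("aa_composition requires at least one sequence")
    mat = _percent_matrix(sequences)
    n = mat.shape[0]
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mat.shape[1])
    return pd.DataFrame(
        {"mean_percent": mat.mean(axis=0), "sem": sem, "n_proteins": n},
        index=pd.Index(list(AMINO_ACIDS), name="residue"),
    )


def compare_composition(
    sequences_a: Sequence[str], sequences_b: Sequence[str]
) -> pd.DataFrame:
    """Per-residue composition difference between two protein sets.

    Returns, per residue: mean percent in each set, ``difference``
    (A minus B) and a two-tailed two-sample t-test p-value over the
    per-protein percentages.  Sets with fewer than 2 proteins get p = NaN.
    """
    mat_a = _percent_matrix(sequences_a) if sequences_a else None
    mat_b = _percent_matrix(sequences_b) if sequences_b else None
    if mat_a is None or mat_b is None:
        raise ValueError("both sets must be non-empty")

    rows = []
    for i, aa in enumerate(AMINO_ACIDS):
        a, b = mat_a[:, i], mat_b[:, i]
        if a.size >= 2 and b.size >= 2:
            p = student_t_two_tailed(a, b)
        else:
            p = float("nan")
        rows.append(
            {
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "difference": a.mean() - b.mean(),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(list(AMINO_ACIDS), name="residue"))


def composition_of_accessions(
    accessions: Sequence[str], proteome: Mapping[str, str]
) -> pd.DataFrame:
    """Convenience: composition profile of a set of accessions."""
    seqs = [proteome[a] for a in accessions if a in proteome]
    if not seqs:
        raise ValueError("no accession found in the proteome")
    return aa_composition(seqs)
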