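"""N-linked glycosylation sequons and the +/-10 occupancy-frequency matrix.

The N-linked consensus is Asn-X-Ser/Thr with X any residue except Pro.
Overlapping sequons are all reported (each Asn is independently
glycosylatable: ``NNTS`` has sequons at both positions 1 and 2).

Around each glycosite a 21-mer window (10 residues up- and downstream of
the modified Asn) is extracted; positions beyond the protein termini are
padded with ``_`` and excluded from frequency denominators so boundary
positions are not diluted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, GlycoSiteRecord

PAD = "_"
WINDOW_FLANK = 10
WINDOW_LENGTH = 2 * WINDOW_FLANK + 1


@dataclass(frozen=True)
class Sequon:
    """One N-X-S/T match: 1-based Asn position plus the triplet itself."""

    accession: str
    position: int
    triplet: str

    @property
    def kind(self) -> str:
        """'N-X-S' or 'N-X-T' depending on the third residue."""
        return f"N-X-{self.triplet[2]}"


def find_sequons(sequence: str, accession: str = "") -> list[Sequon]:
    """All (possibly overlapping) N-X-S/T sequons of a sequence, 1-based.

    X must not be proline.  Sequences shorter than 3 yield an empty list.
    """
    out = []
    for i in range(len(sequence) - 2):
        if sequence[i] == "N" and sequence[i + 1] != "P" and sequence[i + 2] in "ST":
            out.append(Sequon(accession, i + 1, sequence[i : i + 3]))
    return out


def extract_window(sequence: str, position: int, flank: int = WINDOW_FLANK) -> str:
    """(2*flank+1)-mer centered on the glycosylated Asn, ``_``-padded.

    ``position`` is 1-based and must carry an Asn.
    """
    if position < 1 or position > len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    if sequence[position - 1] != "N":
        raise ValueError(f"residue at position {position} is {sequence[position-1]!r}, not 'N'")
    i = position - 1
    left = sequence[max(0, i - flank) : i]
    right = sequence[i + 1 : i + 1 + flank]
    return PAD * (flank - len(left)) + left + "N" + right + PAD * (flank - len(right))


def occupancy_matrix(windows: Sequence[str], flank: int = WINDOW_FLANK) -> pd.DataFrame:
    """Per-position residue frequencies over aligned glycosite windows.

    Returns a 20-residue x (2*flank+1)-position DataFrame (columns labelled
    -flank..+flank).  Pad characters are excluded from each position's
    denominator, so every column with at least one real residue sums to 1.
    """
    if not windows:
        raise ValueError("occupancy_matrix requires at least one window")
    width = 2 * flank + 1
    for w in windows:
        if len(w) != width:
            raise ValueError(f"window {w!r} is not {width} characters")
    positions = list(range(-flank, flank + 1))
    mat = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=positions)
    for j, pos in enumerate(positions):
        counts = Counter(w[j] for w in windows)
        counts.pop(PAD, None)
        total = sum(counts.values())
        if total:
            for aa, c in counts.items():
                if aa in mat.index:
                    mat.at[aa, pos] = c / total
    return mat


def split_windows_by_kind(
    sites: Iterable[GlycoSiteRecord], proteome: Mapping[str, str]
) -> dict[str, list[str]]:
    """Windows grouped into 'N-X-S' / 'N-X-T' subsets (sequon sites only)."""
    groups: dict[str, list[str]] = {"N-X-S": [], "N-X-T": []}
    for site in sites:
        seq = proteome[site.accession]
        i = site.position - 1
        if i + 2 < len(seq) and seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            groups[f"N-X-{seq[i+2]}"].append(extract_window(seq, site.position))
    return groups


def classify_sites(
    sites: Iterable[GlycoSiteRecord], proteome: Mapping[str, str]
) -> tuple[list[GlycoSiteRecord], list[GlycoSiteRecord]]:
    """Split observed sites into (canonical sequon, non-canonical) lists.

    Non-canonical sites (an observed Asn outside an N-X-S/T context, e.g.
    chemical deamidation artifacts) are reported separately and excluded
    from motif matrices by default, never silently dropped.
    """
    canonical, noncanonical = [], []
    for site in sites:
        seq = proteome.get(site.accession, "")
        i = site.position - 1
        ok = (
            0 <= i < len(seq)
            and seq[i] == "N"
            and i + 2 < len(seq)
            and seq[i + 1] != "P"
            and seq[i + 2] in "ST"
        )
        (canonical if ok else noncanonical).append(site)
    return canonical, noncanonical


SITE_COUNT_BINS = ("1", "2", "3", "4", "5+")


def site_count_distribution(sites: Iterable[GlycoSiteRecord | Sequon]) -> pd.Series:
    """Fraction of glycoproteins carrying 1, 2, 3, 4 or >=5 distinct sites."""
    per_protein = Counter()
    seen = set()
    for s in sites:
        key = (s.accession, s.position)
        if key in seen:
            continue
        seen.add(key)
        per_protein[s.accession] += 1
    if not per_protein:
        raise ValueError("no glycoproteins")
    binned = Counter()
    for n in per_protein.values():
        binned[str(n) if n < 5 else "5+"] += 1
    total = sum(binned.values())
    return pd.Series({b: binned.get(b, 0) / total for b in SITE_COUNT_BINS}, name="fraction")
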