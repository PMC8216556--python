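"""Tabular and sequence IO with strict validation.

All tables are tab-separated UTF-8 with '.' as the decimal mark (the dialect
of MaxQuant-style exports).  Missing reporter intensities may be encoded as
an empty field, ``NA`` or ``NaN``; a literal ``0`` is a measured zero and is
kept distinct from missingness, because zeros and missing values behave
differently in ratio arithmetic.

Readers never silently drop data: every rejected row is logged with its row
number and a reason, and structural problems (missing columns, duplicate
accessions, unknown term types) raise :class:`FormatError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 20 standard residues.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Additionally tolerated in sequences (ambiguity codes / selenocysteine).
EXTENDED_RESIDUES = set(AMINO_ACIDS) | set("BZXU")

MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}

GO_NAMESPACES = ("BP", "MF", "CC")
TERM_TYPES = {"GO:BP", "GO:MF", "GO:CC", "KEGG", "DOMAIN", "LOCATION"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Experiment design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentDesign:
    """Channel layout of a multiplexed TMT experiment.

    Parameters
    ----------
    channels
        Ordered channel identifiers (e.g. TMT reporter labels).
    condition_of
        Channel -> condition label (``T30``/``T50``/``T55`` in the default
        three-temperature design).
    replicate_of
        Channel -> 1-based replicate index within its condition.
    comparisons
        Ordered (numerator condition, denominator condition) pairs.
    """

    channels: tuple[str, ...]
    condition_of: Mapping[str, str]
    replicate_of: Mapping[str, int]
    comparisons: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        conds: dict[str, list[str]] = {}
        for ch in self.channels:
            if ch not in self.condition_of or ch not in self.replicate_of:
                raise ValueError(f"channel {ch!r} lacks condition or replicate")
            conds.setdefault(self.condition_of[ch], []).append(ch)
        for cond, chans in conds.items():
            if len(chans) < 2:
                raise ValueError(f"condition {cond!r} has <2 replicate channels")
            reps = sorted(self.replicate_of[c] for c in chans)
            if len(set(reps)) != len(reps):
                raise ValueError(f"condition {cond!r} has duplicate replicate indices")
        for num, den in self.comparisons:
            if num not in conds or den not in conds:
                raise ValueError(f"comparison ({num}, {den}) uses unknown condition")

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ch in self.channels:
            seen.setdefault(self.condition_of[ch], None)
        return tuple(seen)

    def channels_of(self, condition: str) -> tuple[str, ...]:
        """Channels of one condition, ordered by replicate index."""
        chans = [c for c in self.channels if self.condition_of[c] == condition]
        return tuple(sorted(chans, key=lambda c: self.replicate_of[c]))

    def replicate_pairs(self, comparison: tuple[str, str]) -> tuple[tuple[str, str], ...]:
        """Per-replicate (numerator channel, denominator channel) pairs.

        Pairing is by replicate index; a replicate present in only one of the
        two conditions is skipped.
        """
        num, den = comparison
        num_by_rep = {self.replicate_of[c]: c for c in self.channels_of(num)}
        den_by_rep = {self.replicate_of[c]: c for c in self.channels_of(den)}
        shared = sorted(set(num_by_rep) & set(den_by_rep))
        return tuple((num_by_rep[r], den_by_rep[r]) for r in shared)

    @staticmethod
    def comparison_label(comparison: tuple[str, str]) -> str:
        return f"{comparison[0]}/{comparison[1]}"

    @classmethod
    def default(
        cls,
        conditions: Sequence[str] = ("T30", "T50", "T55"),
        n_replicates: int = 3,
        comparisons: Sequence[tuple[str, str]] | None = None,
    ) -> "ExperimentDesign":
        """Three-temperature triplicate design with its canonical comparisons."""
        channels, cond_of, rep_of = [], {}, {}
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                ch = f"{cond}_{rep}"
                channels.append(ch)
                cond_of[ch] = cond
                rep_of[ch] = rep
        if comparisons is None:
            if tuple(conditions) == ("T30", "T50", "T55"):
                comparisons = [("T50", "T30"), ("T55", "T30"), ("T55", "T50")]
            else:
                base = conditions[0]
                comparisons = [(c, base) for c in conditions[1:]]
        return cls(tuple(channels), cond_of, rep_of, tuple(tuple(c) for c in comparisons))


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide with per-channel reporter-ion intensities.

    ``intensities`` maps every design channel to a non-negative float or to
    ``None`` for a missing measurement.  A peptide is *unique* iff it maps to
    exactly one protein accession; only unique peptides enter normalization
    and protein quantitation.
    """

    peptide_seq: str
    accessions: tuple[str, ...]
    intensities: Mapping[str, float | None]

    def __post_init__(self) -> None:
        if not self.peptide_seq:
            raise ValueError("empty peptide sequence")
        if not self.accessions:
            raise ValueError("peptide with no accession")
        for ch, v in self.intensities.items():
            if v is not None and (v != v or v < 0):
                raise ValueError(f"negative/NaN intensity in channel {ch}")

    @property
    def is_unique(self) -> bool:
        return len(self.accessions) == 1


@dataclass(frozen=True)
class GlycoSiteRecord:
    """An N-glycosylation site: a protein accession plus a 1-based Asn index."""

    accession: str
    position: int
    intensities: Mapping[str, float | None]
    localization_prob: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("site position must be >= 1")
        if self.localization_prob is not None and not (0.0 <= self.localization_prob <= 1.0):
            raise ValueError("localization_prob outside [0, 1]")


@dataclass
class AnnotationTable:
    """Per-accession functional annotation: GO terms, KEGG pathways, domains,
    and a single primary subcellular location label.

    Lookups for accessions absent from the table return empty lists / None.
    """

    go: dict[str, list[tuple[str, str]]] = field(default_factory=dict)  # acc -> [(ns, term)]
    kegg: dict[str, list[str]] = field(default_factory=dict)
    domains: dict[str, list[str]] = field(default_factory=dict)
    location: dict[str, str] = field(default_factory=dict)

    def go_terms(self, accession: str, namespace: str | None = None) -> list[str]:
        terms = self.go.get(accession, [])
        if namespace is None:
            return [t for _, t in terms]
        if namespace not in GO_NAMESPACES:
            raise ValueError(f"unknown GO namespace {namespace!r}")
        return [t for ns, t in terms if ns == namespace]

    def kegg_pathways(self, accession: str) -> list[str]:
        return list(self.kegg.get(accession, []))

    def domain_list(self, accession: str) -> list[str]:
        return list(self.domains.get(accession, []))

    def subcellular_location(self, accession: str) -> str | None:
        return self.location.get(accession)

    def accessions(self) -> set[str]:
        return set(self.go) | set(self.kegg) | set(self.domains) | set(self.location)

    def terms_by_category(self, namespace: str) -> dict[str, set[str]]:
        """category/term -> set of annotated accessions, for one namespace.

        ``namespace`` is one of ``BP``/``MF``/``CC`` (GO), ``KEGG`` or
        ``DOMAIN``.
        """
        out: dict[str, set[str]] = {}
        if namespace in GO_NAMESPACES:
            for acc, terms in self.go.items():
                for ns, term in terms:
                    if ns == namespace:
                        out.setdefault(term, set()).add(acc)
        elif namespace == "KEGG":
            for acc, paths in self.kegg.items():
                for p in paths:
                    out.setdefault(p, set()).add(acc)
        elif namespace == "DOMAIN":
            for acc, doms in self.domains.items():
                for d in doms:
                    out.setdefault(d, set()).add(acc)
        else:
            raise ValueError(f"unknown annotation namespace {namespace!r}")
        return out


# ---------------------------------------------------------------------------
# Accession normalization
# ---------------------------------------------------------------------------


def normalize_accession(raw: str) -> str:
    """Reduce a FASTA header token to a bare accession.

    UniProt ``sp|ACC|NAME`` / ``tr|ACC|NAME`` wrappers are stripped to
    ``ACC``; anything else is returned unchanged.
    """
    if raw.startswith(("sp|", "tr|")):
        parts = raw.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return raw


# ---------------------------------------------------------------------------
# Intensity parsing
# ---------------------------------------------------------------------------


def _parse_intensity(token: str) -> float | None:
    tok = token.strip()
    if tok in MISSING_TOKENS:
        return None
    value = float(tok)  # ValueError propagates to caller
    if value < 0:
        raise ValueError(f"negative intensity {tok}")
    return value


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Peptide table
# ---------------------------------------------------------------------------


def read_peptide_table(path: str | Path, design: ExperimentDesign) -> list[PeptideRecord]:
    """Read a peptide quantification TSV.

    Required columns: ``peptide_seq``, ``accessions`` (semicolon-delimited),
    and one intensity column per design channel.  Rows with an unparsable
    intensity are rejected and logged with their (1-based, header-exclusive)
    row number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    _require_columns(df, ["peptide_seq", "accessions", *design.channels], path)

    records: list[PeptideRecord] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            intens = {ch: _parse_intensity(rowd[ch]) for ch in design.channels}
            accs = tuple(a for a in rowd["accessions"].split(";") if a)
            records.append(PeptideRecord(rowd["peptide_seq"], accs, intens))
        except ValueError as exc:
            n_rejected += 1
            logger.warning("%s: rejected peptide row %d: %s", path.name, i, exc)
    if n_rejected:
        logger.warning("%s: %d peptide row(s) rejected", path.name, n_rejected)
    return records


def write_peptide_table(records: Sequence[PeptideRecord], path: str | Path,
                        design: ExperimentDesign) -> None:
    rows = []
    for r in records:
        row = {"peptide_seq": r.peptide_seq, "accessions": ";".join(r.accessions)}
        for ch in design.channels:
            v = r.intensities.get(ch)
            row[ch] = "NA" if v is None else repr(v)
        rows.append(row)
    pd.DataFrame(rows, columns=["peptide_seq", "accessions", *design.channels]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Glycosite table
# ---------------------------------------------------------------------------


def read_site_table(path: str | Path, design: ExperimentDesign,
                    proteome: Mapping[str, str] | None = None) -> list[GlycoSiteRecord]:
    """Read a glycosite TSV (accession, position, per-channel intensities).

    If ``proteome`` is given, sites whose position does not carry an Asn in
    the parent sequence are rejected with a logged reason.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    _require_columns(df, ["accession", "position", *design.channels], path)
    has_prob = "localization_prob" in df.columns

    records: list[GlycoSiteRecord] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            pos = int(rowd["position"])
            acc = normalize_accession(rowd["accession"])
            if proteome is not None:
                seq = proteome.get(acc)
                if seq is None:
                    raise ValueError(f"accession {acc} absent from proteome")
                if pos > len(seq) or seq[pos - 1] != "N":
                    raise ValueError(f"residue at position {pos} of {acc} is not N")
            intens = {ch: _parse_intensity(rowd[ch]) for ch in design.channels}
            prob = _parse_intensity(rowd["localization_prob"]) if has_prob else None
            records.append(GlycoSiteRecord(acc, pos, intens, prob))
        except ValueError as exc:
            n_rejected += 1
            logger.warning("%s: rejected site row %d: %s", path.name, i, exc)
    if n_rejected:
        logger.warning("%s: %d site row(s) rejected", path.name, n_rejected)
    return records


def write_site_table(records: Sequence[GlycoSiteRecord], path: str | Path,
                     design: ExperimentDesign) -> None:
    rows = []
    for r in records:
        row = {"accession": r.accession, "position": r.position}
        for ch in design.channels:
            v = r.intensities.get(ch)
            row[ch] = "NA" if v is None else repr(v)
        row["localization_prob"] = "NA" if r.localization_prob is None else repr(r.localization_prob)
        rows.append(row)
    cols = ["accession", "position", *design.channels, "localization_prob"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a proteome FASTA into accession -> uppercase sequence.

    The accession is the first whitespace-delimited header token, with
    UniProt ``sp|ACC|NAME`` wrappers reduced to ``ACC``.  ``*`` (stop) is
    stripped; any other non-amino-acid character is a format error, as is a
    duplicated accession.
    """
    path = Path(path)
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = normalize_accession(rec.id)
        if acc in proteome:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        seq = str(rec.seq).upper().replace("*", "")
        bad = set(seq) - EXTENDED_RESIDUES
        if bad:
            raise FormatError(
                f"{path}: sequence {acc!r} contains non-amino-acid character(s) "
                f"{''.join(sorted(bad))!r}")
        proteome[acc] = seq
    if not proteome:
        raise FormatError(f"{path}: no FASTA records")
    return proteome


def write_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in proteome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a long-format annotation TSV: accession, term_type, term.

    ``term_type`` is one of ``GO:BP``, ``GO:MF``, ``GO:CC``, ``KEGG``,
    ``DOMAIN``, ``LOCATION``; anything else is a format error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    _require_columns(df, ["accession", "term_type", "term"], path)

    table = AnnotationTable()
    for i, (acc, ttype, term) in enumerate(
            zip(df["accession"], df["term_type"], df["term"]), start=1):
        acc = normalize_accession(acc)
        if ttype not in TERM_TYPES:
            raise FormatError(f"{path}: row {i}: unknown term type {ttype!r}")
        if ttype.startswith("GO:"):
            table.go.setdefault(acc, []).append((ttype[3:], term))
        elif ttype == "KEGG":
            table.kegg.setdefault(acc, []).append(term)
        elif ttype == "DOMAIN":
            table.domains.setdefault(acc, []).append(term)
        else:  # LOCATION: single primary label, last one wins with a warning
            if acc in table.location and table.location[acc] != term:
                logger.warning("%s: row %d: overriding location of %s", path.name, i, acc)
            table.location[acc] = term
    return table


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    rows = []
    for acc in sorted(table.accessions()):
        for ns, term in table.go.get(acc, []):
            rows.append((acc, f"GO:{ns}", term))
        for term in table.kegg.get(acc, []):
            rows.append((acc, "KEGG", term))
        for term in table.domains.get(acc, []):
            rows.append((acc, "DOMAIN", term))
        if acc in table.location:
            rows.append((acc, "LOCATION", table.location[acc]))
    pd.DataFrame(rows, columns=["accession", "term_type", "term"]).to_csv(
        path, sep="\t", index=False)
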