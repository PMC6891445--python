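"""DNA sequence and alignment primitives.

Sequences are plain upper-case strings over the IUPAC nucleotide alphabet
(``ACGT`` plus ambiguity codes and the gap character ``-``).  Coordinates are
0-based, half-open, and refer to the stored (``+``) orientation throughout
the package.

FASTA headers follow the dialect ``id|species|locus``; missing fields default
to ``"unknown"``.  Pairwise global alignment (used to re-identify market
samples against the reference panel) is affine-gap Needleman-Wunsch, delegated
to :class:`Bio.Align.PairwiseAligner`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align

from .errors import AmomarkerError, DataError, FastaParseError

GAP = "-"

#: IUPAC nucleotide codes mapped to the base sets they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS) | {GAP}

#: Reverse lookup: base set -> ambiguity code (e.g. {C,T} -> Y).
AMBIGUITY_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N", GAP: GAP,
}


@dataclass
class SeqRecord:
    """A labelled DNA sequence.

    ``species`` may be ``"unknown"``; ``locus`` is one of the five barcode
    loci or ``"query"`` for monitoring samples.  ``declared_name`` is the
    label under which a market sample was sold (monitoring only).
    """

    id: str
    seq: str
    species: str = "unknown"
    locus: str = "unknown"
    declared_name: str | None = None

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("U", "T")
        bad = set(seq) - IUPAC_ALPHABET
        if not seq:
            raise DataError(f"record {self.id!r}: empty sequence")
        if bad:
            raise DataError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        self.seq = seq

    def __len__(self) -> int:
        return len(self.seq)

    def degapped(self) -> "SeqRecord":
        """Copy of this record with all gap characters removed."""
        return replace(self, seq=self.seq.replace(GAP, ""))

    @property
    def ungapped_length(self) -> int:
        return len(self.seq) - self.seq.count(GAP)


@dataclass
class LocusAlignment:
    """A multiple sequence alignment of one barcode locus."""

    locus: str
    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise DataError(f"alignment {self.locus!r}: needs >= 2 records")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise DataError(
                f"alignment {self.locus!r}: unequal record lengths {sorted(lengths)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"alignment {self.locus!r}: duplicate ids {dupes}")

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, i: int) -> list[str]:
        return [r.seq[i] for r in self.records]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, species: Iterable[str] | None = None,
               ids: Iterable[str] | None = None) -> "LocusAlignment":
        """Alignment restricted to the given species and/or record ids."""
        sp = set(species) if species is not None else None
        keep_ids = set(ids) if ids is not None else None
        recs = [r for r in self.records
                if (sp is None or r.species in sp)
                and (keep_ids is None or r.id in keep_ids)]
        return LocusAlignment(self.locus, recs)


def parse_header(header: str) -> tuple[str, str, str]:
    """Split an ``id|species|locus`` header; missing fields -> "unknown"."""
    parts = header.split("|")
    rec_id = parts[0].strip()
    species = parts[1].strip() if len(parts) > 1 and parts[1].strip() else "unknown"
    locus = parts[2].strip() if len(parts) > 2 and parts[2].strip() else "unknown"
    return rec_id, species, locus


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read records from a FASTA file, normalising case and mapping U to T.

    The gap character ``-`` is accepted (aligned FASTA); ``.`` is rejected.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}:{header_line}: record {header!r} has no sequence"
            )
        rec_id, species, locus = parse_header(header)
        try:
            records.append(SeqRecord(rec_id, seq, species=species, locus=locus))
        except AmomarkerError as exc:
            raise FastaParseError(f"{path}:{header_line}: {exc}") from exc
        header, chunks = None, []

    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                header_line = line_no
                if not header:
                    raise FastaParseError(f"{path}:{line_no}: empty FASTA header")
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{line_no}: sequence data before first header"
                    )
                chunks.append(line)
    flush(line_no=header_line)
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records with ``id|species|locus`` headers, wrapped to `width`."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}|{rec.species}|{rec.locus}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement; gaps are preserved in place."""
    if not seq:
        raise DataError("cannot reverse-complement an empty sequence")
    seq = seq.upper().replace("U", "T")
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise DataError(f"non-IUPAC character {exc.args[0]!r}") from None


def iupac_match(a: str, b: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect.

    The gap character matches only another gap: an indel is never a
    "compatible" residue.
    """
    if a == GAP or b == GAP:
        return a == b
    try:
        return bool(IUPAC_SETS[a] & IUPAC_SETS[b])
    except KeyError:
        raise DataError(f"non-IUPAC characters {a!r}/{b!r}") from None


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring for global alignment.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class GlobalAlignment:
    a_aligned: str
    b_aligned: str
    score: float
    identity: float


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def aligned_identity(a_aligned: str, b_aligned: str) -> float:
    """Fraction of matching columns among columns where neither row is a gap."""
    comparable = 0
    matches = 0
    for x, y in zip(a_aligned, b_aligned):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if iupac_match(x, y):
            matches += 1
    if comparable == 0:
        raise DataError("alignment has no comparable (gap-free) columns")
    return matches / comparable


def global_align(a: str, b: str,
                 scoring: AlignmentScoring | None = None) -> GlobalAlignment:
    """Optimal global alignment of two ungapped sequences.

    Returns one optimal alignment (deterministic for fixed inputs) together
    with its score and the identity fraction over gap-free columns.
    """
    if not a or not b:
        raise DataError("global_align requires two non-empty sequences")
    if GAP in a or GAP in b:
        raise DataError("global_align inputs must be ungapped")
    scoring = scoring or AlignmentScoring()
    aligner = _aligner(scoring)
    result = aligner.align(a.upper(), b.upper())
    best = result[0]
    a_aln, b_aln = str(best[0]), str(best[1])
    return GlobalAlignment(a_aln, b_aln, float(best.score),
                           aligned_identity(a_aln, b_aln))


def align_score(a: str, b: str, scoring: AlignmentScoring | None = None) -> float:
    """Optimal global alignment score only (no traceback)."""
    scoring = scoring or AlignmentScoring()
    return float(_aligner(scoring).score(a.upper(), b.upper()))
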