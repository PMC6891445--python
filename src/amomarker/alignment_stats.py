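"""Site classification, pairwise identity matrices, and locus concatenation.

Site classes follow the conventions of standard barcode-survey summary
tables: a column is *excluded* when fewer than two unambiguous residues
(A/C/G/T) remain after treating gaps and ambiguity codes as missing data;
otherwise it is *conserved* (one state), *parsimony-informative* (at least
two states, each carried by at least two sequences), or a *singleton*
(variable but not parsimony-informative).

The identity convention is declared and isolated here: a gap aligned to a
residue counts as a mismatch, a gap-gap column is excluded from the
denominator, and overlapping IUPAC ambiguity codes count as a match.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .seq_core import GAP, IUPAC_SETS, LocusAlignment, SeqRecord

_UNAMBIGUOUS = frozenset("ACGT")

CONSERVED = "conserved"
VARIABLE_PI = "variable_pi"
VARIABLE_SINGLETON = "variable_singleton"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class AlignmentProfile:
    """Per-locus site-class counts.

    Invariants: ``conserved + variable + excluded == aligned_length`` and
    ``variable == parsimony_informative + singleton``.
    """

    locus: str
    aligned_length: int
    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int
    excluded: int

    def __post_init__(self) -> None:
        if self.conserved + self.variable + self.excluded != self.aligned_length:
            raise DataError(f"profile {self.locus!r}: site classes do not sum")
        if self.variable != self.parsimony_informative + self.singleton:
            raise DataError(f"profile {self.locus!r}: variable != PI + singleton")


@dataclass
class IdentityMatrix:
    """Symmetric pairwise identity fractions with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def pair(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


def classify_site(column: list[str]) -> str:
    """Classify one alignment column; gaps/ambiguity codes are missing data."""
    residues = [c for c in column if c in _UNAMBIGUOUS]
    if len(residues) < 2:
        return EXCLUDED
    counts = Counter(residues)
    if len(counts) == 1:
        return CONSERVED
    if sum(1 for n in counts.values() if n >= 2) >= 2:
        return VARIABLE_PI
    return VARIABLE_SINGLETON


def profile_alignment(aln: LocusAlignment) -> AlignmentProfile:
    """Column-wise site classification of one alignment."""
    tallies = Counter(classify_site(aln.column(i)) for i in range(aln.length))
    pi = tallies[VARIABLE_PI]
    singleton = tallies[VARIABLE_SINGLETON]
    return AlignmentProfile(
        locus=aln.locus,
        aligned_length=aln.length,
        conserved=tallies[CONSERVED],
        variable=pi + singleton,
        parsimony_informative=pi,
        singleton=singleton,
        excluded=tallies[EXCLUDED],
    )


def profiles_to_table(profiles: list[AlignmentProfile]) -> pd.DataFrame:
    """Summary table in the usual barcode-survey column order."""
    return pd.DataFrame(
        {
            "Barcode Target": [p.locus for p in profiles],
            "Aligned Length (Bases)": [p.aligned_length for p in profiles],
            "Conserved Sites": [p.conserved for p in profiles],
            "Variable Sites": [p.variable for p in profiles],
            "Parsimony Informative Sites": [p.parsimony_informative for p in profiles],
            "Singleton Sites": [p.singleton for p in profiles],
        }
    )


# Pairwise-identity lookup tables, indexed by character ordinal.
_ORD = 128
_MATCH_TABLE = np.zeros((_ORD, _ORD), dtype=bool)
_COMPARABLE_TABLE = np.zeros((_ORD, _ORD), dtype=bool)
for _a in list(IUPAC_SETS) + [GAP]:
    for _b in list(IUPAC_SETS) + [GAP]:
        if _a == GAP and _b == GAP:
            continue  # gap-gap columns drop out of the denominator
        _COMPARABLE_TABLE[ord(_a), ord(_b)] = True
        if _a != GAP and _b != GAP and (IUPAC_SETS[_a] & IUPAC_SETS[_b]):
            _MATCH_TABLE[ord(_a), ord(_b)] = True


def pairwise_identity(a: str, b: str) -> float:
    """Identity of two equal-length aligned rows under the declared convention."""
    if len(a) != len(b):
        raise DataError("aligned rows differ in length")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    comparable = _COMPARABLE_TABLE[xa, xb]
    n = int(comparable.sum())
    if n == 0:
        raise DataError("pair has zero comparable columns")
    return float(_MATCH_TABLE[xa, xb].sum() / n)


def identity_matrix(aln: LocusAlignment) -> IdentityMatrix:
    """All-vs-all identity fractions for one alignment."""
    n = len(aln.records)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                ident = pairwise_identity(aln.records[i].seq, aln.records[j].seq)
            except DataError as exc:
                raise DataError(
                    f"pair {aln.records[i].id}/{aln.records[j].id}: {exc}"
                ) from exc
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(ids=aln.ids(), values=values)


def concatenate(alns: list[LocusAlignment],
                locus: str | None = None) -> LocusAlignment:
    """Append alignments column-wise; all must share the same id set."""
    if not alns:
        raise DataError("concatenate: empty alignment list")
    if len(alns) == 1:
        return alns[0]
    base_ids = set(alns[0].ids())
    for aln in alns[1:]:
        missing = base_ids.symmetric_difference(aln.ids())
        if missing:
            raise DataError(
                f"concatenate: id sets differ (locus {aln.locus!r}), "
                f"unmatched ids {sorted(missing)}"
            )
    order = alns[0].ids()
    by_id = [{r.id: r for r in aln.records} for aln in alns]
    records = []
    template = {r.id: r for r in alns[0].records}
    for rec_id in order:
        seq = "".join(m[rec_id].seq for m in by_id)
        proto = template[rec_id]
        records.append(SeqRecord(rec_id, seq, species=proto.species,
                                 locus=locus or "concatenated"))
    return LocusAlignment(locus or "+".join(a.locus for a in alns), records)
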