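"""Species-diagnostic SNP discovery and allele-specific multiplex design.

The marker logic mirrors how allele-specific identification panels for
herbal crude drugs are built in practice:

* scan a labelled alignment for columns at which each target species is
  internally fixed and at least two species-level alleles exist
  (*diagnostic SNPs*);
* anchor a species primer so that its 3'-terminal base sits exactly on a
  diagnostic allele — a single 3' mismatch blocks extension in every
  non-target species;
* place a universal internal-standard pair inside a block that is conserved
  across the whole panel, so its product doubles as a PCR-success control;
* multiplex the primers only if the expected products are separable on a
  gel (pairwise size gap), the oligos cannot form 3' dimers, and their
  melting temperatures are compatible with one annealing step.

Melting temperatures use the unified nearest-neighbor thermodynamic
parameter set at 50 mM monovalent salt and 0.5 uM total oligonucleotide.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import DataError, DesignError, PanelAssemblyError
from .seq_core import (AMBIGUITY_CODE, GAP, LocusAlignment, iupac_match,
                       reverse_complement)

FIXED_INTERSPECIFIC = "fixed_interspecific"
INTRASPECIFIC = "intraspecific"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DiagnosticSNP:
    """One alignment column with per-species allele assignments.

    ``alleles`` maps species to an IUPAC base (``-`` for a fixed
    length-variant, an ambiguity code for a within-species polymorphism).
    ``discriminated_species`` names the single species whose allele differs
    from all others, when such a species exists.
    """

    locus: str
    column: int
    alleles: dict[str, str]
    kind: str
    discriminated_species: str | None = None


def _species_states(column: list[str], members: list[int]) -> Counter:
    """States (A/C/G/T/-) of one species in one column; ambiguity = missing."""
    states: Counter = Counter()
    for i in members:
        c = column[i]
        if c in _BASES or c == GAP:
            states[c] += 1
    return states


def find_diagnostic_snps(aln: LocusAlignment,
                         ingroup: Iterable[str]) -> list[DiagnosticSNP]:
    """Diagnostic columns among the in-group species of a labelled alignment.

    Fixed interspecific columns require every species to be internally
    uniform (a shared gap counts as a fixed length-variant allele).
    Within-species polymorphisms are reported only when supported: the
    minor allele must occur in at least two records, or the species must
    have no more than two records (two accessioned sequences that disagree
    cannot be dismissed as noise).  Isolated single-record variants, which
    in practice are indistinguishable from amplification error, are left
    out of the diagnostic set.
    """
    ingroup = list(dict.fromkeys(ingroup))
    members: dict[str, list[int]] = {sp: [] for sp in ingroup}
    for idx, rec in enumerate(aln.records):
        if rec.species in members:
            members[rec.species].append(idx)
    absent = [sp for sp, rows in members.items() if not rows]
    if absent:
        raise DataError(f"in-group species missing from alignment: {absent}")

    snps: list[DiagnosticSNP] = []
    for col in range(aln.length):
        column = aln.column(col)
        per_species = {sp: _species_states(column, rows)
                       for sp, rows in members.items()}
        if any(not states for states in per_species.values()):
            continue  # a species with no unambiguous observation

        if all(len(states) == 1 for states in per_species.values()):
            alleles = {sp: next(iter(states))
                       for sp, states in per_species.items()}
            if len(set(alleles.values())) < 2:
                continue
            snps.append(DiagnosticSNP(
                locus=aln.locus, column=col, alleles=alleles,
                kind=FIXED_INTERSPECIFIC,
                discriminated_species=_lone_species(alleles),
            ))
            continue

        # Candidate within-species polymorphism: apply the support rule.
        supported = False
        noisy = False
        alleles: dict[str, str] = {}
        for sp, states in per_species.items():
            base_states = {s: n for s, n in states.items() if s in _BASES}
            if GAP in states and base_states:
                noisy = True  # mixed gap/base within a species: skip column
                break
            if len(base_states) >= 2:
                minor = sorted(base_states.values())[-2]
                if minor >= 2 or len(members[sp]) <= 2:
                    supported = True
                    alleles[sp] = AMBIGUITY_CODE[frozenset(base_states)]
                else:
                    noisy = True
                    break
            else:
                alleles[sp] = next(iter(base_states))
        if supported and not noisy:
            snps.append(DiagnosticSNP(
                locus=aln.locus, column=col, alleles=alleles,
                kind=INTRASPECIFIC,
            ))
    return snps


def _lone_species(alleles: dict[str, str]) -> str | None:
    """The single species whose allele differs from all others, if any."""
    by_allele: dict[str, list[str]] = {}
    for sp, allele in alleles.items():
        by_allele.setdefault(allele, []).append(sp)
    singles = [sps[0] for sps in by_allele.values() if len(sps) == 1]
    if len(singles) == 1 and len(by_allele) == 2:
        return singles[0]
    return None


# --- Melting temperature ---------------------------------------------------

# Unified nearest-neighbor parameters: delta-H (kcal/mol), delta-S (cal/mol/K).
_NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)   # per terminal G or C
_INIT_AT = (2.3, 4.1)    # per terminal A or T
_R = 1.987  # gas constant, cal/mol/K


def primer_tm(seq: str, na_mM: float = 50.0, dnac1_nM: float = 250.0,
              dnac2_nM: float = 250.0) -> float:
    """Nearest-neighbor melting temperature in degrees Celsius.

    Unified duplex parameters with the entropic salt correction
    ``dS += 0.368 * (N - 1) * ln[Na+]``.  The effective strand
    concentration is ``dnac1 - dnac2/2`` for non-self-complementary
    duplexes (excess-strand convention) and ``dnac1`` with the symmetry
    entropy penalty for self-complementary ones.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise DataError("primer_tm requires length >= 8")
    if set(seq) - _BASES:
        raise DataError(f"primer_tm: ambiguous/gap characters in {seq!r}")
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        h, s = _NN_PARAMS[seq[i:i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    if seq == reverse_complement(seq):
        ds += -1.4
        ct_eff = dnac1_nM * 1e-9
    else:
        ct_eff = (dnac1_nM - dnac2_nM / 2.0) * 1e-9
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    tm_k = (dh * 1000.0) / (ds + _R * math.log(ct_eff))
    return tm_k - 273.15


# --- Primer and panel types ------------------------------------------------

@dataclass(frozen=True)
class Primer:
    """An oriented oligo, optionally anchored on a diagnostic column.

    ``anchor_column`` is the alignment column carrying the 3'-terminal
    (allele-specific) base; ``None`` for internal-standard primers.
    ``footprint`` is the half-open column interval of the binding site on
    the panel consensus (stored orientation), when known.
    ``target_species`` is empty for universal primers.
    """

    name: str
    seq: str
    orientation: str  # "forward" | "reverse"
    locus: str
    tm_c: float
    anchor_column: int | None = None
    target_species: frozenset[str] = frozenset()
    footprint: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise DataError(f"primer {self.name!r}: bad orientation")
        if not (8 <= len(self.seq) <= 40):
            raise DataError(f"primer {self.name!r}: implausible length")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class MultiplexPanel:
    """A set of primers with gel-separable expected products.

    ``expected_products`` maps a species-group label (or ``"universal"``
    for the internal standard) to the amplicon size in bases, inclusive of
    both primer footprints.
    """

    primers: list[Primer]
    expected_products: dict[str, int]
    size_resolution: int = 50
    locus: str = "ITS"

    def primer(self, name: str) -> Primer:
        for p in self.primers:
            if p.name == name:
                return p
        raise DataError(f"panel has no primer {name!r}")

    @property
    def universal_size(self) -> int:
        return self.expected_products["universal"]

    def species_products(self) -> dict[str, int]:
        return {k: v for k, v in self.expected_products.items()
                if k != "universal"}


@dataclass(frozen=True)
class PrimerConstraints:
    """Tunable design constraints; defaults suit a single-step multiplex."""

    min_len: int = 18
    max_len: int = 26
    tm_min: float = 55.0
    tm_max: float = 65.0
    tm_opt: float = 60.0
    product_min: int = 150
    product_max: int = 600
    is_product_size: int = 100
    max_tm_spread: float = 5.0


def choose_suffix_length(window: str,
                         constraints: PrimerConstraints) -> tuple[int, float]:
    """Primer length for a 3'-anchored oligo (candidates: window suffixes).

    Picks the length whose Tm lies inside the window and closest to
    ``tm_opt``; ties prefer the shorter oligo.
    """
    best: tuple[float, int, float] | None = None
    limit = min(constraints.max_len, len(window))
    for length in range(constraints.min_len, limit + 1):
        cand = window[-length:]
        if set(cand) - _BASES:
            continue
        tm = primer_tm(cand)
        if constraints.tm_min <= tm <= constraints.tm_max:
            key = (abs(tm - constraints.tm_opt), length, tm)
            if best is None or key < best:
                best = key
    if best is None:
        raise DesignError("no primer length satisfies the Tm window")
    return best[1], best[2]


def choose_prefix_length(window: str,
                         constraints: PrimerConstraints) -> tuple[int, float]:
    """Primer length for a 5'-anchored oligo (candidates: window prefixes)."""
    best: tuple[float, int, float] | None = None
    limit = min(constraints.max_len, len(window))
    for length in range(constraints.min_len, limit + 1):
        cand = window[:length]
        if set(cand) - _BASES:
            continue
        tm = primer_tm(cand)
        if constraints.tm_min <= tm <= constraints.tm_max:
            key = (abs(tm - constraints.tm_opt), length, tm)
            if best is None or key < best:
                best = key
    if best is None:
        raise DesignError("no primer length satisfies the Tm window")
    return best[1], best[2]


def product_size(aln: LocusAlignment, species: set[str] | None,
                 start_col: int, end_col: int) -> int:
    """Amplicon size in bases over a column span, on the degapped template.

    Uses the first record of ``species`` (or the first record overall) as
    the representative template; gap columns inside the span do not count
    toward the physical product length.
    """
    for rec in aln.records:
        if species is None or rec.species in species:
            return (end_col - start_col
                    - rec.seq[start_col:end_col].count(GAP))
    raise DataError(f"no records for species {sorted(species or [])}")


def _species_consensus_window(aln: LocusAlignment, species: set[str],
                              start: int, end: int) -> str | None:
    """Shared unambiguous residue string of ``species`` over [start, end).

    Returns None when the window leaves the alignment, contains a gap or
    ambiguity code, or shows a within-group disagreement (such windows are
    not manufacturable as a single oligo).
    """
    if start < 0 or end > aln.length:
        return None
    rows = [r.seq[start:end] for r in aln.records if r.species in species]
    if not rows:
        return None
    window = rows[0]
    if any(row != window for row in rows[1:]):
        return None
    if set(window) - _BASES:
        return None
    return window


def design_species_primer(aln: LocusAlignment, snps: list[DiagnosticSNP],
                          species: str,
                          constraints: PrimerConstraints | None = None,
                          target_species: Iterable[str] | None = None,
                          is_pair: tuple[Primer, Primer] | None = None,
                          name: str | None = None) -> Primer:
    """Design an allele-specific primer for one species (or species group).

    The primer is read from the target group's consensus and ends (3')
    exactly on a diagnostic allele at which **every** other record in the
    panel — congeners, adulterants, outgroups — carries a mismatching base.
    Orientation follows from the anchor's position relative to the
    internal-standard pair, so that the species product (species primer
    with the facing internal-standard primer) falls inside the allowed
    size range.  Candidate anchors are tried in column order.
    """
    constraints = constraints or PrimerConstraints()
    targets = set(target_species) if target_species else {species}
    if is_pair is None:
        is_pair = design_internal_standard(aln, constraints)
    isf, isr = is_pair
    f_start = isf.footprint[0]
    r_end = isr.footprint[1]

    target_rows = [r for r in aln.records if r.species in targets]
    if not target_rows:
        raise DataError(f"no records for target species {sorted(targets)}")
    others = [r for r in aln.records if r.species not in targets]

    candidates: list[DiagnosticSNP] = []
    for snp in sorted(snps, key=lambda s: s.column):
        if snp.kind != FIXED_INTERSPECIFIC:
            continue
        alleles = {snp.alleles.get(sp) for sp in targets if sp in snp.alleles}
        if len(alleles) != 1:
            continue
        allele = next(iter(alleles))
        if allele is None or allele not in _BASES:
            continue
        other_alleles = [a for sp, a in snp.alleles.items() if sp not in targets]
        if any(a == GAP or iupac_match(a, allele) for a in other_alleles):
            continue
        # The 3' terminus must mismatch every non-target panel record too.
        col = snp.column
        if any(r.seq[col] != GAP and iupac_match(r.seq[col], allele)
               for r in others):
            continue
        candidates.append(snp)
    if not candidates:
        raise DesignError(f"no discriminating SNP for species {species!r}")

    for snp in candidates:
        col = snp.column
        if col < f_start:
            orientation = "forward"
        elif col >= r_end:
            orientation = "reverse"
        else:
            continue  # anchor inside the internal-standard product
        max_len = constraints.max_len
        if orientation == "forward":
            window = _species_consensus_window(aln, targets,
                                               col - max_len + 1, col + 1)
            oriented = window
        else:
            window = _species_consensus_window(aln, targets, col, col + max_len)
            oriented = reverse_complement(window) if window else None
        if oriented is None:
            continue
        try:
            length, tm = choose_suffix_length(oriented, constraints)
        except DesignError:
            continue
        if orientation == "forward":
            footprint = (col - length + 1, col + 1)
            product = product_size(aln, targets, footprint[0], r_end)
        else:
            footprint = (col, col + length)
            product = product_size(aln, targets, f_start, footprint[1])
        if not (constraints.product_min <= product <= constraints.product_max):
            continue
        return Primer(name=name or _default_name(species, orientation),
                      seq=oriented[-length:], orientation=orientation,
                      locus=aln.locus, tm_c=tm, anchor_column=col,
                      target_species=frozenset(targets), footprint=footprint)
    raise DesignError(f"no feasible primer window for species {species!r}")


def _default_name(species: str, orientation: str) -> str:
    initials = "".join(w[0] for w in species.replace(".", " ").split()
                       if w).upper()[:3]
    return f"{initials}{'F' if orientation == 'forward' else 'R'}1"


def design_internal_standard(aln: LocusAlignment,
                             constraints: PrimerConstraints | None = None
                             ) -> tuple[Primer, Primer]:
    """Universal primer pair inside a panel-wide conserved block.

    Both footprints must lie entirely in columns at which every panel
    record carries the same unambiguous residue; the product size is fixed
    by ``constraints.is_product_size``.  The leftmost feasible placement in
    the leftmost sufficiently long conserved run is chosen, which makes the
    design deterministic.
    """
    constraints = constraints or PrimerConstraints()
    size = constraints.is_product_size
    consensus = aln.records[0].seq
    for run_start, run_end in _runs(_conserved_columns(aln)):
        if run_end - run_start < size:
            continue
        for f_start in range(run_start, run_end - size + 1):
            product_end = f_start + size
            try:
                f_len, f_tm = choose_prefix_length(
                    consensus[f_start:f_start + constraints.max_len],
                    constraints)
                r_len, r_tm = choose_suffix_length(
                    reverse_complement(
                        consensus[product_end - constraints.max_len:
                                  product_end]),
                    constraints)
            except DesignError:
                continue
            if f_start + f_len > product_end - r_len:
                continue  # footprints would overlap inside the product
            fwd = Primer(name="ISF", seq=consensus[f_start:f_start + f_len],
                         orientation="forward", locus=aln.locus, tm_c=f_tm,
                         footprint=(f_start, f_start + f_len))
            rev = Primer(name="ISR",
                         seq=reverse_complement(
                             consensus[product_end - r_len:product_end]),
                         orientation="reverse", locus=aln.locus, tm_c=r_tm,
                         footprint=(product_end - r_len, product_end))
            return fwd, rev
    raise DesignError("no conserved block long enough for an internal standard")


def _conserved_columns(aln: LocusAlignment) -> list[bool]:
    out = []
    for i in range(aln.length):
        column = aln.column(i)
        first = column[0]
        out.append(first in _BASES and all(c == first for c in column))
    return out


def _runs(mask: list[bool]) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def has_3prime_dimer(a: Primer, b: Primer, run: int = 4) -> bool:
    """True when the 3' terminus of ``a`` could anneal inside ``b``.

    Checks for a complementary run of at least ``run`` bases covering the
    3' end of ``a`` anywhere in ``b`` (both read 5'->3').
    """
    tail = a.seq[-run:]
    if len(tail) < run:
        return False
    return reverse_complement(tail) in b.seq


def assemble_multiplex_panel(species_primers: list[Primer],
                             is_pair: tuple[Primer, Primer],
                             aln: LocusAlignment,
                             size_resolution: int = 50,
                             constraints: PrimerConstraints | None = None
                             ) -> MultiplexPanel:
    """Validate and assemble species primers plus the internal standard.

    Expected product sizes are computed from consensus coordinates.  The
    panel is rejected on a product-size collision, a potential 3' primer
    dimer, or a melting-temperature spread incompatible with a single
    annealing temperature.
    """
    constraints = constraints or PrimerConstraints()
    isf, isr = is_pair
    if isf.footprint is None or isr.footprint is None:
        raise DataError("internal-standard primers lack footprints")
    f_start = isf.footprint[0]
    r_end = isr.footprint[1]

    expected: dict[str, int] = {
        "universal": product_size(aln, None, f_start, r_end)}
    for primer in species_primers:
        if primer.footprint is None:
            raise DataError(f"species primer {primer.name!r} lacks a footprint")
        targets = set(primer.target_species) or None
        if primer.orientation == "forward":
            size = product_size(aln, targets, primer.footprint[0], r_end)
        else:
            size = product_size(aln, targets, f_start, primer.footprint[1])
        expected[species_group_label(primer.target_species)] = size

    sizes = sorted(expected.items(), key=lambda kv: kv[1])
    for (la, sa), (lb, sb) in zip(sizes, sizes[1:]):
        if sb - sa < size_resolution:
            raise PanelAssemblyError(
                f"products {la!r} ({sa} b) and {lb!r} ({sb} b) differ by "
                f"less than {size_resolution} bases")

    primers = list(species_primers) + [isf, isr]
    for a in primers:
        for b in primers:
            if has_3prime_dimer(a, b):
                raise PanelAssemblyError(
                    f"3' dimer risk between {a.name!r} and {b.name!r}")
    tms = [p.tm_c for p in primers]
    if max(tms) - min(tms) > constraints.max_tm_spread:
        raise PanelAssemblyError(
            f"Tm spread {max(tms) - min(tms):.1f} C exceeds "
            f"{constraints.max_tm_spread} C")
    return MultiplexPanel(primers=primers, expected_products=expected,
                          size_resolution=size_resolution, locus=aln.locus)


def species_group_label(target_species: frozenset[str]) -> str:
    """Stable label for a species group (sorted, slash-joined)."""
    if not target_species:
        return "universal"
    return "/".join(sorted(target_species))


# --- Panel TSV round-trip --------------------------------------------------

def write_panel_tsv(panel: MultiplexPanel, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#locus\t{panel.locus}\n")
        fh.write(f"#size_resolution\t{panel.size_resolution}\n")
        for label, size in panel.expected_products.items():
            fh.write(f"#product\t{label}\t{size}\n")
        fh.write("name\tsequence\torientation\tanchor_column\ttm_c\t"
                 "target_species\n")
        for p in panel.primers:
            anchor = "" if p.anchor_column is None else str(p.anchor_column)
            fh.write(f"{p.name}\t{p.seq}\t{p.orientation}\t{anchor}\t"
                     f"{p.tm_c:.2f}\t{';'.join(sorted(p.target_species))}\n")


def read_panel_tsv(path: str | Path) -> MultiplexPanel:
    path = Path(path)
    locus = "ITS"
    size_resolution = 50
    expected: dict[str, int] = {}
    primers: list[Primer] = []
    header_seen = False
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts[0] == "locus":
                    locus = parts[1]
                elif parts[0] == "size_resolution":
                    size_resolution = int(parts[1])
                elif parts[0] == "product":
                    expected[parts[1]] = int(parts[2])
                continue
            if not header_seen:
                header_seen = True
                continue
            name, seq, orientation, anchor, tm_c, targets = line.split("\t")
            primers.append(Primer(
                name=name, seq=seq, orientation=orientation, locus=locus,
                tm_c=float(tm_c),
                anchor_column=int(anchor) if anchor else None,
                target_species=frozenset(t for t in targets.split(";") if t),
            ))
    if not primers or not expected:
        raise DataError(f"{path}: not a valid panel TSV")
    return MultiplexPanel(primers=primers, expected_products=expected,
                          size_resolution=size_resolution, locus=locus)
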