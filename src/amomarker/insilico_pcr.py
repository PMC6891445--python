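"""In-silico multiplex PCR: binding-site search, products, gel calls.

The amplification model is deliberately binary, matching a gel readout:
a primer binds where its sequence anneals with at most ``max_mismatch``
IUPAC-incompatible positions, *except* in the 3'-terminal ``anchor_len``
bases where no mismatch is tolerated (allele-specific extension blocking).
Any convergent forward/reverse site pair within ``max_product`` yields a
product whose size includes both primer footprints.

Band patterns are merged across records sharing one sample number — a gel
lane of a mixed template shows the superposition of both band sets.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AmbiguousBandError, DataError
from .marker_design import MultiplexPanel, Primer
from .seq_core import GAP, SeqRecord, iupac_match, reverse_complement


@dataclass(frozen=True)
class PCRRules:
    """Binding and product-calling rules."""

    max_mismatch: int = 2     # mismatches tolerated outside the 3' anchor
    anchor_len: int = 3       # 3'-terminal bases requiring perfect match
    max_product: int = 2000   # bases
    band_tolerance: float = 0.10  # fractional size bin for gel calls


@dataclass(frozen=True)
class BindingSite:
    """One primer binding site on the + strand of a template.

    ``strand`` "+" means the primer extends rightward (forward role);
    "-" means it anneals to the + strand and extends leftward.
    ``mismatches`` excludes the 3'-anchor window (which must be perfect).
    """

    primer: str
    template: str
    strand: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class PCRProduct:
    template: str
    forward: str
    reverse: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class BandPattern:
    """Observed band sizes for one gel lane (one sample number)."""

    sample: str
    sizes: list[int]
    tolerance: float = 0.10


@dataclass(frozen=True)
class SpeciesCall:
    sample: str
    verdict: str  # villosum_group | longiligulare | mixture | non_target | assay_failure
    evidence: tuple[int, ...]


VILLOSUM_GROUP = "villosum_group"
LONGILIGULARE = "longiligulare"
MIXTURE = "mixture"
NON_TARGET = "non_target"
ASSAY_FAILURE = "assay_failure"


def _scan(template: str, oligo: str, anchor_at_start: bool,
          rules: PCRRules) -> list[tuple[int, int]]:
    """Sliding-window scan returning (start, mismatches-outside-anchor).

    ``oligo`` is given in + strand orientation.  ``anchor_at_start`` marks
    the 3' anchor at the left end of the window (reverse-role primers).
    """
    n, m = len(template), len(oligo)
    hits = []
    if m > n:
        return hits
    anchor = rules.anchor_len
    for start in range(n - m + 1):
        window = template[start:start + m]
        if anchor_at_start:
            anchor_zone = range(0, min(anchor, m))
        else:
            anchor_zone = range(max(0, m - anchor), m)
        mism = 0
        ok = True
        anchor_set = set(anchor_zone)
        for i in range(m):
            if iupac_match(oligo[i], window[i]):
                continue
            if i in anchor_set:
                ok = False
                break
            mism += 1
            if mism > rules.max_mismatch:
                ok = False
                break
        if ok:
            hits.append((start, mism))
    return hits


def find_binding_sites(template: SeqRecord | str, primer: Primer,
                       rules: PCRRules | None = None) -> list[BindingSite]:
    """All binding sites of one primer on an ungapped template.

    Both roles are scanned: the primer sequence itself against the +
    strand (forward role, extends rightward) and its reverse complement
    (reverse role, extends leftward).  Sites are sorted by position.
    """
    rules = rules or PCRRules()
    if isinstance(template, SeqRecord):
        tid, seq = template.id, template.seq
    else:
        tid, seq = "template", template.upper()
    if GAP in seq:
        raise DataError("find_binding_sites requires an ungapped template")

    sites = []
    for start, mism in _scan(seq, primer.seq, anchor_at_start=False,
                             rules=rules):
        sites.append(BindingSite(primer.name, tid, "+", start,
                                 start + len(primer.seq), mism))
    rc = reverse_complement(primer.seq)
    for start, mism in _scan(seq, rc, anchor_at_start=True, rules=rules):
        sites.append(BindingSite(primer.name, tid, "-", start,
                                 start + len(primer.seq), mism))
    sites.sort(key=lambda s: (s.start, s.strand, s.primer))
    return sites


def simulate_pcr(template: SeqRecord, panel: MultiplexPanel,
                 rules: PCRRules | None = None) -> list[PCRProduct]:
    """Enumerate all products of a multiplex panel on one template.

    Every convergent pair (a forward-role site left of a reverse-role
    site, non-overlapping footprints) within ``max_product`` is reported;
    any primer may serve either role.
    """
    rules = rules or PCRRules()
    fwd_sites: list[BindingSite] = []
    rev_sites: list[BindingSite] = []
    for primer in panel.primers:
        for site in find_binding_sites(template, primer, rules):
            (fwd_sites if site.strand == "+" else rev_sites).append(site)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.start >= f.end and (r.end - f.start) <= rules.max_product:
                products.append(PCRProduct(
                    template=template.id, forward=f.primer, reverse=r.primer,
                    start=f.start, end=r.end))
    products.sort(key=lambda p: (p.start, p.end, p.forward, p.reverse))
    return products


def band_pattern(sample: str, product_lists: list[list[PCRProduct]],
                 rules: PCRRules | None = None) -> BandPattern:
    """Merge product sizes of one or more records into one gel lane."""
    rules = rules or PCRRules()
    sizes = sorted({p.size for products in product_lists for p in products})
    return BandPattern(sample=sample, sizes=sizes,
                       tolerance=rules.band_tolerance)


def call_species(pattern: BandPattern, panel: MultiplexPanel) -> SpeciesCall:
    """Interpret a band pattern against the panel's expected products.

    No internal-standard band means the assay failed; the internal
    standard alone means a non-target species; one species band on top of
    the standard identifies that group; both species bands mean a mixture.
    """
    matched: dict[str, int] = {}
    for size in pattern.sizes:
        labels = [label for label, expected in panel.expected_products.items()
                  if abs(size - expected) <= pattern.tolerance * expected]
        if len(labels) > 1:
            raise AmbiguousBandError(
                f"band {size} b matches {sorted(labels)}; "
                "size tolerance too loose for this panel")
        if labels:
            matched[labels[0]] = size

    evidence = tuple(sorted(matched.values()))
    if "universal" not in matched:
        return SpeciesCall(pattern.sample, ASSAY_FAILURE, evidence)
    species_hits = [label for label in matched if label != "universal"]
    if not species_hits:
        return SpeciesCall(pattern.sample, NON_TARGET, evidence)
    if len(species_hits) > 1:
        return SpeciesCall(pattern.sample, MIXTURE, evidence)
    return SpeciesCall(pattern.sample, _verdict_for(species_hits[0]), evidence)


def _verdict_for(label: str) -> str:
    """Map a species-group product label to a gel verdict."""
    if "longiligulare" in label and "villosum" not in label:
        return LONGILIGULARE
    if "villosum" in label:
        return VILLOSUM_GROUP
    return label
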