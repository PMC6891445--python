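"""Seeded synthetic reference and monitoring panels for Amomi Fructus.

Real voucher sequences are not bundled; this generator is the test
substrate for the whole pipeline.  It emulates a five-locus barcode survey
of the three genuine Amomi Fructus species — *Amomum villosum* (18
samples), *A. villosum* var. *xanthioides* (2), and *A. longiligulare*
(5) — plus eleven morphologically confusable adulterant species from
*Amomum*, *Alpinia*, and *Elettaria*, and two distant outgroups for
rooting trees.

The in-group polymorphism structure is *planted*, not emergent: 19
diagnostic positions in ITS, 1 in matK, 4 in rbcL, 1 in rpoB, and 7 in
trnL-F (32 in total), with the documented patterns (the single matK and
rbcL differences separate *A. longiligulare*; the single rpoB difference
separates var. *xanthioides*; trnL-F carries two intraspecific positions
within var. *xanthioides*).  Every planted position is logged, which gives
downstream SNP discovery an exact truth set.

The ITS region carries a fixed architecture: a conserved 5.8S block
(identical in every species, hosting the universal internal-standard
sites) flanked by ITS1 and ITS2, with the allele-specific marker sites
placed so that the species amplicons are 270 bases (*A. villosum* group)
and 350 bases (*A. longiligulare*) against a 100-base internal standard.
Low-rate intraspecific noise (single-record substitutions in *A.
villosum* ITS) and species-specific indels provide the length variation
seen across real panels while never touching primer windows or planted
diagnostic columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .alignment_stats import pairwise_identity
from .marker_design import (PrimerConstraints, choose_prefix_length,
                            choose_suffix_length)
from .seq_core import (GAP, LocusAlignment, SeqRecord, reverse_complement,
                       write_fasta)

A_VILLOSUM = "Amomum villosum"
A_XANTHIOIDES = "Amomum villosum var. xanthioides"
A_LONGILIGULARE = "Amomum longiligulare"
INGROUP_SPECIES = (A_VILLOSUM, A_XANTHIOIDES, A_LONGILIGULARE)
VILLOSUM_GROUP = frozenset({A_VILLOSUM, A_XANTHIOIDES})

LOCI = ("ITS", "matK", "rbcL", "rpoB", "trnLF")

# Published allele-specific marker oligos used as fixed ITS site sequences.
AVF1_SEQ = "TGGATGATTGTGAACGTGTCAACA"
ALF1_SEQ = "AGGGTCTCTTTGAGGACACATCCCG"
AVF1_WINDOW = "CT" + AVF1_SEQ    # 26-mer, 3' end on the anchor column
ALF1_WINDOW = "A" + ALF1_SEQ     # 26-mer in primer orientation

# Fixed 160-base conserved block standing in for the 5.8S rRNA gene.
FIVE8S = (
    "GCTAAGGGCGGAGTGCTCGGTTACTTCCACGGACATTTCACCGCGCTGTCGGCAACAAGA"
    "CACCCTCTAATCTAATATTGACAATACCTAACTGTACTACGAGGCAGGTATGCGTCGCCA"
    "GTCCCAATCAGTCCCCATCATTCTCATTATAAGCTGACCA"
)

# ITS architecture in ungapped in-group coordinates (length 652).
ITS_LEN_U = 652
ITS1_SPAN_U = (0, 230)
S58_SPAN_U = (230, 390)
ITS2_SPAN_U = (390, 652)
ITS_DEL_ZONE_U = (120, 145)     # adulterant deletions confined here
ITS_GUARDS_U = (229, 390)       # variability guards pinning the 5.8S run
ITS_INS_BLOCKS = ((150, 10), (600, 8))   # (ungapped position, width)
ITS_ALIGNED_LEN = ITS_LEN_U + sum(w for _, w in ITS_INS_BLOCKS)

TRNLF_LEN_U = 408
TRNLF_DEL_ZONE_U = (350, 390)
TRNLF_XANTH_DEL_U = 50          # the fixed length variant in xanthioides
TRNLF_INS_BLOCKS = ((100, 6), (200, 2), (300, 6))
TRNLF_ALIGNED_LEN = TRNLF_LEN_U + sum(w for _, w in TRNLF_INS_BLOCKS)

PLASTID_LENGTHS = {"matK": 933, "rbcL": 743, "rpoB": 516}

#: Positions per locus where the three genuine species share a derived
#: base against every adulterant and outgroup.  These model the lineage
#: signal uniting congeners: without them the panel degenerates into a
#: star radiating from the consensus and the in-group has no true
#: internal edge for neighbor joining to recover.  Uniform within the
#: in-group, they are invisible to in-group SNP discovery.
INGROUP_SHARED = {"ITS": 8, "matK": 8, "rbcL": 6, "rpoB": 4, "trnLF": 4}

_ALT = {"A": "C", "C": "A", "G": "T", "T": "G"}
_BASES = "ACGT"


@dataclass(frozen=True)
class AdulterantSpec:
    """One adulterant (or outgroup) species with per-locus divergence.

    Divergences are substitution fractions relative to the in-group
    consensus; ITS values are chosen so the identity ordering of a real
    panel is reproduced (congeners closest, outgroups farthest).  ``fill``
    names the shared insertion block the species carries, ``deletion`` the
    length of its deletion run inside the fixed deletion zone.
    """

    name: str
    code: str
    n: int
    its: float
    trnlf: float
    matk: float = 0.02
    rbcl: float = 0.015
    rpob: float = 0.012
    its_fill: int | None = None      # index into ITS_INS_BLOCKS
    its_deletion: int = 0
    trnlf_fill: int | None = None    # index into TRNLF_INS_BLOCKS
    trnlf_deletion: int = 0
    outgroup: bool = False


DEFAULT_ADULTERANTS: tuple[AdulterantSpec, ...] = (
    AdulterantSpec("Amomum verum", "AK", 4, 0.08, 0.04,
                   its_fill=0, trnlf_fill=0),
    AdulterantSpec("Amomum compactum", "AC", 4, 0.09, 0.05,
                   its_fill=0, its_deletion=4, trnlf_fill=0, trnlf_deletion=3),
    AdulterantSpec("Amomum tsao-ko", "ATK", 4, 0.10, 0.06, rbcl=0.10,
                   its_fill=0, its_deletion=6, trnlf_fill=0, trnlf_deletion=5),
    AdulterantSpec("Alpinia hainanensis", "AH", 4, 0.11, 0.05,
                   its_fill=1, trnlf_fill=2, trnlf_deletion=1),
    AdulterantSpec("Alpinia oxyphylla", "AO", 4, 0.12, 0.06,
                   its_fill=1, its_deletion=5, trnlf_fill=2, trnlf_deletion=6),
    AdulterantSpec("Alpinia officinarum", "AOR", 4, 0.13, 0.04,
                   its_deletion=2, trnlf_deletion=4),
    AdulterantSpec("Alpinia conchigera", "ACC", 2, 0.14, 0.07,
                   trnlf_deletion=8),
    AdulterantSpec("Alpinia zerumbet", "AZ", 2, 0.15, 0.08,
                   its_deletion=6, trnlf_deletion=11),
    AdulterantSpec("Alpinia malaccensis", "AM", 1, 0.16, 0.09,
                   its_deletion=3, trnlf_fill=1, trnlf_deletion=13),
    AdulterantSpec("Alpinia galanga", "AG", 1, 0.13, 0.10,
                   its_deletion=5, trnlf_deletion=13),
    AdulterantSpec("Elettaria cardamomum", "EC", 2, 0.12, 0.03,
                   its_deletion=1, trnlf_deletion=9),
)

DEFAULT_OUTGROUPS: tuple[AdulterantSpec, ...] = (
    AdulterantSpec("Brassica rapa", "BRA", 1, 0.30, 0.20,
                   matk=0.12, rbcl=0.12, rpob=0.12,
                   its_fill=0, trnlf_fill=0, outgroup=True),
    AdulterantSpec("Oryza sativa", "ORY", 1, 0.30, 0.20,
                   matk=0.12, rbcl=0.12, rpob=0.12,
                   its_fill=1, its_deletion=2, trnlf_fill=2,
                   trnlf_deletion=2, outgroup=True),
)


@dataclass
class PanelConfig:
    """Study conditions for the synthetic panel."""

    seed: int = 42
    n_villosum: int = 18
    n_xanthioides: int = 2
    n_longiligulare: int = 5
    adulterants: tuple[AdulterantSpec, ...] = DEFAULT_ADULTERANTS
    include_outgroups: bool = True
    intraspecific_rate: float = 0.002   # per-site noise, A. villosum ITS only
    query_noise_rate: float = 0.002     # per-site noise on monitoring queries
    unknown_divergence: float = 0.12    # the off-panel adulterant species
    unknown_threshold: float = 0.95
    # Planted diagnostic counts (in-group): must total 32 across loci.
    its_snps: int = 19
    matk_snps: int = 1
    rbcl_snps: int = 4
    rpob_snps: int = 1
    trnlf_snps: int = 7
    constraints: PrimerConstraints = field(default_factory=PrimerConstraints)

    def __post_init__(self) -> None:
        total = (self.its_snps + self.matk_snps + self.rbcl_snps
                 + self.rpob_snps + self.trnlf_snps)
        if total != 32:
            raise ConfigError(f"planted SNP counts sum to {total}, expected 32")
        if self.n_xanthioides < 2:
            raise ConfigError("need >= 2 xanthioides records for "
                              "intraspecific trnL-F variation")
        for bad in [s for s in self.adulterants if not 0 < s.its < 1]:
            raise ConfigError(f"adulterant {bad.name!r}: bad ITS divergence")

    @property
    def species_specs(self) -> tuple[AdulterantSpec, ...]:
        extra = DEFAULT_OUTGROUPS if self.include_outgroups else ()
        return tuple(self.adulterants) + tuple(extra)


@dataclass(frozen=True)
class ItsGeometry:
    """Marker-site architecture of the synthetic ITS, both in ungapped
    in-group coordinates (``*_u``) and alignment columns."""

    its1_span: tuple[int, int]
    fivep8S_span: tuple[int, int]
    its2_span: tuple[int, int]
    avf1_site_u: tuple[int, int]
    isf_site_u: tuple[int, int]
    isr_site_u: tuple[int, int]
    alf1_site_u: tuple[int, int]
    avf1_anchor_u: int
    alf1_anchor_u: int
    avf1_anchor_col: int
    alf1_anchor_col: int
    fivep8S_cols: tuple[int, int]

    def check(self) -> None:
        """Inclusive 5'-to-5' distances realised by the site placement."""
        av_5p = self.avf1_site_u[0]
        isf_5p = self.isf_site_u[0]
        isr_5p = self.isr_site_u[1] - 1
        alf_5p = self.alf1_site_u[1] - 1
        if isr_5p - av_5p + 1 != 270:
            raise ConfigError("AVF1..ISR span is not 270 bases")
        if isr_5p - isf_5p + 1 != 100:
            raise ConfigError("ISF..ISR span is not 100 bases")
        if alf_5p - isf_5p + 1 != 350:
            raise ConfigError("ISF..ALF1 span is not 350 bases")


def _its_col(u: int) -> int:
    col = u
    for pos, width in ITS_INS_BLOCKS:
        if u >= pos:
            col += width
    return col


def _trnlf_col(u: int) -> int:
    col = u
    for pos, width in TRNLF_INS_BLOCKS:
        if u >= pos:
            col += width
    return col


def compute_its_geometry(constraints: PrimerConstraints | None = None
                         ) -> ItsGeometry:
    """Derive the marker-site placement from the fixed site sequences.

    The internal-standard pair is placed exactly as the deterministic
    designer would place it (leftmost feasible offset in the conserved
    block); the species anchors are then positioned so the amplicons come
    out at 270 and 350 bases.
    """
    c = constraints or PrimerConstraints()
    size = c.is_product_size
    placement = None
    for off in range(0, len(FIVE8S) - size + 1):
        try:
            f_len, _ = choose_prefix_length(FIVE8S[off:off + c.max_len], c)
            r_len, _ = choose_suffix_length(
                reverse_complement(FIVE8S[off + size - c.max_len:off + size]),
                c)
        except Exception:
            continue
        if off + f_len <= off + size - r_len:
            placement = (off, f_len, r_len)
            break
    if placement is None:
        raise ConfigError("conserved block cannot host an internal standard")
    off, f_len, r_len = placement
    s58 = S58_SPAN_U[0]
    isf_u = (s58 + off, s58 + off + f_len)
    isr_u = (s58 + off + size - r_len, s58 + off + size)
    r_end_u = isr_u[1]
    f_start_u = isf_u[0]

    lv, _ = choose_suffix_length(AVF1_WINDOW, c)
    ll, _ = choose_suffix_length(ALF1_WINDOW, c)
    a_v = r_end_u - 271 + lv           # forward anchor: product of 270
    a_l = f_start_u + 350 - ll         # reverse anchor: product of 350
    avf1_site = (a_v - lv + 1, a_v + 1)
    alf1_site = (a_l, a_l + ll)
    if not (ITS1_SPAN_U[0] <= avf1_site[0] and avf1_site[1] <= ITS1_SPAN_U[1]):
        raise ConfigError("AVF1 site falls outside ITS1")
    if not (ITS2_SPAN_U[0] <= alf1_site[0] and alf1_site[1] <= ITS2_SPAN_U[1]):
        raise ConfigError("ALF1 site falls outside ITS2")
    geometry = ItsGeometry(
        its1_span=ITS1_SPAN_U, fivep8S_span=S58_SPAN_U, its2_span=ITS2_SPAN_U,
        avf1_site_u=avf1_site, isf_site_u=isf_u, isr_site_u=isr_u,
        alf1_site_u=alf1_site, avf1_anchor_u=a_v, alf1_anchor_u=a_l,
        avf1_anchor_col=_its_col(a_v), alf1_anchor_col=_its_col(a_l),
        fivep8S_cols=(_its_col(S58_SPAN_U[0]), _its_col(S58_SPAN_U[1] - 1) + 1),
    )
    geometry.check()
    return geometry


@dataclass
class ReferencePanel:
    """Generated five-locus panel plus the planted-truth log."""

    config: PanelConfig
    alignments: dict[str, LocusAlignment]
    truth: dict
    its_geometry: ItsGeometry
    its_templates: dict[str, str]       # species -> ungapped ITS template
    unknown_its: str                    # off-panel adulterant ITS (ungapped)
    its_noise_positions: list[int]      # ungapped positions eligible for noise

    def __getitem__(self, locus: str) -> LocusAlignment:
        return self.alignments[locus]

    @property
    def ingroup(self) -> tuple[str, ...]:
        return INGROUP_SPECIES

    def planted_columns(self, locus: str) -> list[int]:
        return sorted(e["column"] for e in self.truth["loci"][locus]["planted"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for locus, aln in self.alignments.items():
            write_fasta(aln.records, outdir / f"refs_{locus}.fasta")
        with (outdir / "truth.json").open("w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _sample_positions(rng: np.random.Generator, allowed: list[int],
                      n: int) -> list[int]:
    idx = rng.choice(len(allowed), size=n, replace=False)
    return [allowed[i] for i in sorted(idx)]


def _variant(rng: np.random.Generator, base: str) -> str:
    options = [b for b in _BASES if b != base]
    return options[int(rng.integers(0, 3))]


def _mutate(rng: np.random.Generator, seq: list[str], allowed: list[int],
            frac: float) -> None:
    n = int(round(frac * len(allowed)))
    if n == 0:
        return
    for pos in _sample_positions(rng, allowed, n):
        seq[pos] = _variant(rng, seq[pos])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _expand(seq_u: str, length_u: int, ins_blocks, col_of,
            fills: dict[int, str], deletions: set[int]) -> str:
    """Project an ungapped species sequence into alignment columns."""
    aligned = [GAP] * (length_u + sum(w for _, w in ins_blocks))
    for u in range(length_u):
        if u in deletions:
            continue
        aligned[col_of(u)] = seq_u[u]
    offset = 0
    for pos, width in ins_blocks:
        start = pos + offset
        block = fills.get(pos)
        if block is not None:
            for i, base in enumerate(block):
                aligned[start + i] = base
        offset += width
    return "".join(aligned)


def generate_reference_panel(config: PanelConfig | None = None
                             ) -> ReferencePanel:
    """Generate the full five-locus reference panel from one seed."""
    config = config or PanelConfig()
    rng = np.random.default_rng(config.seed)
    geometry = compute_its_geometry(config.constraints)

    truth: dict = {"seed": config.seed, "loci": {}}
    alignments: dict[str, LocusAlignment] = {}

    its_result = _build_its(config, rng, geometry, truth)
    alignments["ITS"] = its_result["alignment"]

    for locus in ("matK", "rbcL", "rpoB"):
        alignments[locus] = _build_plastid(config, rng, locus, truth)
    alignments["trnLF"] = _build_trnlf(config, rng, truth)

    truth["its_geometry"] = {
        "its1_span_u": list(geometry.its1_span),
        "fivep8S_span_u": list(geometry.fivep8S_span),
        "its2_span_u": list(geometry.its2_span),
        "fivep8S_cols": list(geometry.fivep8S_cols),
        "avf1_site_u": list(geometry.avf1_site_u),
        "isf_site_u": list(geometry.isf_site_u),
        "isr_site_u": list(geometry.isr_site_u),
        "alf1_site_u": list(geometry.alf1_site_u),
        "avf1_anchor_col": geometry.avf1_anchor_col,
        "alf1_anchor_col": geometry.alf1_anchor_col,
    }

    panel = ReferencePanel(
        config=config, alignments=alignments, truth=truth,
        its_geometry=geometry,
        its_templates=its_result["templates"],
        unknown_its=its_result["unknown"],
        its_noise_positions=its_result["noise_allowed"],
    )
    _check_unknown_identity(panel)
    return panel


def _ingroup_ids(config: PanelConfig):
    ids = [(f"AV{i + 1:02d}", A_VILLOSUM) for i in range(config.n_villosum)]
    ids += [(f"AX{i + 1:02d}", A_XANTHIOIDES)
            for i in range(config.n_xanthioides)]
    ids += [(f"AL{i + 1:02d}", A_LONGILIGULARE)
            for i in range(config.n_longiligulare)]
    return ids


def _build_its(config: PanelConfig, rng: np.random.Generator,
               geometry: ItsGeometry, truth: dict) -> dict:
    consensus = list(_random_bases(rng, ITS_LEN_U))
    s0, s1 = S58_SPAN_U
    consensus[s0:s1] = list(FIVE8S)
    av0, av1 = geometry.avf1_site_u
    consensus[av0:av1] = list(AVF1_WINDOW)
    al0, al1 = geometry.alf1_site_u
    consensus[al0:al1] = list(reverse_complement(ALF1_WINDOW))

    ins_strings = {pos: _random_bases(rng, width)
                   for pos, width in ITS_INS_BLOCKS}

    # Positions eligible for planted SNPs and intraspecific noise.
    blocked = set(range(*S58_SPAN_U)) | set(range(*ITS_DEL_ZONE_U))
    blocked |= set(range(av0, av1)) | set(range(al0, al1))
    blocked |= set(ITS_GUARDS_U)
    allowed = [u for u in range(ITS_LEN_U) if u not in blocked]

    n_extra = config.its_snps - 2  # two positions are the marker anchors
    planted_u = _sample_positions(rng, allowed, n_extra)
    # Pattern mix: mostly longiligulare-divergent (the two in-group clades),
    # a few xanthioides- and villosum-private positions, two intraspecific.
    n_long = n_extra - 7
    patterns = ([("AL",)] * n_long + [("AX",)] * 3 + [("AV",)] * 2
                + [("AV_intra",)] * 2)

    a_v, a_l = geometry.avf1_anchor_u, geometry.alf1_anchor_u
    base_v = consensus[a_v]
    base_l = consensus[a_l]
    overrides: dict[str, dict[int, str]] = {sp: {} for sp in INGROUP_SPECIES}
    # Anchor alleles: the villosum group keeps the AVF1 3' base and the
    # longiligulare consensus keeps the ALF1 3' complement; everyone else
    # mismatches at the respective anchor.
    overrides[A_LONGILIGULARE][a_v] = _ALT[base_v]
    overrides[A_VILLOSUM][a_l] = _ALT[base_l]
    overrides[A_XANTHIOIDES][a_l] = _ALT[base_l]

    planted_log = [
        {"column": _its_col(a_v), "kind": "fixed_interspecific",
         "alleles": {A_VILLOSUM: base_v, A_XANTHIOIDES: base_v,
                     A_LONGILIGULARE: _ALT[base_v]},
         "role": "avf1_anchor"},
        {"column": _its_col(a_l), "kind": "fixed_interspecific",
         "alleles": {A_VILLOSUM: _ALT[base_l], A_XANTHIOIDES: _ALT[base_l],
                     A_LONGILIGULARE: base_l},
         "role": "alf1_anchor"},
    ]

    intra_columns: list[tuple[int, str]] = []  # (u, minor base)
    for u, pattern in zip(planted_u, patterns):
        ref = consensus[u]
        var = _variant(rng, ref)
        alleles = {sp: ref for sp in INGROUP_SPECIES}
        if pattern[0] == "AL":
            overrides[A_LONGILIGULARE][u] = var
            alleles[A_LONGILIGULARE] = var
            kind = "fixed_interspecific"
        elif pattern[0] == "AX":
            overrides[A_XANTHIOIDES][u] = var
            alleles[A_XANTHIOIDES] = var
            kind = "fixed_interspecific"
        elif pattern[0] == "AV":
            overrides[A_VILLOSUM][u] = var
            alleles[A_VILLOSUM] = var
            kind = "fixed_interspecific"
        else:  # AV_intra: supported within-species polymorphism
            intra_columns.append((u, var))
            from .seq_core import AMBIGUITY_CODE
            alleles[A_VILLOSUM] = AMBIGUITY_CODE[frozenset({ref, var})]
            kind = "intraspecific"
        planted_log.append({"column": _its_col(u), "kind": kind,
                            "alleles": alleles})

    ids = _ingroup_ids(config)
    carriers = {}
    for u, var in intra_columns:
        picks = rng.choice(config.n_villosum, size=3, replace=False)
        carriers[u] = ([f"AV{i + 1:02d}" for i in sorted(picks)], var)
    for entry in planted_log:
        if entry["kind"] == "intraspecific":
            u = _its_u_from_col(entry["column"])
            entry["carriers"] = carriers[u][0]

    species_seqs: dict[str, list[str]] = {}
    for sp in INGROUP_SPECIES:
        seq = consensus.copy()
        for u, base in overrides[sp].items():
            seq[u] = base
        species_seqs[sp] = seq

    # Adulterants and outgroups: seeded divergence plus forced anchor
    # mismatches and the variability guards flanking the 5.8S block.
    # At every planted non-anchor SNP one adulterant species shares the
    # variant allele (rotating through the adulterants so no single
    # species accumulates in-group alleles) — only the designed anchor
    # columns are unique against the whole panel, as in a real marker
    # survey.
    shared_variants: dict[str, dict[int, str]] = {}
    adult_names = [s.name for s in config.adulterants]
    k = 0
    for u, pattern in zip(planted_u, patterns):
        if pattern[0] in ("AL", "AX", "AV"):
            sp = {"AL": A_LONGILIGULARE, "AX": A_XANTHIOIDES,
                  "AV": A_VILLOSUM}[pattern[0]]
            holder = adult_names[k % len(adult_names)]
            shared_variants.setdefault(holder, {})[u] = overrides[sp][u]
            k += 1

    # Lineage signal: a handful of positions where the whole in-group
    # carries a derived base against every adulterant and outgroup.
    shared_pool = [u for u in allowed if u not in set(planted_u)]
    ingroup_shared = {
        u: _variant(rng, consensus[u])
        for u in _sample_positions(rng, shared_pool, INGROUP_SHARED["ITS"])}

    mutable = [u for u in range(ITS_LEN_U)
               if not (s0 <= u < s1) and u not in (a_v, a_l)]
    for spec in config.species_specs:
        seq = consensus.copy()
        _mutate(rng, seq, mutable, spec.its)
        seq[a_v] = _ALT[base_v]
        seq[a_l] = _ALT[base_l]
        for u, var in shared_variants.get(spec.name, {}).items():
            seq[u] = var
        for u, var in ingroup_shared.items():
            seq[u] = var
        for g in ITS_GUARDS_U:
            seq[g] = _ALT[consensus[g]]
        species_seqs[spec.name] = seq

    # Off-panel unknown adulterant (the "new species" in monitoring).
    unknown = consensus.copy()
    _mutate(rng, unknown, mutable, config.unknown_divergence)
    unknown[a_v] = _ALT[base_v]
    unknown[a_l] = _ALT[base_l]
    for u, var in ingroup_shared.items():
        unknown[u] = var

    # Intraspecific noise: single-record substitutions, distinct columns.
    noise_allowed = [u for u in allowed
                     if u not in set(planted_u) and u not in ingroup_shared]
    available = noise_allowed.copy()
    noise_log = []
    noise_by_record: dict[str, list[tuple[int, str]]] = {}
    for rec_id, sp in ids:
        if sp != A_VILLOSUM:
            continue
        k = int(rng.binomial(ITS_LEN_U, config.intraspecific_rate))
        k = min(k, len(available))
        if k == 0:
            continue
        hits = _sample_positions(rng, available, k)
        available = [u for u in available if u not in set(hits)]
        for u in hits:
            var = _variant(rng, consensus[u])
            noise_by_record.setdefault(rec_id, []).append((u, var))
            noise_log.append({"column": _its_col(u), "record": rec_id})

    records = []
    for rec_id, sp in ids:
        seq = species_seqs[sp].copy()
        for u, (carrier_ids, var) in carriers.items():
            if rec_id in carrier_ids:
                seq[u] = var
        for u, var in noise_by_record.get(rec_id, []):
            seq[u] = var
        records.append(SeqRecord(rec_id, _expand(
            "".join(seq), ITS_LEN_U, ITS_INS_BLOCKS, _its_col, {}, set()),
            species=sp, locus="ITS"))

    for spec in config.species_specs:
        fills = {}
        if spec.its_fill is not None:
            pos, width = ITS_INS_BLOCKS[spec.its_fill]
            fills[pos] = ins_strings[pos]
        deletions = set(range(ITS_DEL_ZONE_U[0],
                              ITS_DEL_ZONE_U[0] + spec.its_deletion))
        aligned = _expand("".join(species_seqs[spec.name]), ITS_LEN_U,
                          ITS_INS_BLOCKS, _its_col, fills, deletions)
        for i in range(spec.n):
            records.append(SeqRecord(f"{spec.code}{i + 1:02d}", aligned,
                                     species=spec.name, locus="ITS"))

    truth["loci"]["ITS"] = {
        "aligned_length": ITS_ALIGNED_LEN,
        "planted": sorted(planted_log, key=lambda e: e["column"]),
        "noise": sorted(noise_log, key=lambda e: (e["column"], e["record"])),
        "ingroup_shared": sorted(
            ({"column": _its_col(u), "base": v}
             for u, v in ingroup_shared.items()),
            key=lambda e: e["column"]),
    }

    templates = {sp: _degap_for(sp, records) for sp in species_seqs}
    return {
        "alignment": LocusAlignment("ITS", records),
        "templates": templates,
        "unknown": "".join(unknown),
        "noise_allowed": noise_allowed,
    }


def _its_u_from_col(col: int) -> int:
    offset = 0
    for pos, width in ITS_INS_BLOCKS:
        if col >= pos + offset + width:
            offset += width
    return col - offset


def _degap_for(species: str, records: list[SeqRecord]) -> str:
    """Ungapped template of a species' *clean* sequence (first record is
    noise-bearing for A. villosum, so rebuild from the majority)."""
    rows = [r for r in records if r.species == species]
    if len(rows) == 1:
        return rows[0].degapped().seq
    # Column-wise majority over the species keeps planted alleles and
    # drops single-record noise.
    length = len(rows[0].seq)
    out = []
    for i in range(length):
        column = [r.seq[i] for r in rows]
        best = max(set(column), key=lambda c: (column.count(c), c))
        if best != GAP:
            out.append(best)
    return "".join(out)


def _build_plastid(config: PanelConfig, rng: np.random.Generator,
                   locus: str, truth: dict) -> LocusAlignment:
    length = PLASTID_LENGTHS[locus]
    consensus = list(_random_bases(rng, length))
    n_snps = {"matK": config.matk_snps, "rbcL": config.rbcl_snps,
              "rpoB": config.rpob_snps}[locus]
    target = A_XANTHIOIDES if locus == "rpoB" else A_LONGILIGULARE
    planted_u = _sample_positions(rng, list(range(length)), n_snps)
    overrides = {}
    planted_log = []
    for u in planted_u:
        var = _variant(rng, consensus[u])
        overrides[u] = var
        alleles = {sp: consensus[u] for sp in INGROUP_SPECIES}
        alleles[target] = var
        planted_log.append({"column": u, "kind": "fixed_interspecific",
                            "alleles": alleles})

    shared_pool = [u for u in range(length) if u not in set(planted_u)]
    ingroup_shared = {
        u: _variant(rng, consensus[u])
        for u in _sample_positions(rng, shared_pool, INGROUP_SHARED[locus])}

    records = []
    for rec_id, sp in _ingroup_ids(config):
        seq = consensus.copy()
        if sp == target:
            for u, var in overrides.items():
                seq[u] = var
        records.append(SeqRecord(rec_id, "".join(seq), species=sp,
                                 locus=locus))
    mutable = list(range(length))
    for spec in config.species_specs:
        seq = consensus.copy()
        frac = {"matK": spec.matk, "rbcL": spec.rbcl, "rpoB": spec.rpob}[locus]
        _mutate(rng, seq, mutable, frac)
        for u, var in ingroup_shared.items():
            seq[u] = var
        aligned = "".join(seq)
        for i in range(spec.n):
            records.append(SeqRecord(f"{spec.code}{i + 1:02d}", aligned,
                                     species=spec.name, locus=locus))
    truth["loci"][locus] = {
        "aligned_length": length,
        "planted": sorted(planted_log, key=lambda e: e["column"]),
        "noise": [],
        "ingroup_shared": sorted(
            ({"column": u, "base": v} for u, v in ingroup_shared.items()),
            key=lambda e: e["column"]),
    }
    return LocusAlignment(locus, records)


def _build_trnlf(config: PanelConfig, rng: np.random.Generator,
                 truth: dict) -> LocusAlignment:
    consensus = list(_random_bases(rng, TRNLF_LEN_U))
    ins_strings = {pos: _random_bases(rng, width)
                   for pos, width in TRNLF_INS_BLOCKS}
    # Private insert of the single A. malaccensis record: these two
    # columns carry exactly one residue and drop out of site statistics.
    blocked = (set(range(*TRNLF_DEL_ZONE_U)) | {TRNLF_XANTH_DEL_U})
    allowed = [u for u in range(TRNLF_LEN_U) if u not in blocked]
    planted_u = _sample_positions(rng, allowed, config.trnlf_snps - 1)
    patterns = ([("AL",)] * 2 + [("AX",)] * 2
                + [("AX_intra",)] * (config.trnlf_snps - 5))

    overrides: dict[str, dict[int, str]] = {sp: {} for sp in INGROUP_SPECIES}
    intra: list[tuple[int, str]] = []
    planted_log = [{
        "column": _trnlf_col(TRNLF_XANTH_DEL_U), "kind": "fixed_interspecific",
        "alleles": {A_VILLOSUM: consensus[TRNLF_XANTH_DEL_U],
                    A_XANTHIOIDES: GAP,
                    A_LONGILIGULARE: consensus[TRNLF_XANTH_DEL_U]},
        "role": "xanthioides_deletion"}]
    from .seq_core import AMBIGUITY_CODE
    for u, pattern in zip(planted_u, patterns):
        ref = consensus[u]
        var = _variant(rng, ref)
        alleles = {sp: ref for sp in INGROUP_SPECIES}
        if pattern[0] == "AL":
            overrides[A_LONGILIGULARE][u] = var
            alleles[A_LONGILIGULARE] = var
            kind = "fixed_interspecific"
        elif pattern[0] == "AX":
            overrides[A_XANTHIOIDES][u] = var
            alleles[A_XANTHIOIDES] = var
            kind = "fixed_interspecific"
        else:  # variation between the two xanthioides accessions
            intra.append((u, var))
            alleles[A_XANTHIOIDES] = AMBIGUITY_CODE[frozenset({ref, var})]
            kind = "intraspecific"
        planted_log.append({"column": _trnlf_col(u), "kind": kind,
                            "alleles": alleles,
                            **({"carriers": ["AX02"]}
                               if kind == "intraspecific" else {})})

    species_seqs = {}
    for sp in INGROUP_SPECIES:
        seq = consensus.copy()
        for u, var in overrides[sp].items():
            seq[u] = var
        species_seqs[sp] = seq

    shared_pool = [u for u in allowed if u not in set(planted_u)]
    ingroup_shared = {
        u: _variant(rng, consensus[u])
        for u in _sample_positions(rng, shared_pool,
                                   INGROUP_SHARED["trnLF"])}

    mutable = list(range(TRNLF_LEN_U))
    for spec in config.species_specs:
        seq = consensus.copy()
        _mutate(rng, seq, mutable, spec.trnlf)
        for u, var in ingroup_shared.items():
            seq[u] = var
        species_seqs[spec.name] = seq

    records = []
    for rec_id, sp in _ingroup_ids(config):
        seq = species_seqs[sp].copy()
        if rec_id == "AX02":
            for u, var in intra:
                seq[u] = var
        deletions = {TRNLF_XANTH_DEL_U} if sp == A_XANTHIOIDES else set()
        records.append(SeqRecord(rec_id, _expand(
            "".join(seq), TRNLF_LEN_U, TRNLF_INS_BLOCKS, _trnlf_col,
            {}, deletions), species=sp, locus="trnLF"))

    for spec in config.species_specs:
        fills = {}
        if spec.trnlf_fill is not None:
            pos, width = TRNLF_INS_BLOCKS[spec.trnlf_fill]
            fills[pos] = ins_strings[pos]
        deletions = set(range(TRNLF_DEL_ZONE_U[0],
                              TRNLF_DEL_ZONE_U[0] + spec.trnlf_deletion))
        aligned = _expand("".join(species_seqs[spec.name]), TRNLF_LEN_U,
                          TRNLF_INS_BLOCKS, _trnlf_col, fills, deletions)
        for i in range(spec.n):
            records.append(SeqRecord(f"{spec.code}{i + 1:02d}", aligned,
                                     species=spec.name, locus="trnLF"))

    truth["loci"]["trnLF"] = {
        "aligned_length": TRNLF_ALIGNED_LEN,
        "planted": sorted(planted_log, key=lambda e: e["column"]),
        "noise": [],
        "ingroup_shared": sorted(
            ({"column": _trnlf_col(u), "base": v}
             for u, v in ingroup_shared.items()),
            key=lambda e: e["column"]),
    }
    return LocusAlignment("trnLF", records)


def _check_unknown_identity(panel: ReferencePanel) -> None:
    """The off-panel adulterant must stay below the assignment threshold."""
    unknown_cols = _expand(panel.unknown_its, ITS_LEN_U, ITS_INS_BLOCKS,
                           _its_col, {}, set())
    for rec in panel.alignments["ITS"].records:
        ident = pairwise_identity(unknown_cols, rec.seq)
        if ident >= panel.config.unknown_threshold:
            raise ConfigError(
                f"unknown adulterant too close to {rec.id} "
                f"(identity {ident:.3f})")


# --- Monitoring panel ------------------------------------------------------

_AV, _AX, _AL = A_VILLOSUM, A_XANTHIOIDES, A_LONGILIGULARE
UNKNOWN = "unknown"

#: The 40-sample market-monitoring composition: (sample number, declared
#: name, true identity).  One two-species mixture (sample 9) and two
#: samples of an off-panel adulterant species (samples 12 and 26).
MONITORING_ROWS: tuple[tuple[int, str, tuple[str, ...]], ...] = (
    (1, _AV, (_AV,)), (2, _AV, (_AV,)), (3, _AV, (_AV,)), (4, _AV, (_AV,)),
    (5, _AV, (_AL,)), (6, _AV, (_AV,)), (7, _AV, (_AV,)), (8, _AV, (_AV,)),
    (9, _AV, (_AV, _AL)), (10, _AV, (_AV,)),
    (11, _AL, (_AL,)), (12, _AL, (UNKNOWN,)), (13, _AL, (_AV,)),
    (14, _AV, (_AV,)), (15, _AV, (_AV,)), (16, _AV, (_AV,)),
    (17, _AX, (_AV,)), (18, _AX, (_AV,)), (19, _AX, (_AV,)),
    (20, _AX, (_AV,)),
    (21, _AL, (_AL,)), (22, _AV, (_AV,)), (23, _AV, (_AV,)),
    (24, _AV, (_AV,)), (25, _AV, (_AV,)), (26, _AL, (UNKNOWN,)),
    (27, _AL, (_AV,)), (28, _AV, (_AV,)), (29, _AV, (_AV,)),
    (30, _AV, (_AV,)), (31, _AX, (_AV,)), (32, _AX, (_AL,)),
    (33, _AV, (_AV,)), (34, _AV, (_AV,)), (35, _AV, (_AV,)),
    (36, _AV, (_AV,)), (37, _AV, (_AV,)), (38, _AV, (_AV,)),
    (39, _AV, (_AV,)), (40, _AV, (_AV,)),
)


@dataclass
class MonitoringPanel:
    """Ungapped ITS queries with their sold-as labels."""

    records: list[SeqRecord]
    manifest: list[dict]   # sample_no, declared_name, record_ids

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, outdir / "queries.fasta")
        with (outdir / "manifest.tsv").open("w") as fh:
            fh.write("sample_no\tdeclared_name\trecord_ids\n")
            for row in self.manifest:
                fh.write(f"{row['sample_no']}\t{row['declared_name']}\t"
                         f"{';'.join(row['record_ids'])}\n")


def generate_monitoring_panel(panel: ReferencePanel,
                              rows=MONITORING_ROWS) -> MonitoringPanel:
    """Emulated market samples drawn from the reference panel's species.

    Each query is its true species' ITS template with fresh low-rate
    noise; the mixture sample contributes two records under one sample
    number; the unknown-species samples derive from the off-panel
    adulterant, which shares the internal-standard sites but lacks both
    species anchors and sits below the assignment identity threshold.
    """
    config = panel.config
    rng = np.random.default_rng(config.seed + 9001)
    allowed = panel.its_noise_positions
    records: list[SeqRecord] = []
    manifest: list[dict] = []
    for sample_no, declared, true in rows:
        if any(t != UNKNOWN and t not in panel.its_templates for t in true):
            raise ConfigError(
                f"sample {sample_no}: species {true!r} not in the panel")
        rec_ids = []
        for part, sp in enumerate(true):
            template = (panel.unknown_its if sp == UNKNOWN
                        else panel.its_templates[sp])
            seq = list(template)
            k = int(rng.binomial(len(template), config.query_noise_rate))
            if k:
                for u in _sample_positions(rng, allowed, min(k, len(allowed))):
                    seq[u] = _variant(rng, seq[u])
            suffix = chr(ord("a") + part) if len(true) > 1 else ""
            rec_id = f"S{sample_no:02d}{suffix}"
            rec_ids.append(rec_id)
            records.append(SeqRecord(rec_id, "".join(seq), species=sp,
                                     locus="query", declared_name=declared))
        manifest.append({"sample_no": sample_no, "declared_name": declared,
                         "record_ids": rec_ids})
    return MonitoringPanel(records=records, manifest=manifest)
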