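# Methods

This note documents the models, conventions, and design choices behind
the package: what each stage computes, which knobs matter, what the
synthetic data does and does not emulate, and the numerical details a
user re-deriving a result would need.

## Sequence conventions

Sequences are upper-case IUPAC strings; `U` is mapped to `T` on input and
`-` is the only gap character (`.` is rejected, so there is exactly one
alignment dialect).  All coordinates are 0-based half-open on the stored
(`+`) orientation.  Two bases "match" when their IUPAC base sets
intersect; a gap matches only a gap.  FASTA headers use the
`id|species|locus` dialect, with missing fields defaulting to `unknown`.

Pairwise global alignment (used only for query re-identification) is
affine-gap Needleman–Wunsch, delegated to Biopython's `PairwiseAligner`
with defaults match +1, mismatch −1, gap open −2, gap extend −0.5 (a gap
of length k costs −2 − 0.5(k−1)).  When several alignments are
co-optimal, the aligner's first enumerated traceback is reported; this is
deterministic for fixed inputs, and the score and identity — the
quantities consumed downstream — are invariant across co-optimal
tracebacks.  Identity is matched columns divided by columns where neither
row is a gap.

## Site classification and identity

A column is classified after treating gaps and ambiguity codes as
missing: fewer than two unambiguous residues → *excluded*; one state →
*conserved*; at least two states each carried by at least two sequences →
*parsimony-informative*; otherwise *singleton*.  These definitions make
the two bookkeeping identities hold exactly: conserved + variable +
excluded = aligned length, and variable = PI + singleton.

The identity-matrix convention is declared and isolated in one function:
gap-vs-residue is a mismatch, gap-gap columns leave the denominator, and
overlapping ambiguity codes count as a match.  Different survey tools
differ on exactly these conventions; anyone comparing against another
program should check its gap rule first.

## Diagnostic SNP discovery

For a set of in-group species, a column is a **fixed interspecific** SNP
when every species is internally uniform (ignoring ambiguity codes) and
at least two species-level alleles exist.  A species uniformly carrying a
gap yields a `-` allele: a fixed length variant is as diagnostic as a
substitution and is counted as such.

Within-species polymorphisms are reported as **intraspecific** SNPs only
when supported: the minor allele must occur in at least two records, or
the species must have at most two records (two deposited accessions that
disagree cannot be dismissed).  The rationale is practical: in real
surveys a variant seen in exactly one amplicon is indistinguishable from
polymerase or sequencing error, which is why such studies sequence each
sample repeatedly.  The synthetic generator plants exactly this
situation — low-rate single-record noise in *A. villosum* ITS — and the
support rule is what makes discovery on noisy data return exactly the
planted diagnostic set.

## Melting temperature

`primer_tm` implements the unified nearest-neighbor duplex model:
enthalpy/entropy stack parameters plus terminal initiation terms, the
entropic salt correction ΔS += 0.368·(N−1)·ln[Na⁺], and the
strand-concentration term R·ln(CT) with CT = [primer] − [template]/2 for
non-self-complementary duplexes (self-complementary oligos instead use
the full concentration and the symmetry entropy penalty).  Defaults are
50 mM monovalent salt and 250 nM of each strand (0.5 µM total oligo).
The tests cross-check against Biopython's independent implementation of
the same parameter set to within 0.1 °C.

## Marker design

Allele specificity is enforced purely by the 3′-terminal base: the
species primer is read from the target group's consensus and ends exactly
on a diagnostic allele at which **every** other record in the panel —
congeneric species, adulterants, outgroups — carries a different base.
No artificial penultimate mismatches are added; single-mismatch 3′
discrimination is the simplest rule consistent with a binary gel readout.
One marker intentionally covers both *A. villosum* and its variety
*xanthioides* (they are inseparable at the marker locus and jointly
constitute the drug in some pharmacopeias).

Primer length (18–26 nt) is chosen deterministically: among lengths whose
Tm falls in the window (default 55–65 °C), the one closest to 60 °C, ties
to the shorter oligo.  Windows containing a gap, an ambiguity code, or a
within-group disagreement are disqualified.  Orientation follows from the
anchor's position relative to the internal standard so the species
product lands in the allowed size range (default 150–600 b).

The internal standard is a universal pair placed entirely inside a run of
columns conserved across the whole panel, with a fixed product size
(default 100 b); the leftmost feasible placement is taken, making the
design reproducible.  Multiplex assembly enforces: pairwise product-size
gaps ≥ 50 b (gel resolvability), no complementary run of ≥ 4 bases
covering any primer's 3′ end against any panel oligo (3′-dimer
screening), and a panel Tm spread ≤ 5 °C (one shared annealing step).

## In-silico PCR

A primer binds where it anneals with at most 2 IUPAC-incompatible
positions, except in its 3′-terminal 3 bases, which must match perfectly
— extension blocking is all-or-nothing, matching the binary band/no-band
readout.  Both roles are scanned for every oligo (the primer sequence on
the + strand, its reverse complement for leftward extension), and every
convergent, non-overlapping site pair within 2000 b yields a product
whose size includes both primer footprints (the standard amplicon
definition; the 270/350/100 sizes are realized under this convention
end-to-end).  Band patterns merge the products of all records sharing one
sample number — a gel lane of a mixed extract superimposes both band
sets.  Calls: no internal-standard band → assay failure; standard only →
non-target; standard plus one species band → that group; plus both →
mixture.  A band matching two expected products within the ±10% size
tolerance raises an error rather than guessing.

## Distance phylogenetics

Distances use pairwise deletion (a column is dropped for a pair when
either sequence has a gap or ambiguity code there) under p, JC69, K2P, or
TN93; saturated pairs raise an error naming the pair instead of returning
infinity.  The closed forms were verified against an independent R
implementation to printed precision.  TN93 is the package's stand-in for
composite-likelihood distances: the substitution affects branch lengths,
not the topology or monophyly conclusions the pipeline draws, and the
pairwise form keeps saturation failures local to a pair.  Bayesian tree
building is out of scope; the concatenated-plastid analysis runs with
neighbor joining and checks the same monophyly claim.

UPGMA uses average linkage with heights equal to half the merge distance
(ultrametric by construction, verified to 1e−9); NJ is Saitou–Nei with
the standard Q criterion.  Both break ties on the lowest-index pair, and
NJ clamps negative branch lengths to zero, transferring the excess to the
sister branch so the cherry's total length is preserved.  The NJ root is
a trifurcation and the tree is read as unrooted; monophyly is therefore
evaluated rooting-free, as the existence of an edge separating exactly
the queried taxa from a side containing the outgroup.

Bootstrap resamples columns with replacement; support for each internal
edge of the full-data tree is the percentage of successful replicates
whose tree contains the same bipartition.  Replicates with a saturated
pair are skipped with a warning and removed from the denominator.  With
fixed seeds the whole procedure is reproducible byte-for-byte.

## Monitoring workflow

Each market sample runs through two independent routes: the multiplex
assay (band pattern → verdict) and nearest-reference ITS identity (global
alignment against every degapped reference, best identity wins, ties to
the lexicographically first reference id).  A best identity below the
threshold (default 0.95, sitting between the in-group minimum of ≈0.97
and the congeneric adulterant maximum of ≈0.94) leaves the sample
*unidentified* — deliberately unnamed, since naming a new adulterant from
a single nearest-neighbor hit is not defensible.  Route agreement is
checked at the species-group level (the marker cannot separate
*A. villosum* from var. *xanthioides*); the ITS route reports the finer
label, and the declared-name comparison uses that finer label, so a
sample of genuine *A. villosum* sold as "var. *xanthioides*" is flagged
mislabeled even though its marker band is the expected one.  Flags:
concordant, mislabeled, mixture (both species bands), unknown adulterant
(internal standard only and no reference above threshold), assay failure,
and discordant-methods (never observed on consistent data; strict mode
raises instead).

## The synthetic panel

The generator is the test substrate: every quantitative claim the tests
and the acceptance script make is made against its logged ground truth,
at the study's own scale (seconds on one CPU).

Composition (defaults): 18 *A. villosum* + 2 var. *xanthioides* + 5
*A. longiligulare* in-group records; 30 adulterant records in 11 species
across *Amomum*, *Alpinia*, *Elettaria*; 2 distant outgroups for rooting.
Loci and aligned lengths: ITS 670, *matK* 933, *rbcL* 743, *rpoB* 516,
*trnL-F* 422 (plastid concatenation 2614).  Every ITS record's ungapped
length falls in 645–665; in-group *trnL-F* is 407–408 with adulterants
spanning 395–415.

Planted in-group polymorphism (32 positions, all logged):

* ITS 19 — the two marker anchors, ten further *A. longiligulare*-
  divergent positions, three *xanthioides*-private, two *villosum*-
  private, and two supported intraspecific positions within *A. villosum*
  (minor allele in three samples);
* *matK* 1 and *rbcL* 4, separating *A. longiligulare*; *rpoB* 1,
  separating var. *xanthioides* — the documented pattern in which the
  variety is plastid-identical to *A. villosum* except at *rpoB*;
* *trnL-F* 7 — two *villosum*/*longiligulare* differences, two fixed
  *xanthioides* substitutions, one fixed *xanthioides* single-base
  deletion (the 407 vs 408 length variant, reported as a `-` allele), and
  two intraspecific positions between the two *xanthioides* accessions.

The ITS architecture is fixed rather than seed-dependent: a 160-b
conserved block (standing in for the 5.8S rRNA gene, identical in every
species so the internal standard is truly universal) flanked by ITS1 and
ITS2, with the published marker oligo sequences embedded as the species
primer sites and the anchors placed so the deterministic designer yields
270/350/100-b products.  Two "variability guard" columns flank the
conserved block so its boundaries — and hence the internal-standard
placement — are identical for every seed.  Three structural details keep
the designed panel honest: (i) at every planted non-anchor SNP one
adulterant species shares the variant allele (rotating across the
adulterant list), so only the intended anchor columns are unique
panel-wide, exactly as in a real survey where marker SNPs are chosen for
their uniqueness; (ii) a handful of positions per locus carry an
in-group-shared base against all adulterants and outgroups, modelling the
lineage signal that unites congeners — without it the panel is a star
radiating from the consensus, the in-group has no internal edge, and NJ
monophyly is genuinely undefined; (iii) single-record ITS noise
(rate 0.002/site in *A. villosum*) never reuses a column, touches a
primer window, or lands on a diagnostic position, keeping the planted
truth exact.

Adulterant divergence defaults (substitution fraction from the in-group
consensus): ITS 8–16% (congeners lowest), *matK* 2%, *rbcL* 1.5% (10% for
the one deliberately divergent species), *rpoB* 1.2%, *trnL-F* 3–10%;
outgroups 30% at ITS and 12–20% at the plastids.  These reproduce the
qualitative identity ordering of real panels — ITS the most
discriminating, *rpoB* the least — and place congeneric adulterants at
0.85–0.94 ITS identity, safely below the 0.95 assignment threshold and
the ≥0.97 in-group range.

The 40-sample monitoring composition is fixed: 28 correctly labelled
samples, 9 mislabeled (including five sold as var. *xanthioides*), one
two-record mixture (sample 9), and two samples (12 and 26) of an
off-panel adulterant generated at 12% divergence with intact
internal-standard sites and both species anchors removed; the generator
verifies it stays below 0.95 identity to every reference.  Queries are
drawn from their true species' ITS template with fresh 0.002/site noise
confined to neutral positions.

What the generator does **not** emulate: alignment error (inputs are
born aligned), sequencing chromatogram noise and heterozygous base
calls, fungal ITS contamination, within-adulterant-species variation,
rate heterogeneity along sequences, and realistic phylogenetic depth
between adulterant genera (each adulterant species diverges independently
from one consensus).  Passing tests therefore demonstrate that the
algorithms are correct under their stated models — not that the assay
would survive every failure mode of herbal-market DNA.

## Problem sizes

Default scales were chosen to match the study design they emulate: a
59-record five-locus panel, a four-primer multiplex, 40 monitoring
samples, 100 bootstrap replicates per tree.  The full test suite runs in
about a minute on one CPU; the acceptance script in a few seconds.

## Known limitations

* The BioEdit/MEGA conventions for identity matrices and site counts are
  not uniquely documented; the declared conventions here reproduce the
  internal arithmetic of such tables but are not guaranteed to match
  either program column-for-column on real data.
* Primer thermodynamics stop at nearest-neighbor Tm and a string-match
  dimer screen; no secondary-structure folding.
* Re-identification is nearest-reference within the supplied panel, not
  a database search: an unknown sample is flagged, never named.
* The amplicon-size convention (inclusive of both primer footprints) is
  assumed consistently end-to-end; a wet-lab ladder calibrated otherwise
  would shift all sizes together.
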