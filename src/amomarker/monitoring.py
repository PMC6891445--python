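"""End-to-end market monitoring: multiplex assay + ITS re-identification.

Each market sample is pushed through two independent identification
routes: (1) the in-silico multiplex assay, read as a gel band pattern and
called per the panel's expected products, and (2) nearest-reference ITS
identity, where the query is globally aligned against every (degapped)
reference sequence and assigned to the best-identity species unless it
falls below the ``unknown_threshold``.  The two routes are reconciled
with the declared (sold-as) label into a per-sample flag.

The species marker cannot separate *A. villosum* from its variety
*xanthioides* (they share one common marker), so route agreement is
checked at the species-group level while the ITS route reports the finer
label.  A sample with only the internal-standard band and no reference
above the identity threshold is reported as an unidentified candidate
new adulterant rather than being given a species name.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DataError
from .insilico_pcr import (ASSAY_FAILURE, LONGILIGULARE, MIXTURE, NON_TARGET,
                           VILLOSUM_GROUP, PCRRules, band_pattern,
                           call_species, simulate_pcr)
from .marker_design import (MultiplexPanel, PrimerConstraints,
                            assemble_multiplex_panel,
                            design_internal_standard, design_species_primer,
                            find_diagnostic_snps)
from .seq_core import GlobalAlignment, LocusAlignment, SeqRecord, global_align
from .synthetic_data import (A_LONGILIGULARE, A_VILLOSUM, A_XANTHIOIDES,
                             INGROUP_SPECIES)

CONCORDANT = "concordant"
MISLABELED = "mislabeled"
UNKNOWN_ADULTERANT = "unknown_adulterant"
DISCORDANT_METHODS = "discordant_methods"

UNIDENTIFIED = "unidentified"
ASSIGNED = "assigned"


@dataclass(frozen=True)
class Thresholds:
    unknown_threshold: float = 0.95
    strict: bool = False   # raise on marker/ITS disagreement instead of flagging


@dataclass(frozen=True)
class ReIdentification:
    sample: str
    best_reference: str
    best_species: str
    identity: float
    status: str  # assigned | unidentified


@dataclass
class MonitoringRow:
    sample_no: int
    declared_name: str
    marker_verdict: str
    bands: tuple[int, ...]
    its_species: tuple[str, ...]
    its_identity: float
    flag: str


@dataclass
class MonitoringReport:
    rows: list[MonitoringRow]
    summary: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.summary.values()) != len(self.rows):
            raise DataError("report summary does not sum to the row count")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sample_no": r.sample_no,
            "declared_name": r.declared_name,
            "marker_verdict": r.marker_verdict,
            "bands": ";".join(str(b) for b in r.bands),
            "its_reidentified": "/".join(r.its_species),
            "its_identity": round(r.its_identity, 4),
            "flag": r.flag,
        } for r in self.rows])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def design_marker_panel(its: LocusAlignment,
                        constraints: PrimerConstraints | None = None
                        ) -> MultiplexPanel:
    """The standard four-primer panel for a labelled ITS alignment.

    One common allele-specific marker for *A. villosum* and its variety
    *xanthioides* (AVF1-style), one for *A. longiligulare* (ALF1-style),
    and the universal internal-standard pair (ISF/ISR) in the conserved
    block.
    """
    constraints = constraints or PrimerConstraints()
    is_pair = design_internal_standard(its, constraints)
    snps = find_diagnostic_snps(its, INGROUP_SPECIES)
    avf1 = design_species_primer(
        its, snps, A_VILLOSUM, constraints,
        target_species={A_VILLOSUM, A_XANTHIOIDES},
        is_pair=is_pair, name="AVF1")
    alf1 = design_species_primer(its, snps, A_LONGILIGULARE, constraints,
                                 is_pair=is_pair, name="ALF1")
    return assemble_multiplex_panel([avf1, alf1], is_pair, its)


def species_group(species: str) -> str:
    """Collapse the villosum group for marker-level comparison."""
    if species in (A_VILLOSUM, A_XANTHIOIDES):
        return VILLOSUM_GROUP
    if species == A_LONGILIGULARE:
        return LONGILIGULARE
    return NON_TARGET


def reidentify_by_its(query: SeqRecord, references: LocusAlignment,
                      thresholds: Thresholds | None = None
                      ) -> ReIdentification:
    """Assign a query to the best-identity reference species.

    References are degapped per record before alignment; ties break on the
    lexicographically first reference id.  A best identity below the
    unknown threshold yields status ``unidentified``.
    """
    thresholds = thresholds or Thresholds()
    refs = sorted(references.records, key=lambda r: r.id)
    if not refs:
        raise DataError("empty reference set")
    best: tuple[float, str, str] | None = None
    for ref in refs:
        result: GlobalAlignment = global_align(query.seq, ref.degapped().seq)
        if best is None or result.identity > best[0] + 1e-12:
            best = (result.identity, ref.id, ref.species)
    identity, ref_id, species = best
    status = (ASSIGNED if identity >= thresholds.unknown_threshold
              else UNIDENTIFIED)
    return ReIdentification(sample=query.id, best_reference=ref_id,
                            best_species=species, identity=identity,
                            status=status)


def run_authentication(references: LocusAlignment, panel: MultiplexPanel,
                       queries: list[SeqRecord], manifest: list[dict],
                       thresholds: Thresholds | None = None,
                       rules: PCRRules | None = None) -> MonitoringReport:
    """Authenticate a monitoring panel sample by sample.

    ``manifest`` rows carry ``sample_no``, ``declared_name`` and
    ``record_ids`` (a gel lane merges the products of all records sharing
    one sample number).  Flags: ``mixture`` when the lane shows both
    species bands; ``unknown_adulterant`` when only the internal standard
    amplified and no reference reaches the identity threshold;
    ``mislabeled`` when the genetic identity disagrees with the declared
    name; ``concordant`` otherwise.  A marker/ITS conflict for a
    panel-member species yields ``discordant_methods`` (or an error in
    strict mode).
    """
    thresholds = thresholds or Thresholds()
    rules = rules or PCRRules()
    by_id = {q.id: q for q in queries}
    rows: list[MonitoringRow] = []
    for entry in manifest:
        sample_no = int(entry["sample_no"])
        declared = entry["declared_name"]
        if not declared or declared == "unknown":
            raise DataError(f"sample {sample_no}: no declared name")
        recs = [by_id[rid] for rid in entry["record_ids"]]
        product_lists = [simulate_pcr(rec, panel, rules) for rec in recs]
        pattern = band_pattern(f"S{sample_no:02d}", product_lists, rules)
        call = call_species(pattern, panel)

        reids = [reidentify_by_its(rec, references, thresholds)
                 for rec in recs]
        its_species = tuple(r.best_species if r.status == ASSIGNED
                            else "unidentified" for r in reids)
        its_identity = max(r.identity for r in reids)

        flag = _reconcile(call.verdict, its_species, declared, thresholds)
        rows.append(MonitoringRow(
            sample_no=sample_no, declared_name=declared,
            marker_verdict=call.verdict, bands=tuple(pattern.sizes),
            its_species=its_species, its_identity=its_identity, flag=flag))

    summary = dict(Counter(r.flag for r in rows))
    return MonitoringReport(rows=rows, summary=summary)


def _reconcile(verdict: str, its_species: tuple[str, ...], declared: str,
               thresholds: Thresholds) -> str:
    if verdict == ASSAY_FAILURE:
        return ASSAY_FAILURE
    if verdict == MIXTURE:
        return MIXTURE
    if verdict == NON_TARGET:
        if all(sp == "unidentified" for sp in its_species):
            return UNKNOWN_ADULTERANT
        # An identified non-Amomi reference species sold as the drug.
        return MISLABELED
    # Marker says one of the two target groups: the ITS route must agree.
    its_groups = {species_group(sp) for sp in its_species
                  if sp != "unidentified"}
    if its_groups != {verdict}:
        if thresholds.strict:
            raise DataError(
                f"marker verdict {verdict!r} disagrees with ITS "
                f"re-identification {its_species!r}")
        return DISCORDANT_METHODS
    if all(sp == declared for sp in its_species):
        return CONCORDANT
    return MISLABELED
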