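"""Isolate dereplication, reference assignment, and novelty decision rules.

The decision engine implements the conventional polyphasic criteria used to
delineate gut-bacterial taxa:

* a NEW SPECIES must simultaneously satisfy three "golden standards" —
  best 16S rRNA identity < 98%, ANI < 95%, and dDDH < 70% (dDDH is an
  externally supplied value; it is not computed here);
* a new species is additionally a NEW GENUS when at least three of five
  signals hold: 16S identity <= 95%, a separate phylogenetic clade, POCP
  < 50%, a marker-gene grouping pointing to a novel genus, and distinct
  morphology/physiology.  The last three of the five rely on analyses that
  are performed outside this toolkit and enter as supplied booleans.

Unknown evidence is conservative: it can never support a novelty call.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Union

from .align import AlignmentParams, DEFAULT_NT_PARAMS, global_identity
from .errors import FormatError, PreconditionError
from .io import CatalogEntry, SequenceRecord

logger = logging.getLogger(__name__)

INDETERMINATE = "indeterminate"

SPECIES_SSU_MAX = 98.0   # percent, strict <
SPECIES_ANI_MAX = 95.0   # percent, strict <
SPECIES_DDH_MAX = 70.0   # percent, strict <
GENUS_SSU_MAX = 95.0     # percent, inclusive <=
GENUS_POCP_MAX = 50.0    # percent, strict <
GENUS_MIN_CRITERIA = 3

GENUS_CRITERIA = (
    "ssu_identity_le_95",
    "separate_clade",
    "pocp_lt_50",
    "marker_gene_novel_genus",
    "phenotype_distinct",
)


@dataclass
class TaxonCluster:
    taxon_id: str
    centroid_id: str
    member_ids: List[str]

    def __post_init__(self) -> None:
        assert self.centroid_id in self.member_ids


def dereplicate_isolates(
    seqs: Sequence[SequenceRecord],
    threshold: float = 0.98,
    params: AlignmentParams = DEFAULT_NT_PARAMS,
) -> List[TaxonCluster]:
    """Greedy centroid clustering of 16S sequences at an identity cutoff.

    Sequences are processed longest first (ties by id); each joins the
    first existing centroid with identity >= ``threshold``, otherwise it
    founds a new cluster.  The result partitions the input.
    """
    ordered = sorted(seqs, key=lambda r: (-len(r), r.id))
    clusters: List[TaxonCluster] = []
    centroids: List[SequenceRecord] = []
    for rec in ordered:
        placed = False
        for cluster, centroid in zip(clusters, centroids):
            if global_identity(rec, centroid, params).identity >= threshold:
                cluster.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(
                TaxonCluster(f"taxon_{len(clusters) + 1:04d}", rec.id, [rec.id])
            )
            centroids.append(rec)
    logger.info(
        "dereplicated %d isolates into %d taxa at %.1f%% identity",
        len(ordered), len(clusters), 100 * threshold,
    )
    return clusters


def remove_failed(
    clusters: Sequence[TaxonCluster], failed_ids: Set[str]
) -> List[TaxonCluster]:
    """Drop isolates that failed downstream propagation.

    Clusters losing all members disappear; a cluster losing its centroid
    keeps its id with the first surviving member as the new centroid.
    """
    kept: List[TaxonCluster] = []
    for cluster in clusters:
        members = [m for m in cluster.member_ids if m not in failed_ids]
        if not members:
            continue
        centroid = cluster.centroid_id if cluster.centroid_id in members else members[0]
        kept.append(TaxonCluster(cluster.taxon_id, centroid, members))
    return kept


@dataclass(frozen=True)
class Assignment:
    query_id: str
    reference_id: Optional[str]   # None when unassigned
    best_reference_id: str
    identity: float               # fraction, vs best reference

    @property
    def assigned(self) -> bool:
        return self.reference_id is not None


def assign_to_reference(
    seq: SequenceRecord,
    refdb: Sequence[Union[SequenceRecord, CatalogEntry]],
    threshold: float = 0.98,
    params: AlignmentParams = DEFAULT_NT_PARAMS,
) -> Assignment:
    """Best-hit assignment of a 16S sequence against a reference set.

    The sequence is assigned to the reference with maximal identity when
    that identity exceeds ``threshold`` STRICTLY; ties are broken by
    reference order.
    """
    if not refdb:
        raise PreconditionError("assign_to_reference requires a nonempty reference set")
    best_id: Optional[str] = None
    best_identity = -1.0
    for ref in refdb:
        rec = ref.ssu if isinstance(ref, CatalogEntry) else ref
        rid = ref.species_id if isinstance(ref, CatalogEntry) else ref.id
        ident = global_identity(seq, rec, params).identity
        if ident > best_identity:
            best_identity = ident
            best_id = rid
            if ident == 1.0:
                break
    assigned_to = best_id if best_identity > threshold else None
    return Assignment(seq.id, assigned_to, best_id, best_identity)


@dataclass
class NoveltyEvidence:
    """Per-isolate evidence consumed by the novelty rules.

    Percent-valued fields are on the 0-100 scale; ``None`` means the
    measurement is unavailable.  The three boolean signals are tri-state:
    True / False / None (unknown), and unknown never counts in favour of
    novelty.
    """

    isolate_id: str
    ssu_identity_best: float           # percent vs closest described species
    ani: Optional[float] = None        # percent
    ddh: Optional[float] = None        # percent
    pocp: Optional[float] = None       # percent
    separate_clade: Optional[bool] = None
    marker_gene_novel_genus: Optional[bool] = None
    phenotype_distinct: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("ssu_identity_best", "ani", "ddh", "pocp"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise PreconditionError(f"{self.isolate_id}: {name}={v} outside [0, 100]")


@dataclass
class NoveltyCall:
    isolate_id: str
    is_new_species: bool
    is_new_genus: bool
    criteria_met: List[str] = field(default_factory=list)
    rationale: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_new_genus:
            assert self.is_new_species, "a new genus must be a new species"
            assert len(self.criteria_met) >= GENUS_MIN_CRITERIA


def call_species_novelty(ev: NoveltyEvidence) -> Union[bool, str]:
    """Apply the three species golden standards conjunctively.

    Returns True when 16S identity < 98 AND ANI < 95 AND dDDH < 70; False
    as soon as any defined value fails its criterion; the string
    ``INDETERMINATE`` when nothing fails but ANI or dDDH is missing.
    """
    if ev.ssu_identity_best is None:
        raise PreconditionError(f"{ev.isolate_id}: ssu_identity_best is required")
    if ev.ssu_identity_best >= SPECIES_SSU_MAX:
        return False
    if ev.ani is not None and ev.ani >= SPECIES_ANI_MAX:
        return False
    if ev.ddh is not None and ev.ddh >= SPECIES_DDH_MAX:
        return False
    if ev.ani is None or ev.ddh is None:
        return INDETERMINATE
    return True


def call_genus_novelty(ev: NoveltyEvidence) -> NoveltyCall:
    """Count the five genus criteria for a confirmed new species.

    Requires ``call_species_novelty(ev) is True``; at least three satisfied
    criteria make the new species a new genus.  Unknown booleans and an
    unknown POCP count as unsatisfied.
    """
    species = call_species_novelty(ev)
    if species is not True:
        raise PreconditionError(
            f"{ev.isolate_id}: genus novelty evaluated on a non-novel species "
            f"(species call: {species})"
        )
    status: Dict[str, bool] = {
        "ssu_identity_le_95": ev.ssu_identity_best <= GENUS_SSU_MAX,
        "separate_clade": ev.separate_clade is True,
        "pocp_lt_50": ev.pocp is not None and ev.pocp < GENUS_POCP_MAX,
        "marker_gene_novel_genus": ev.marker_gene_novel_genus is True,
        "phenotype_distinct": ev.phenotype_distinct is True,
    }
    met = [name for name in GENUS_CRITERIA if status[name]]
    rationale = {name: ("pass" if status[name] else "fail/unknown") for name in GENUS_CRITERIA}
    return NoveltyCall(
        isolate_id=ev.isolate_id,
        is_new_species=True,
        is_new_genus=len(met) >= GENUS_MIN_CRITERIA,
        criteria_met=met,
        rationale=rationale,
    )


# ---------------------------------------------------------------------------
# Evidence table I/O
# ---------------------------------------------------------------------------

_EVIDENCE_COLUMNS = [
    "isolate_id",
    "ssu_identity_best",
    "ani",
    "ddh",
    "pocp",
    "separate_clade",
    "marker_gene_novel_genus",
    "phenotype_distinct",
]


def _parse_optional_float(token: str, where: str) -> Optional[float]:
    if token.upper() in ("NA", ""):
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"{where}: {token!r} is not a number or NA") from exc


def _parse_optional_bool(token: str, where: str) -> Optional[bool]:
    t = token.strip().lower()
    if t in ("na", ""):
        return None
    if t in ("true", "t", "1", "yes"):
        return True
    if t in ("false", "f", "0", "no"):
        return False
    raise FormatError(f"{where}: {token!r} is not a boolean or NA")


def read_evidence_table(path: str | Path) -> List[NoveltyEvidence]:
    """Read a tab-separated evidence table (NA for unknown values)."""
    rows: List[NoveltyEvidence] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != _EVIDENCE_COLUMNS:
            raise FormatError(
                f"{path}: expected header {_EVIDENCE_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            where = f"{path}: line {lineno}"
            rows.append(
                NoveltyEvidence(
                    isolate_id=row[0],
                    ssu_identity_best=float(row[1]),
                    ani=_parse_optional_float(row[2], where),
                    ddh=_parse_optional_float(row[3], where),
                    pocp=_parse_optional_float(row[4], where),
                    separate_clade=_parse_optional_bool(row[5], where),
                    marker_gene_novel_genus=_parse_optional_bool(row[6], where),
                    phenotype_distinct=_parse_optional_bool(row[7], where),
                )
            )
    return rows


def novelty_report(evidence: Sequence[NoveltyEvidence]) -> List[Dict[str, str]]:
    """One report row per isolate with per-criterion status and final calls."""
    report: List[Dict[str, str]] = []
    for ev in evidence:
        species = call_species_novelty(ev)
        row: Dict[str, str] = {
            "isolate_id": ev.isolate_id,
            "species_call": str(species) if species is INDETERMINATE else ("new_species" if species else "known_species"),
        }
        if species is True:
            call = call_genus_novelty(ev)
            row["genus_call"] = "new_genus" if call.is_new_genus else "same_genus"
            row["genus_criteria_met"] = str(len(call.criteria_met))
            for name in GENUS_CRITERIA:
                row[name] = call.rationale[name]
        else:
            row["genus_call"] = "not_evaluated"
            row["genus_criteria_met"] = "NA"
            for name in GENUS_CRITERIA:
                row[name] = "NA"
        report.append(row)
    return report


def write_novelty_report(report: Sequence[Dict[str, str]], path: str | Path) -> None:
    if not report:
        raise PreconditionError("empty novelty report")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(report[0].keys()), delimiter="\t")
        writer.writeheader()
        writer.writerows(report)
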