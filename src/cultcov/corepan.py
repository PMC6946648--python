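"""Genus-level occupancy/abundance statistics and core/pan classification.

For every genus the toolkit computes, across the samples of an OTU table:

* FO (frequency of occurrence): the fraction of samples in which the genus
  has at least one read;
* mean RA (relative abundance): per-sample genus reads divided by the
  sample's total reads, averaged over samples.

Core genera satisfy FO > 80% and mean RA > 0.1%; pan genera satisfy
FO > 5% (configurable).  A core genus is always also a pan genus under the
defaults; classification records the most specific label.  OTUs labelled
"unclassified" never aggregate into a genus, but their reads stay in the
per-sample denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from ._util import percent
from .errors import PreconditionError
from .io import Catalog, OtuTable

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

CORE_FO_DEFAULT = 0.80
CORE_RA_DEFAULT = 0.001
PAN_FO_DEFAULT = 0.05


@dataclass
class GenusStats:
    genus: str
    fo: float            # fraction of samples containing the genus
    ra_mean: float       # mean per-sample relative abundance (fraction)
    classification: Optional[str] = None  # "core" | "pan" | "neither"


def genus_stats(
    table: OtuTable, samples: Optional[Sequence[str]] = None
) -> List[GenusStats]:
    """Per-genus FO and mean RA over (a subset of) the table's samples."""
    if table.genus_labels is None:
        raise PreconditionError("OTU table has no genus labels")
    sub = table.subset_samples(samples) if samples is not None else table
    totals = sub.sample_totals().astype(float)
    if np.all(totals == 0):
        logger.warning("genus_stats: all samples are empty")
    genera = sorted(
        {sub.genus_of(o) for o in sub.otu_ids} - {UNCLASSIFIED}
    )
    if not genera:
        logger.warning("genus_stats: no genus-labelled OTUs")
        return []
    nonzero = totals > 0
    results: List[GenusStats] = []
    for genus in genera:
        mask = np.array([sub.genus_of(o) == genus for o in sub.otu_ids], dtype=bool)
        reads = sub.counts[mask].sum(axis=0).astype(float)
        fo = float(np.mean(reads >= 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            ra = np.where(nonzero, reads / np.where(nonzero, totals, 1.0), 0.0)
        # empty samples contribute RA 0 (no evidence of presence)
        ra_mean = float(ra.mean()) if len(ra) else 0.0
        results.append(GenusStats(genus, fo, ra_mean))
    return results


def classify_core_pan(
    stats: Sequence[GenusStats],
    core_fo: float = CORE_FO_DEFAULT,
    core_ra: float = CORE_RA_DEFAULT,
    pan_fo: float = PAN_FO_DEFAULT,
) -> List[GenusStats]:
    """Label each genus core / pan / neither (strict > thresholds).

    core: FO > core_fo AND mean RA > core_ra; pan: FO > pan_fo.  The most
    specific label wins (core over pan).
    """
    out: List[GenusStats] = []
    for s in stats:
        if s.fo > core_fo and s.ra_mean > core_ra:
            label = "core"
        elif s.fo > pan_fo:
            label = "pan"
        else:
            label = "neither"
        out.append(GenusStats(s.genus, s.fo, s.ra_mean, label))
    n_core = sum(1 for s in out if s.classification == "core")
    n_pan = sum(1 for s in out if s.classification in ("core", "pan"))
    logger.info(
        "classify_core_pan: %d core, %d pan of %d genera "
        "(core_fo=%s core_ra=%s pan_fo=%s)",
        n_core, n_pan, len(out), core_fo, core_ra, pan_fo,
    )
    return out


@dataclass(frozen=True)
class CorePanCoverage:
    n_core: int
    n_core_covered: int
    n_pan: int
    n_pan_covered: int

    @property
    def core_pct(self) -> int:
        """Round-half-up integer percent of core genera covered."""
        return int(percent(self.n_core_covered, self.n_core)) if self.n_core else 0

    @property
    def pan_pct(self) -> int:
        return int(percent(self.n_pan_covered, self.n_pan)) if self.n_pan else 0


def corepan_catalog_coverage(
    stats: Sequence[GenusStats],
    catalog: Union[Catalog, Sequence[str]],
) -> CorePanCoverage:
    """How many core / pan genera carry at least one catalog member.

    Genus names are compared by exact string equality (after whitespace
    trimming at parse time).  Core genera also count in the pan totals,
    mirroring the subset relation of the default thresholds.
    """
    covered_genera = catalog.genera if isinstance(catalog, Catalog) else set(catalog)
    core = [s for s in stats if s.classification == "core"]
    pan = [s for s in stats if s.classification in ("core", "pan")]
    return CorePanCoverage(
        n_core=len(core),
        n_core_covered=sum(1 for s in core if s.genus in covered_genera),
        n_pan=len(pan),
        n_pan_covered=sum(1 for s in pan if s.genus in covered_genera),
    )


def stats_table(
    stats: Sequence[GenusStats], catalog: Optional[Union[Catalog, Sequence[str]]] = None
) -> List[Dict[str, object]]:
    """Rows for the output TSV: genus, fo, ra_mean, classification, covered."""
    covered = (
        (catalog.genera if isinstance(catalog, Catalog) else set(catalog))
        if catalog is not None
        else None
    )
    rows: List[Dict[str, object]] = []
    for s in stats:
        row: Dict[str, object] = {
            "genus": s.genus,
            "fo": s.fo,
            "ra_mean": s.ra_mean,
            "classification": s.classification or "NA",
        }
        if covered is not None:
            row["covered_by_catalog"] = s.genus in covered
        rows.append(row)
    return rows
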