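"""Two-group per-taxon relative-abundance comparison with star coding.

Each taxon's per-sample relative abundances in two groups (e.g., ob/ob vs
wild-type mice) are compared with a two-sided t test (Welch by default,
Student optionally).  Significance is star-coded exactly as in the field's
summary tables — p < 0.05 '*', p < 0.01 '**', p < 0.001 '***', otherwise
'ns' — and a starred taxon is labelled as enriched in the group with the
larger mean.  P-values are reported unadjusted to match the per-taxon star
convention; a Benjamini-Hochberg column is available as an optional extra.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import FormatError, PreconditionError

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p_value: float) -> str:
    """Map a p-value to its star code; boundaries are strict (< not <=)."""
    for threshold, code in STAR_THRESHOLDS:
        if p_value < threshold:
            return code
    return "ns"


@dataclass
class GroupedAbundance:
    """Per-taxon relative abundances for two sample groups.

    Matrices are taxa x samples with values in [0, 1].  Raw counts may be
    passed instead; ``from_counts`` converts them to per-sample proportions.
    """

    taxon_ids: List[str]
    group_a: np.ndarray
    group_b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        self.group_a = np.asarray(self.group_a, dtype=float)
        self.group_b = np.asarray(self.group_b, dtype=float)
        n = len(self.taxon_ids)
        if self.group_a.shape[0] != n or self.group_b.shape[0] != n:
            raise FormatError("group matrices must share the taxon axis")
        for name, mat in (("A", self.group_a), ("B", self.group_b)):
            if np.any(mat < 0) or np.any(mat > 1):
                raise FormatError(f"group {name}: relative abundances outside [0, 1]")

    @classmethod
    def from_counts(
        cls,
        taxon_ids: Sequence[str],
        counts_a: np.ndarray,
        counts_b: np.ndarray,
        label_a: str = "A",
        label_b: str = "B",
    ) -> "GroupedAbundance":
        def to_ra(counts: np.ndarray) -> np.ndarray:
            counts = np.asarray(counts, dtype=float)
            totals = counts.sum(axis=0)
            if np.any(totals == 0):
                raise PreconditionError("sample with zero total count")
            return counts / totals
        return cls(list(taxon_ids), to_ra(counts_a), to_ra(counts_b), label_a, label_b)


@dataclass(frozen=True)
class EnrichmentRow:
    taxon_id: str
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float
    stars: str
    enriched_in: Optional[str]  # group label or None ('ns')


def compare_groups(data: GroupedAbundance, test: str = "welch") -> List[EnrichmentRow]:
    """Per-taxon two-sided t test between the two groups.

    ``test`` is "welch" (unequal variances, default) or "student" (pooled).
    Degenerate taxa with zero variance in both groups get p = 1 when the
    means are equal and p = 0 when they differ.
    """
    if test not in ("welch", "student"):
        raise PreconditionError(f"unknown test {test!r}")
    a, b = data.group_a, data.group_b
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise PreconditionError("each group needs at least 2 samples")
    t_arr, p_arr = sps.ttest_ind(a, b, axis=1, equal_var=(test == "student"))
    rows: List[EnrichmentRow] = []
    for i, taxon in enumerate(data.taxon_ids):
        mean_a = float(a[i].mean())
        mean_b = float(b[i].mean())
        t, p = float(t_arr[i]), float(p_arr[i])
        if not np.isfinite(p):  # zero variance in both groups
            t, p = (0.0, 1.0) if mean_a == mean_b else (np.inf if mean_a > mean_b else -np.inf, 0.0)
        code = stars(p)
        if code == "ns":
            enriched = None
        else:
            enriched = data.label_a if mean_a > mean_b else data.label_b
        rows.append(EnrichmentRow(taxon, mean_a, mean_b, t, p, code, enriched))
    n_sig = sum(1 for r in rows if r.enriched_in is not None)
    logger.info("compare_groups (%s): %d/%d taxa starred", test, n_sig, len(rows))
    return rows


def benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    """BH-adjusted q-values (optional extra; star codes stay unadjusted)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0, 1)
    return q.tolist()


def count_enriched(
    rows: Iterable, label_a: str = "A", label_b: str = "B"
) -> Tuple[int, int]:
    """(count enriched in group A, count enriched in group B).

    Accepts any objects carrying an ``enriched_in`` attribute, so it works
    both on computed :class:`EnrichmentRow` lists and on transcribed
    published summary rows.
    """
    n_a = n_b = 0
    for row in rows:
        side = getattr(row, "enriched_in")
        if side == label_a:
            n_a += 1
        elif side == label_b:
            n_b += 1
    return n_a, n_b


@dataclass(frozen=True)
class SummaryRow:
    """One row of a published two-group summary table (means and stars only)."""

    taxon_id: str
    name: str
    mean_wt: float
    mean_ob: float
    stars: str
    enriched_in: Optional[str]


def load_published_summary(path: Optional[str | Path] = None) -> List[SummaryRow]:
    """Load the packaged transcription of a published species-level two-group
    comparison (per-species mean relative abundance in ob/ob vs wild-type
    C57BL/6J mouse cecal samples, with star-coded t-test significance).

    Per-sample data are not published for that table, so these rows support
    count-level checks only — the t statistics themselves cannot be
    recomputed from them.
    """
    if path is None:
        source = resources.files("cultcov").joinpath("data/two_group_summary.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows: List[SummaryRow] = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for rec in reader:
        sig = rec["significance"]
        if sig not in ("ns", "*", "**", "***"):
            raise FormatError(f"bad significance code {sig!r}")
        enriched = rec["enriched_in"] or None
        if sig == "ns" and enriched is not None:
            raise FormatError(f"{rec['taxon_id']}: ns row with a direction")
        if sig != "ns" and enriched not in ("OB", "WT"):
            raise FormatError(f"{rec['taxon_id']}: starred row without a direction")
        rows.append(
            SummaryRow(
                taxon_id=rec["taxon_id"],
                name=rec["name"],
                mean_wt=float(rec["ra_wt"]),
                mean_ob=float(rec["ra_ob"]),
                stars=sig,
                enriched_in=enriched,
            )
        )
    return rows
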