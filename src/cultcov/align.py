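"""Pairwise sequence-comparison engines.

Three metrics drive the taxonomy and coverage logic:

* :func:`global_identity` — semi-global (free end-gap) nucleotide identity,
  used for 16S rRNA gene comparisons at the 98% / 97% / 95% thresholds.
* :func:`fragment_ani` — fragment-based whole-genome average nucleotide
  identity (ANI): the query genome is cut into consecutive 1020-bp pieces,
  each placed at its best location in the subject, and the mean identity of
  the retained fragments is reported (species boundary ~95%).
* :func:`pocp` — percentage of conserved proteins between two proteomes,
  100*(C1+C2)/(T1+T2), a genus-level signal (boundary ~50%).

Nucleotide alignments use Biopython's pairwise aligner; fragment placement
uses exact k-mer seeding plus edlib's bit-parallel alignment; protein
alignments are Smith-Waterman with BLOSUM62 and Karlin-Altschul e-value
statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import PreconditionError
from .io import Alphabet, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for global nucleotide alignment.

    A gap of length L costs ``gap_open + L * gap_extend``, including
    terminal gap runs (plain Needleman-Wunsch).  Terminal gap runs are
    excluded from the identity DENOMINATOR instead, so trimmed 16S
    sequences of unequal length are not penalised for their overhangs while
    unrelated sequences still receive low identities.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


DEFAULT_NT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class PairwiseIdentity:
    query_id: str
    subject_id: str
    identity: float
    aligned_columns: int
    matches: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.identity <= 1.0
        assert self.matches <= self.aligned_columns


@dataclass(frozen=True)
class AniResult:
    query_id: str
    subject_id: str
    ani: Optional[float]  # percent, None when no fragment is retained
    fragments_total: int
    fragments_retained: int

    @property
    def defined(self) -> bool:
        return self.ani is not None


@dataclass(frozen=True)
class PocpResult:
    proteome_a_id: str
    proteome_b_id: str
    c1: int
    c2: int
    t1: int
    t2: int

    @property
    def pocp(self) -> float:
        return 100.0 * (self.c1 + self.c2) / (self.t1 + self.t2)


@lru_cache(maxsize=8)
def _nt_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # Biopython charges open_gap_score for the first gapped column.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _identity_from_alignment(
    alignment: Align.Alignment, target: str, query: str
) -> Tuple[int, int, Tuple[int, int]]:
    """Matches and columns between the first and last aligned pair.

    Terminal gap runs are excluded from the column count.  Returns
    (matches, columns, query_span) where query_span is the (start, end)
    range of the query covered by the alignment.
    """
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return 0, 0, (0, 0)
    matches = 0
    columns = 0
    prev_t_end: Optional[int] = None
    prev_q_end: Optional[int] = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            columns += (ts - prev_t_end) + (qs - prev_q_end)
        block_t = target[ts:te]
        block_q = query[qs:qe]
        matches += sum(1 for x, y in zip(block_t, block_q) if x == y)
        columns += te - ts
        prev_t_end, prev_q_end = te, qe
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    return int(matches), int(columns), q_span


def global_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    params: AlignmentParams = DEFAULT_NT_PARAMS,
) -> PairwiseIdentity:
    """Global (Needleman-Wunsch) nucleotide identity between two sequences.

    identity = matched columns / alignment columns, where the column count
    runs from the first to the last aligned pair, so terminal gap runs do
    not enter the denominator.  Symmetric up to co-optimal traceback ties.
    """
    for rec in (a, b):
        if rec.alphabet is not Alphabet.DNA:
            raise PreconditionError(f"{rec.id!r}: global_identity requires dna records")
        if not rec.residues:
            raise PreconditionError(f"{rec.id!r}: empty sequence")
    aligner = _nt_aligner(params)
    alignment = aligner.align(a.residues, b.residues)[0]
    matches, columns, _ = _identity_from_alignment(alignment, a.residues, b.residues)
    identity = matches / columns if columns else 0.0
    return PairwiseIdentity(a.id, b.id, identity, columns, matches)


# ---------------------------------------------------------------------------
# Fragment-based ANI
# ---------------------------------------------------------------------------

_ANI_KMER = 16
_ANI_MIN_SEED_VOTES = 2
_ANI_WINDOW_PAD = 48


def _as_contigs(genome: Sequence[SequenceRecord] | SequenceRecord) -> List[SequenceRecord]:
    if isinstance(genome, SequenceRecord):
        return [genome]
    return list(genome)


def _kmer_index(text: str, k: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = {}
    for i in range(len(text) - k + 1):
        kmer = text[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _fragments(contigs: Sequence[SequenceRecord], fragment_length: int) -> List[str]:
    frags: List[str] = []
    for contig in contigs:
        seq = contig.residues
        for start in range(0, len(seq) - fragment_length + 1, fragment_length):
            frags.append(seq[start : start + fragment_length])
    return frags


def _place_fragment(
    fragment: str,
    subject: str,
    index: Dict[str, List[int]],
    k: int,
    min_votes: int,
) -> Optional[Tuple[int, int]]:
    """Best subject window for a fragment via k-mer diagonal voting.

    Returns (window_start, window_end) or None when the fragment has no
    credible placement (fewer than ``min_votes`` seeds on its best
    diagonal) — the situation BLAST-style search reports as "no hit".
    """
    votes: Dict[int, int] = {}
    step = max(1, k // 2)
    for i in range(0, len(fragment) - k + 1, step):
        kmer = fragment[i : i + k]
        for pos in index.get(kmer, ()):  # diagonal = subject offset of fragment start
            d = pos - i
            votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    best_votes = max(votes.values())
    if best_votes < min_votes:
        return None
    diagonal = min(d for d, v in votes.items() if v == best_votes)
    start = max(0, diagonal - _ANI_WINDOW_PAD)
    end = min(len(subject), diagonal + len(fragment) + _ANI_WINDOW_PAD)
    return start, end


def _edlib_identity(query: str, window: str) -> Tuple[float, float]:
    """(identity, coverage) of a query aligned within a subject window.

    The whole query is aligned to its best location in the window (infix
    alignment); identity = matches / alignment columns, coverage = fraction
    of query bases sitting in match or mismatch columns.
    """
    res = edlib.align(query, window, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, query, window)
    bar = nice["matched_aligned"]
    matches = bar.count("|")
    columns = len(bar)
    q_aln = nice["query_aligned"]
    t_aln = nice["target_aligned"]
    paired = sum(1 for qc, tc in zip(q_aln, t_aln) if qc != "-" and tc != "-")
    return matches / columns if columns else 0.0, paired / len(query)


def fragment_ani(
    query: Sequence[SequenceRecord] | SequenceRecord,
    subject: Sequence[SequenceRecord] | SequenceRecord,
    fragment_length: int = 1020,
    retain_identity: float = 0.30,
    retain_coverage: float = 0.70,
    query_id: Optional[str] = None,
    subject_id: Optional[str] = None,
) -> AniResult:
    """Fragment-based average nucleotide identity of query against subject.

    The query is cut into consecutive non-overlapping fragments (terminal
    remainder dropped); each fragment is aligned to its best subject
    location; fragments with identity > ``retain_identity`` over more than
    ``retain_coverage`` of their length are retained; ANI is the mean
    retained identity in percent.  With no retained fragment the ANI is
    undefined (``ani=None``) — never reported as 0.
    """
    q_contigs = _as_contigs(query)
    s_contigs = _as_contigs(subject)
    if not q_contigs or not s_contigs:
        raise PreconditionError("fragment_ani requires nonempty genomes")
    qid = query_id or q_contigs[0].id
    sid = subject_id or s_contigs[0].id

    # Join subject contigs with an N-spacer so no k-mer spans a boundary.
    subject_text = ("N" * _ANI_KMER).join(c.residues for c in s_contigs)
    index = _kmer_index(subject_text, _ANI_KMER)
    frags = _fragments(q_contigs, fragment_length)

    identities: List[float] = []
    for frag in frags:
        window = _place_fragment(frag, subject_text, index, _ANI_KMER, _ANI_MIN_SEED_VOTES)
        if window is None:
            continue
        identity, coverage = _edlib_identity(frag, subject_text[window[0] : window[1]])
        if identity > retain_identity and coverage > retain_coverage:
            identities.append(identity)
    ani = 100.0 * sum(identities) / len(identities) if identities else None
    logger.info(
        "fragment_ani %s vs %s: %d/%d fragments retained, ani=%s",
        qid, sid, len(identities), len(frags),
        f"{ani:.2f}" if ani is not None else "undefined",
    )
    return AniResult(qid, sid, ani, len(frags), len(identities))


# ---------------------------------------------------------------------------
# Protein local alignment, e-value statistics, POCP
# ---------------------------------------------------------------------------

# Karlin-Altschul parameters for gapped BLOSUM62 with gap cost 11 + k
# (the BLASTp defaults).
_KA_LAMBDA = 0.267
_KA_K = 0.041


@lru_cache(maxsize=1)
def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # gap of length L costs 11 + L
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def karlin_altschul_evalue(score: float, query_length: int, db_length: int) -> float:
    """BLAST-style expect value E = K * m * n * exp(-lambda * S)."""
    return _KA_K * query_length * db_length * math.exp(-_KA_LAMBDA * score)


@dataclass(frozen=True)
class ProteinHit:
    query_id: str
    subject_id: str
    identity: float
    query_coverage: float
    score: float
    evalue: float


def best_protein_hits(
    query: SequenceRecord,
    subjects: Sequence[SequenceRecord],
    db_length: Optional[int] = None,
) -> List[ProteinHit]:
    """Smith-Waterman of one protein against each subject protein."""
    if query.alphabet is not Alphabet.PROTEIN:
        raise PreconditionError(f"{query.id!r}: protein record required")
    n = db_length if db_length is not None else sum(len(s) for s in subjects)
    aligner = _protein_aligner()
    hits: List[ProteinHit] = []
    for subj in subjects:
        alignment = aligner.align(subj.residues, query.residues)[0]
        matches, columns, q_span = _identity_from_alignment(
            alignment, subj.residues, query.residues
        )
        identity = matches / columns if columns else 0.0
        qcov = (q_span[1] - q_span[0]) / len(query)
        evalue = karlin_altschul_evalue(alignment.score, len(query), n)
        hits.append(ProteinHit(query.id, subj.id, identity, qcov, alignment.score, evalue))
    return hits


def has_conserved_match(
    query: SequenceRecord,
    subjects: Sequence[SequenceRecord],
    min_identity: float,
    min_alignable: float,
    evalue_max: Optional[float],
    db_length: Optional[int] = None,
) -> bool:
    """True when some subject matches the query at the given thresholds.

    The alignable-region condition is measured against the QUERY length.
    ``evalue_max=None`` disables the e-value condition (identity and
    alignable region only).
    """
    for hit in best_protein_hits(query, subjects, db_length):
        if hit.identity >= min_identity and hit.query_coverage >= min_alignable:
            if evalue_max is None or hit.evalue <= evalue_max:
                return True
    return False


def pocp(
    a: Sequence[SequenceRecord],
    b: Sequence[SequenceRecord],
    evalue_max: Optional[float] = 1e-5,
    min_identity: float = 0.40,
    min_alignable: float = 0.50,
    a_id: str = "A",
    b_id: str = "B",
) -> PocpResult:
    """Percentage of conserved proteins between two proteomes.

    A protein counts as conserved when it has a match in the other proteome
    with identity >= ``min_identity`` over an alignable region >=
    ``min_alignable`` of its own length and e-value <= ``evalue_max``.
    POCP = 100 * (C1 + C2) / (T1 + T2), symmetric by construction.
    """
    a = list(a)
    b = list(b)
    if not a or not b:
        raise PreconditionError("pocp requires nonempty proteomes")
    len_a = sum(len(p) for p in a)
    len_b = sum(len(p) for p in b)
    c1 = sum(
        has_conserved_match(p, b, min_identity, min_alignable, evalue_max, len_b)
        for p in a
    )
    c2 = sum(
        has_conserved_match(p, a, min_identity, min_alignable, evalue_max, len_a)
        for p in b
    )
    result = PocpResult(a_id, b_id, c1, c2, len(a), len(b))
    logger.info(
        "pocp %s vs %s: c1=%d/%d c2=%d/%d pocp=%.2f",
        a_id, b_id, c1, len(a), c2, len(b), result.pocp,
    )
    return result
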