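"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and seed and returns
its planted ground truth alongside the data, so every pipeline stage has a
parameter-recovery test.  The generators emulate the statistical structure
of the real inputs — pairwise 16S divergence, per-genus occupancy and
abundance, genome pairs at a target ANI, binary KO profiles with controlled
redundancy, and two-group abundance matrices with planted fold changes —
not their biological detail (no secondary structure, chimeras, or
read-level error models).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .corepan import GenusStats
from .enrich import GroupedAbundance
from .errors import PreconditionError
from .funcover import KoProfile
from .io import Alphabet, OtuTable, SequenceRecord

_DNA = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def random_dna(length: int, rng: np.random.Generator, seq_id: str = "seq") -> SequenceRecord:
    residues = "".join(rng.choice(_DNA, size=length))
    return SequenceRecord(seq_id, residues, alphabet=Alphabet.DNA)


def random_protein(length: int, rng: np.random.Generator, seq_id: str = "prot") -> SequenceRecord:
    residues = "".join(rng.choice(_AA, size=length))
    return SequenceRecord(seq_id, residues, alphabet=Alphabet.PROTEIN)


@dataclass(frozen=True)
class DivergenceSpec:
    """Substitution/indel process applied to an ancestor sequence."""

    substitution_rate: float
    indel_rate: float = 0.0
    mean_indel_length: float = 2.0  # geometric
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate < 1.0):
            raise PreconditionError("substitution_rate must be in [0, 1)")
        if not (0.0 <= self.indel_rate < 1.0):
            raise PreconditionError("indel_rate must be in [0, 1)")


@dataclass(frozen=True)
class MutationEvent:
    position: int          # position in the ancestor
    kind: str              # "sub" | "ins" | "del"
    length: int = 1
    detail: str = ""


@dataclass
class MutationMap:
    """Record of every mutation event, for exact oracle bookkeeping."""

    events: List[MutationEvent] = field(default_factory=list)

    @property
    def n_substitutions(self) -> int:
        return sum(1 for e in self.events if e.kind == "sub")

    def substituted_positions(self) -> Set[int]:
        return {e.position for e in self.events if e.kind == "sub"}


def mutate_sequence(
    seq: SequenceRecord, spec: DivergenceSpec, out_id: Optional[str] = None
) -> Tuple[SequenceRecord, MutationMap]:
    """Apply i.i.d. substitutions and geometric-length indels to a sequence.

    Substitutions replace a base with a uniformly chosen different base.
    Deterministic given the spec's seed; rate 0 returns the input unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    mutmap = MutationMap()
    out: List[str] = []
    alphabet = "ACGT" if seq.alphabet is Alphabet.DNA else "ACDEFGHIKLMNPQRSTVWY"
    residues_in = seq.residues
    n = len(residues_in)
    i = 0
    while i < n:
        if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
            length = int(rng.geometric(1.0 / spec.mean_indel_length))
            if rng.random() < 0.5:
                # delete `length` ancestor bases starting here
                mutmap.events.append(MutationEvent(i, "del", min(length, n - i)))
                i += length
                continue
            insert = "".join(rng.choice(list(alphabet), size=length))
            mutmap.events.append(MutationEvent(i, "ins", length, insert))
            out.append(insert)
        base = residues_in[i]
        if spec.substitution_rate > 0 and rng.random() < spec.substitution_rate:
            choices = [c for c in alphabet if c != base]
            new = choices[rng.integers(len(choices))]
            mutmap.events.append(MutationEvent(i, "sub", 1, new))
            out.append(new)
        else:
            out.append(base)
        i += 1
    residues = "".join(out)
    rec = SequenceRecord(
        out_id or f"{seq.id}_mut", residues, alphabet=seq.alphabet
    )
    return rec, mutmap


@dataclass(frozen=True)
class CommunitySpec:
    """Planted per-genus occupancy/abundance structure of a mock community."""

    genera: Tuple[str, ...]
    occupancy: Tuple[float, ...]       # Bernoulli presence per sample
    ra_targets: Tuple[float, ...]      # mean relative abundance targets
    n_samples: int = 50
    reads_per_sample: int = 10_000
    rep_seq_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.genera)
        if len(self.occupancy) != n or len(self.ra_targets) != n:
            raise PreconditionError("genera, occupancy, ra_targets must align")
        if any(not (0 <= o <= 1) for o in self.occupancy):
            raise PreconditionError("occupancy targets must be in [0, 1]")
        if any(r < 0 for r in self.ra_targets) or sum(self.ra_targets) > 1 + 1e-9:
            raise PreconditionError("RA targets must be nonnegative and sum <= 1")


def gen_community(spec: CommunitySpec) -> Tuple[OtuTable, List[GenusStats]]:
    """Generate an OTU table with planted genus occupancy and abundance.

    One OTU per genus.  Per sample, each genus is present with its planted
    occupancy; reads are drawn multinomially with probabilities equal to
    the RA targets renormalised over the present genera.  Returns the table
    and the planted truth as :class:`GenusStats` (classification unset).
    """
    rng = np.random.default_rng(spec.seed)
    n_gen = len(spec.genera)
    otu_ids = [f"otu_{i + 1:03d}" for i in range(n_gen)]
    sample_ids = [f"sample_{j + 1:03d}" for j in range(spec.n_samples)]
    counts = np.zeros((n_gen, spec.n_samples), dtype=np.int64)
    ra = np.asarray(spec.ra_targets, dtype=float)
    for j in range(spec.n_samples):
        present = rng.random(n_gen) < np.asarray(spec.occupancy)
        if spec.reads_per_sample == 0 or not present.any():
            continue
        p = np.where(present, ra, 0.0)
        if p.sum() == 0:
            continue
        counts[:, j] = rng.multinomial(spec.reads_per_sample, p / p.sum())
    rep_seqs = {
        oid: random_dna(spec.rep_seq_length, rng, seq_id=oid) for oid in otu_ids
    }
    genus_labels = dict(zip(otu_ids, spec.genera))
    table = OtuTable(otu_ids, sample_ids, counts, rep_seqs, genus_labels)
    planted = [
        GenusStats(g, o, r)
        for g, o, r in zip(spec.genera, spec.occupancy, spec.ra_targets)
    ]
    return table, planted


def gen_genome_pair(
    ani_target: float, length: int, seed: int = 0
) -> Tuple[SequenceRecord, SequenceRecord, MutationMap]:
    """Genome pair at a target ANI (substitutions only, exact oracle map).

    The second genome differs from the first by i.i.d. substitutions at
    rate 1 - ani_target/100, so the map gives the exact per-fragment
    mismatch counts.  Sensible for ani_target in about [70, 100].
    """
    if not (0 < ani_target <= 100):
        raise PreconditionError("ani_target must be in (0, 100]")
    rng = np.random.default_rng(seed)
    ancestor = random_dna(length, rng, seq_id="genomeA")
    spec = DivergenceSpec(
        substitution_rate=1.0 - ani_target / 100.0,
        indel_rate=0.0,
        seed=int(rng.integers(2**31)),
    )
    derived, mutmap = mutate_sequence(ancestor, spec, out_id="genomeB")
    return ancestor, derived, mutmap


def gen_proteome_pair(
    n_proteins: int,
    n_conserved: int,
    protein_length: int = 120,
    conserved_sub_rate: float = 0.10,
    seed: int = 0,
) -> Tuple[List[SequenceRecord], List[SequenceRecord], Set[str]]:
    """Proteome pair where exactly ``n_conserved`` proteins are homologous.

    Proteome B keeps slightly diverged copies of the first ``n_conserved``
    proteins of A and replaces the rest with unrelated random proteins.
    Returns (A, B, ids of conserved A proteins).
    """
    if n_conserved > n_proteins:
        raise PreconditionError("n_conserved cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    a = [random_protein(protein_length, rng, seq_id=f"a_{i:03d}") for i in range(n_proteins)]
    b: List[SequenceRecord] = []
    conserved: Set[str] = set()
    for i, prot in enumerate(a):
        if i < n_conserved:
            spec = DivergenceSpec(conserved_sub_rate, 0.0, seed=int(rng.integers(2**31)))
            variant, _ = mutate_sequence(prot, spec, out_id=f"b_{i:03d}")
            b.append(variant)
            conserved.add(prot.id)
        else:
            b.append(random_protein(protein_length, rng, seq_id=f"b_{i:03d}"))
    return a, b, conserved


def gen_ko_profiles(
    n_genomes: int,
    universe: int,
    target_pool: int,
    overlap_per_genome: float,
    redundancy: float,
    seed: int = 0,
    offtarget_per_genome: int = 20,
) -> Tuple[List[KoProfile], KoProfile, float]:
    """Binary KO profiles with controlled overlap against a metagenome pool.

    Each genome carries ``overlap_per_genome * target_pool`` KOs from the
    target pool; a ``redundancy`` share of those comes from a core subset
    common to all genomes (redundancy 1 makes all genomes identical on the
    target), plus some off-target KOs.  Returns (profiles, target profile,
    exact union coverage of the target by all profiles).
    """
    if not (0 <= overlap_per_genome <= 1 and 0 <= redundancy <= 1):
        raise PreconditionError("overlap_per_genome and redundancy must be in [0, 1]")
    if target_pool > universe:
        raise PreconditionError("target_pool cannot exceed universe")
    rng = np.random.default_rng(seed)
    all_kos = np.array([f"K{i + 1:05d}" for i in range(universe)])
    target_ids = rng.choice(universe, size=target_pool, replace=False)
    target = KoProfile("metagenome", frozenset(all_kos[target_ids]))
    off_target = np.setdiff1d(np.arange(universe), target_ids)

    per_genome = int(round(overlap_per_genome * target_pool))
    n_core = int(round(redundancy * per_genome))
    core = rng.choice(target_ids, size=min(n_core, target_pool), replace=False)
    profiles: List[KoProfile] = []
    for g in range(n_genomes):
        rest_pool = np.setdiff1d(target_ids, core)
        n_rest = per_genome - len(core)
        rest = (
            rng.choice(rest_pool, size=min(n_rest, len(rest_pool)), replace=False)
            if n_rest > 0 and len(rest_pool)
            else np.array([], dtype=int)
        )
        extra = (
            rng.choice(off_target, size=min(offtarget_per_genome, len(off_target)), replace=False)
            if len(off_target)
            else np.array([], dtype=int)
        )
        kos = frozenset(all_kos[np.concatenate([core, rest, extra]).astype(int)])
        profiles.append(KoProfile(f"genome_{g + 1:03d}", kos))
    union: Set[str] = set()
    for p in profiles:
        union |= p.kos
    planted_coverage = len(union & target.kos) / len(target.kos) if target_pool else 0.0
    return profiles, target, planted_coverage


def gen_two_group_ra(
    n_taxa: int,
    n_per_group: int,
    effect_taxa: Dict[str, float],
    noise_sd: float = 0.3,
    seed: int = 0,
    label_a: str = "A",
    label_b: str = "B",
) -> Tuple[GroupedAbundance, Dict[str, str]]:
    """Two-group log-normal abundance matrices with planted fold changes.

    Taxa are named ``taxon_001``...; ``effect_taxa`` maps taxon id to the
    fold change of group A relative to group B (fold > 1 plants enrichment
    in A).  Returns the data and the planted enrichment direction per
    affected taxon.
    """
    if any(f <= 0 for f in effect_taxa.values()):
        raise PreconditionError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    taxon_ids = [f"taxon_{i + 1:03d}" for i in range(n_taxa)]
    unknown = set(effect_taxa) - set(taxon_ids)
    if unknown:
        raise PreconditionError(f"effect taxa not in the table: {sorted(unknown)[:5]}")
    # baseline mean RA around 1e-3 on the log10 scale
    base_log = rng.uniform(math.log(2e-4), math.log(5e-3), size=n_taxa)
    a = np.empty((n_taxa, n_per_group))
    b = np.empty((n_taxa, n_per_group))
    planted: Dict[str, str] = {}
    for i, taxon in enumerate(taxon_ids):
        fold = effect_taxa.get(taxon, 1.0)
        mu_a = base_log[i] + math.log(fold) / 2
        mu_b = base_log[i] - math.log(fold) / 2
        a[i] = np.exp(rng.normal(mu_a, noise_sd, size=n_per_group))
        b[i] = np.exp(rng.normal(mu_b, noise_sd, size=n_per_group))
        if taxon in effect_taxa and fold != 1.0:
            planted[taxon] = label_a if fold > 1 else label_b
    a = np.clip(a, 0.0, 1.0)
    b = np.clip(b, 0.0, 1.0)
    data = GroupedAbundance(taxon_ids, a, b, label_a, label_b)
    return data, planted


def gen_reference_and_isolates(
    n_assignable: int,
    n_novel: int,
    n_references: int = 20,
    seq_length: int = 250,
    close_rate: float = 0.005,
    far_rate: float = 0.12,
    seed: int = 0,
) -> Tuple[List[SequenceRecord], List[SequenceRecord], Dict[str, bool]]:
    """Reference 16S set plus isolates with planted assignability.

    ``n_assignable`` isolates are near-copies of references (divergence
    ``close_rate``, identity well above 98%); ``n_novel`` isolates diverge
    at ``far_rate`` (identity well below 98%).  Returns (references,
    isolates, planted truth: isolate id -> should be assignable).
    """
    rng = np.random.default_rng(seed)
    refs = [
        random_dna(seq_length, rng, seq_id=f"ref_{i + 1:03d}")
        for i in range(n_references)
    ]
    isolates: List[SequenceRecord] = []
    truth: Dict[str, bool] = {}
    for i in range(n_assignable + n_novel):
        assignable = i < n_assignable
        parent = refs[int(rng.integers(len(refs)))]
        rate = close_rate if assignable else far_rate
        spec = DivergenceSpec(rate, 0.0, seed=int(rng.integers(2**31)))
        iso, _ = mutate_sequence(parent, spec, out_id=f"iso_{i + 1:04d}")
        isolates.append(iso)
        truth[iso.id] = assignable
    return refs, isolates, truth
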