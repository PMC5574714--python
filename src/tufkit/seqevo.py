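"""Sequence-level analyses for EF-Tu homolog sets.

Covers global pairwise identity (Needleman–Wunsch), Poisson-corrected
evolutionary distance, patristic (branch-length) distance on newick trees,
divergence normalization, the viability-discriminating alignment-column
filter, structural-domain partitioning of discriminating positions, and the
codon adaptation index.

The discriminating-column filter formalizes a simple comparative rule: an
alignment column is a candidate determinant of viability when every homolog
that supports viability carries one identical (non-gap) residue there while
at least one non-supporting homolog differs (a gap counts as differing).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SequenceError",
    "ProteinSequence",
    "LabeledAlignment",
    "DivergenceEstimate",
    "DiscriminatingResidueReport",
    "DomainDefinition",
    "CaiResult",
    "EFTU_DOMAINS",
    "pairwise_identity",
    "poisson_distance",
    "patristic_distance",
    "normalize_divergence",
    "find_discriminating_residues",
    "partition_by_domain",
    "codon_adaptation_index",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = set("-.")
STOP_CODONS = {"TAA", "TAG", "TGA"}
SINGLE_CODON_AA = {"ATG", "TGG"}   # Met and Trp have no synonymous choice


class SequenceError(ValueError):
    """Raised for invalid sequences, alignments or codon input."""


@dataclass
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - AMINO_ACIDS - GAP_CHARS - {"X"}
        if bad:
            raise SequenceError(f"sequence {self.id!r} has invalid characters {sorted(bad)}")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return "".join(c for c in self.residues if c not in GAP_CHARS)


VALID_LABELS = ("viable", "nonviable", "reference")


@dataclass
class LabeledAlignment:
    """Equal-length gapped protein sequences with per-row viability labels.

    The ``reference`` row (at most one) counts as viable and anchors
    residue-position numbering.
    """

    sequences: list[ProteinSequence]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise SequenceError("one label per sequence required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise SequenceError(f"ragged alignment: row lengths {sorted(lengths)}")
        for lab in self.labels:
            if lab not in VALID_LABELS:
                raise SequenceError(f"invalid label {lab!r}; expected one of {VALID_LABELS}")
        if self.labels.count("reference") > 1:
            raise SequenceError("at most one reference sequence permitted")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def reference(self) -> ProteinSequence | None:
        for seq, lab in zip(self.sequences, self.labels):
            if lab == "reference":
                return seq
        return None

    def rows(self, label: str) -> list[ProteinSequence]:
        return [s for s, lab in zip(self.sequences, self.labels) if lab == label]


@dataclass
class DivergenceEstimate:
    p_distance: float          # proportion of differing positions
    poisson_d: float           # -ln(1 - p), substitutions/site; inf when p == 1
    positions_used: int
    normalized: float | None = None


@dataclass
class DiscriminatingResidueReport:
    columns: list[int]                       # 1-based alignment columns
    reference_positions: list[int]           # 1-based ungapped reference coords
    per_domain_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.columns)


@dataclass
class DomainDefinition:
    name: str
    start: int     # 1-based inclusive, reference coordinates
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise SequenceError(f"domain {self.name}: invalid interval {self.start}-{self.end}")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


# conventional three-domain structural split of the 393-residue E. coli EF-Tu:
# the GTP-binding G domain followed by the two beta-barrel domains
EFTU_DOMAINS = [
    DomainDefinition("G-domain", 1, 200),
    DomainDefinition("domain2", 201, 299),
    DomainDefinition("domain3", 300, 393),
]


@dataclass
class CaiResult:
    cai: float
    codons_used: int
    weights_source: str = ""


# ---------------------------------------------------------------------------
# pairwise identity (global alignment)
# ---------------------------------------------------------------------------

def _make_aligner(gap_open: float, gap_extend: float, matrix_name: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # EMBOSS-needle convention: 'open' is charged for the first gap position
    aligner.open_gap_score = -(gap_open)
    aligner.extend_gap_score = -(gap_extend)
    return aligner


def pairwise_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix_name: str = "BLOSUM62",
) -> tuple[float, tuple[str, str]]:
    """Percent identity from a Needleman–Wunsch global alignment.

    Identity is the number of identical aligned residue pairs divided by the
    full alignment length (gap columns included), times 100 — the convention
    EMBOSS needle reports.  Returns (percent_identity, (aligned_a, aligned_b)).
    """
    if not a.ungapped or not b.ungapped:
        raise SequenceError("cannot align an empty sequence")
    aligner = _make_aligner(gap_open, gap_extend, matrix_name)
    aln = aligner.align(a.ungapped, b.ungapped)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(row_a, row_b) if x == y and x not in GAP_CHARS)
    pct = 100.0 * identical / len(row_a)
    return pct, (row_a, row_b)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def poisson_distance(
    a_aligned: str | ProteinSequence,
    b_aligned: str | ProteinSequence,
    gap_policy: str = "complete",
) -> DivergenceEstimate:
    """Poisson-corrected amino acid distance between two aligned rows.

    Columns containing a gap in either row are eliminated ("complete
    deletion"); ``gap_policy="pairwise"`` gives the same result for a single
    pair but is accepted for API symmetry with multi-row use.  The corrected
    distance is d = −ln(1 − p) with p the proportion of differing positions;
    p = 1 yields an infinite-distance flag rather than an error.
    """
    sa = a_aligned.residues if isinstance(a_aligned, ProteinSequence) else a_aligned.upper()
    sb = b_aligned.residues if isinstance(b_aligned, ProteinSequence) else b_aligned.upper()
    if len(sa) != len(sb):
        raise SequenceError("aligned rows must have equal length")
    if gap_policy not in ("complete", "pairwise"):
        raise SequenceError(f"unknown gap_policy {gap_policy!r}")
    pairs = [(x, y) for x, y in zip(sa, sb) if x not in GAP_CHARS and y not in GAP_CHARS]
    if not pairs:
        raise SequenceError("no gap-free positions available for distance")
    n = len(pairs)
    mismatches = sum(1 for x, y in pairs if x != y)
    p = mismatches / n
    d = math.inf if p >= 1.0 else -math.log(1.0 - p)
    return DivergenceEstimate(p_distance=p, poisson_d=d, positions_used=n)


def patristic_distance(tree: str | dendropy.Tree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths along the path between two leaves of a newick tree."""
    if isinstance(tree, str):
        src = io.StringIO(tree) if tree.lstrip().startswith("(") else open(tree)
        with src:
            tree = dendropy.Tree.get(file=src, schema="newick")
    taxa = {t.label: t for t in tree.taxon_namespace}
    for name in (leaf_a, leaf_b):
        if name not in taxa:
            raise SequenceError(f"leaf {name!r} not found in tree")
    if leaf_a == leaf_b:
        return 0.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise SequenceError("tree has missing branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    return float(pdm.patristic_distance(taxa[leaf_a], taxa[leaf_b]))


def normalize_divergence(distances: dict[str, float]) -> dict[str, float]:
    """Scale distances so the most divergent entry maps to 1.0."""
    if not distances:
        raise SequenceError("empty distance map")
    mx = max(distances.values())
    if mx <= 0:
        raise SequenceError("all distances are zero; nothing to normalize")
    return {k: v / mx for k, v in distances.items()}


# ---------------------------------------------------------------------------
# viability-discriminating columns
# ---------------------------------------------------------------------------

def find_discriminating_residues(
    aln: LabeledAlignment,
    domains: list[DomainDefinition] | None = None,
) -> DiscriminatingResidueReport:
    """Columns identical in every viable homolog but variant in ≥1 nonviable.

    A column qualifies iff all viable rows (the reference included) carry the
    same non-gap residue and at least one nonviable row differs from it, a
    gap counting as a difference.  Reported alignment columns are 1-based;
    positions are also mapped onto ungapped reference coordinates when a
    reference row is present, and optionally partitioned by domain.
    """
    viable = aln.rows("viable") + aln.rows("reference")
    nonviable = aln.rows("nonviable")
    if not viable or not nonviable:
        raise SequenceError("discrimination needs >=1 viable (or reference) and >=1 nonviable row")

    columns: list[int] = []
    for c in range(aln.length):
        vres = {s.residues[c] for s in viable}
        if len(vres) != 1:
            continue
        res = next(iter(vres))
        if res in GAP_CHARS:
            continue
        if any(s.residues[c] != res for s in nonviable):
            columns.append(c + 1)

    ref = aln.reference
    ref_positions: list[int] = []
    if ref is not None:
        # cumulative ungapped position of each alignment column on the reference
        pos = 0
        col_to_ref: dict[int, int] = {}
        for c, ch in enumerate(ref.residues):
            if ch not in GAP_CHARS:
                pos += 1
                col_to_ref[c + 1] = pos
        # qualifying columns are never gapped in the reference (it is viable)
        ref_positions = [col_to_ref[c] for c in columns]

    report = DiscriminatingResidueReport(columns=columns, reference_positions=ref_positions)
    if domains is not None:
        report.per_domain_counts = partition_by_domain(report, domains)
    return report


def partition_by_domain(
    report: DiscriminatingResidueReport,
    domains: list[DomainDefinition],
) -> dict[str, int]:
    """Count discriminating reference positions per structural domain.

    Positions falling outside every domain are tallied under ``"outside"``.
    Overlapping domain definitions are rejected.
    """
    ordered = sorted(domains, key=lambda d: d.start)
    for d1, d2 in zip(ordered, ordered[1:]):
        if d2.start <= d1.end:
            raise SequenceError(f"domains {d1.name} and {d2.name} overlap")
    counts = {d.name: 0 for d in domains}
    outside = 0
    for pos in report.reference_positions:
        for d in domains:
            if pos in d:
                counts[d.name] += 1
                break
        else:
            outside += 1
    if outside:
        counts["outside"] = outside
    return counts


# ---------------------------------------------------------------------------
# codon adaptation index
# ---------------------------------------------------------------------------

def codon_adaptation_index(
    cds: str,
    weights: dict[str, float],
    weights_source: str = "",
) -> CaiResult:
    """CAI as the geometric mean of relative-adaptiveness codon weights.

    Codons for Met (ATG), Trp (TGG) and the stop codons carry no synonymous
    choice and are excluded.  All included codons must have a positive weight
    in the supplied table.
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise SequenceError(f"coding sequence length {len(seq)} is not a multiple of 3")
    log_sum = 0.0
    n = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if any(c not in "ACGT" for c in codon):
            raise SequenceError(f"invalid codon {codon!r} at position {i + 1}")
        if codon in SINGLE_CODON_AA or codon in STOP_CODONS:
            continue
        if codon not in weights:
            raise SequenceError(f"no weight supplied for codon {codon!r}")
        w = weights[codon]
        if w <= 0:
            raise SequenceError(f"non-positive weight {w} for codon {codon!r}")
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise SequenceError("no weighted codons in sequence")
    return CaiResult(cai=math.exp(log_sum / n), codons_used=n, weights_source=weights_source)
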