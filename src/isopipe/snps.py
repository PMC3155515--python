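"""Rule-based SNP calling from isotig read stacks.

A biallelic site is called when the column depth is at least 6 reads and the
minor allele reaches 30% of the non-N reads; candidates flanked by
ambiguous-identity neighbours are removed; per gene, only the isotig with
the most surviving calls is kept (non-redundant set). Substitutions are
classified as A<->G/C<->T (transitions), A<->C/G<->T, A<->T and G<->C, and
summarized for the full set and for the high-depth (>=31) subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import IsotigAssembly
from .syndata import revcomp

_BASE_IDX = {b: i for i, b in enumerate("ACGTN")}

MIN_DEPTH = 6
MIN_FRACTION = 0.30
HIGH_DEPTH = 31
FLANK_N_FRACTION = 0.20


@dataclass
class PileupColumn:
    isotig_id: str
    position: int
    base_counts: tuple[int, int, int, int, int]  # A, C, G, T, N
    consensus_base: str

    @property
    def depth(self) -> int:
        return int(sum(self.base_counts))

    @property
    def non_n_depth(self) -> int:
        return int(sum(self.base_counts[:4]))

    @property
    def n_count(self) -> int:
        return int(self.base_counts[4])


@dataclass
class SnpCall:
    isotig_id: str
    position: int
    major_allele: str
    minor_allele: str
    depth: int
    minor_fraction: float
    gene_id: str | None = None

    @property
    def substitution_class(self) -> str:
        return classify_substitution(self.major_allele, self.minor_allele)

    @property
    def is_transition(self) -> bool:
        return self.substitution_class == "AG_CT"

    @property
    def high_depth(self) -> bool:
        return self.depth >= HIGH_DEPTH


def pileup_matrix(assembly: IsotigAssembly) -> np.ndarray:
    """5 x L base-count matrix (A,C,G,T,N) over the consensus columns.

    Minus-strand reads are reverse-complemented into consensus orientation
    before counting.
    """
    L = len(assembly.consensus)
    counts = np.zeros((5, L), dtype=np.int32)
    for read in assembly.reads:
        seq = revcomp(read.seq) if read.strand == "-" else read.seq
        for i, base in enumerate(seq):
            counts[_BASE_IDX[base], read.offset + i] += 1
    return counts


def pileup(assembly: IsotigAssembly) -> list[PileupColumn]:
    """One column per consensus position with at least one covering read."""
    counts = pileup_matrix(assembly)
    cols = []
    for pos in np.nonzero(counts.sum(axis=0))[0]:
        cols.append(
            PileupColumn(
                assembly.isotig_id,
                int(pos),
                tuple(int(c) for c in counts[:, pos]),
                assembly.consensus[pos],
            )
        )
    return cols


def call_candidates(
    columns: list[PileupColumn],
    min_depth: int = MIN_DEPTH,
    min_fraction: float = MIN_FRACTION,
) -> list[SnpCall]:
    """Depth and minor-allele-frequency screen.

    The minor fraction is computed over non-N reads ('N' is absence of
    evidence, never an allele). A third allele at or above the threshold
    invalidates the column (flagged biallelic violation, not called). Ties
    for major/minor are broken alphabetically.
    """
    calls = []
    for col in columns:
        if col.depth < min_depth:
            continue
        non_n = col.non_n_depth
        if non_n == 0:
            continue
        acgt = col.base_counts[:4]
        order = sorted(range(4), key=lambda i: (-acgt[i], "ACGT"[i]))
        major_i, minor_i, third_i = order[0], order[1], order[2]
        if acgt[minor_i] == 0:
            continue
        minor_frac = acgt[minor_i] / non_n
        if minor_frac < min_fraction:
            continue
        if acgt[third_i] / non_n >= min_fraction:
            continue  # triallelic column: flagged, not called
        calls.append(
            SnpCall(
                col.isotig_id,
                col.position,
                "ACGT"[major_i],
                "ACGT"[minor_i],
                col.depth,
                minor_frac,
            )
        )
    return calls


def filter_flanking(
    calls: list[SnpCall],
    columns: list[PileupColumn],
    consensus: str,
    max_n_fraction: float = FLANK_N_FRACTION,
) -> list[SnpCall]:
    """Remove candidates whose immediate neighbours have ambiguous identity.

    A flank is ambiguous when the consensus base there is N, the position has
    zero read coverage, or more than ``max_n_fraction`` of its covering reads
    carry N. Calls at the consensus ends are judged on the existing side only.
    """
    by_pos = {c.position: c for c in columns}

    def flank_ok(pos: int) -> bool:
        if pos < 0 or pos >= len(consensus):
            return True  # no flank on this side
        if consensus[pos] == "N":
            return False
        col = by_pos.get(pos)
        if col is None or col.depth == 0:
            return False
        return col.n_count / col.depth <= max_n_fraction

    return [c for c in calls if flank_ok(c.position - 1) and flank_ok(c.position + 1)]


def dedupe_per_gene(
    calls: list[SnpCall],
    isotig_gene: dict[str, str | None],
    isotig_coverage: dict[str, int] | None = None,
) -> list[SnpCall]:
    """Keep, per gene, only the isotig with the most surviving calls.

    Ties go to the isotig with larger chained coverage, then the
    lexicographically smaller id. Isotigs without a gene mapping are kept as
    their own units, and calls are annotated with their gene id.
    """
    isotig_coverage = isotig_coverage or {}
    per_isotig: dict[str, list[SnpCall]] = {}
    for c in calls:
        per_isotig.setdefault(c.isotig_id, []).append(c)

    per_gene: dict[str, list[str]] = {}
    unmapped = []
    for iso in per_isotig:
        gene = isotig_gene.get(iso)
        if gene is None:
            unmapped.append(iso)
        else:
            per_gene.setdefault(gene, []).append(iso)

    kept: list[SnpCall] = []
    for gene in sorted(per_gene):
        isotigs = per_gene[gene]
        winner = min(
            isotigs,
            key=lambda i: (-len(per_isotig[i]), -isotig_coverage.get(i, 0), i),
        )
        for c in per_isotig[winner]:
            c.gene_id = gene
            kept.append(c)
    for iso in sorted(unmapped):
        kept.extend(per_isotig[iso])
    return kept


_CLASS = {
    frozenset("AG"): "AG_CT",
    frozenset("CT"): "AG_CT",
    frozenset("AC"): "AC_GT",
    frozenset("GT"): "AC_GT",
    frozenset("AT"): "AT",
    frozenset("CG"): "GC",
}


def classify_substitution(major: str, minor: str) -> str:
    """Unordered substitution class; AG_CT is the transition class."""
    try:
        return _CLASS[frozenset((major, minor))]
    except KeyError:
        raise ValueError(f"not a biallelic substitution: {major}/{minor}") from None


CLASS_ORDER = ("AG_CT", "AC_GT", "AT", "GC")


@dataclass
class SnpSummary:
    n_calls: int
    n_genes: int
    class_counts: dict[str, int]
    transition_pct: int | None  # rounded to the nearest integer; None if empty

    @classmethod
    def from_class_counts(cls, counts: dict[str, int], n_genes: int = 0):
        total = sum(counts.values())
        pct = int(round(100.0 * counts.get("AG_CT", 0) / total)) if total else None
        full = {k: int(counts.get(k, 0)) for k in CLASS_ORDER}
        return cls(total, n_genes, full, pct)


@dataclass
class SnpReport:
    all: SnpSummary
    high_depth: SnpSummary


def summarize(calls: list[SnpCall], high_depth: int = HIGH_DEPTH) -> SnpReport:
    """Tallies for the full call set and the depth >= ``high_depth`` subset."""

    def tally(subset):
        counts = {k: 0 for k in CLASS_ORDER}
        genes = set()
        for c in subset:
            counts[c.substitution_class] += 1
            genes.add(c.gene_id if c.gene_id is not None else c.isotig_id)
        return SnpSummary.from_class_counts(counts, len(genes))

    return SnpReport(
        all=tally(calls),
        high_depth=tally([c for c in calls if c.depth >= high_depth]),
    )


def call_snps(
    assembly: IsotigAssembly,
    min_depth: int = MIN_DEPTH,
    min_fraction: float = MIN_FRACTION,
    max_n_fraction: float = FLANK_N_FRACTION,
) -> list[SnpCall]:
    """candidates -> flanking filter for one assembly (pre-dedupe)."""
    cols = pileup(assembly)
    cands = call_candidates(cols, min_depth, min_fraction)
    return filter_flanking(cands, cols, assembly.consensus, max_n_fraction)
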