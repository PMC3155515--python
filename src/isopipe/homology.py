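"""Homology-based isotig annotation.

Chains local-alignment HSPs into syntenic hits (largest-query-coverage
colinear, non-overlapping subset), screens gene-level unique hits with the
conjunctive 2x coverage-and-bit-score rule (same-gene hits exempt), clusters
unique isotigs by target gene with greedy non-overlapping representative
selection, and classifies each isotig's cross-species gene hits into
orthology-consistency categories 1-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import HSP, GeneModel, OrthologyTable


class ChainingError(ValueError):
    pass


@dataclass
class ChainedHit:
    """A colinear, query- and target-disjoint HSP subset for one query-target pair."""

    query_id: str
    target_id: str
    members: list[HSP]
    gene_id: str | None = None
    coding_bp: int = 0
    utr_bp: int = 0

    @property
    def coverage(self) -> int:
        return sum(h.q_len for h in self.members)

    @property
    def total_bits(self) -> float:
        return sum(h.bit_score for h in self.members)

    @property
    def strand(self) -> str:
        return self.members[0].strand


@dataclass
class UniqueCall:
    query_id: str
    status: str  # unique | ambiguous | no-hit
    best: ChainedHit | None = None
    runner_up: ChainedHit | None = None
    size_ratio: float = math.inf
    bits_ratio: float = math.inf


@dataclass
class GeneCluster:
    species: str
    gene_id: str
    member_isotigs: list[str]
    representative: str
    non_overlapping: list[str]


@dataclass
class CategoryCall:
    isotig_id: str
    genes: dict[str, str | None]  # species -> unique gene id (None = no call)
    category: int
    coding_portion: float | None = None
    aligned_total: int = 0


def _compatible(a: HSP, b: HSP) -> bool:
    """True if b can follow a in a chain: disjoint and order-consistent on
    query and target (target descending for minus-strand chains)."""
    if a.q_end > b.q_start:
        return False
    if a.strand == "+":
        return a.t_end <= b.t_start
    return b.t_end <= a.t_start


def chain_hsps(hsps: list[HSP]) -> ChainedHit:
    """Select the colinear non-overlapping HSP subset maximizing query coverage.

    Weighted DP over HSPs sorted by query start. Ties broken by larger total
    bit score, then fewer members, then the earlier member order after the
    deterministic sort.
    """
    if not hsps:
        raise ChainingError("cannot chain an empty HSP list")
    qids = {h.query_id for h in hsps}
    tids = {h.target_id for h in hsps}
    strands = {h.strand for h in hsps}
    if len(qids) > 1 or len(tids) > 1:
        raise ChainingError("all HSPs must share one query and one target")
    if len(strands) > 1:
        raise ChainingError("mixed strands; split by strand and keep the better chain")

    order = sorted(
        range(len(hsps)),
        key=lambda i: (hsps[i].q_start, hsps[i].q_end, hsps[i].t_start, hsps[i].t_end),
    )
    hs = [hsps[i] for i in order]
    n = len(hs)
    # DP value: (coverage, bits, -members); parent for reconstruction
    best = [(hs[i].q_len, hs[i].bit_score, -1) for i in range(n)]
    parent = [-1] * n
    for j in range(n):
        for i in range(j):
            if _compatible(hs[i], hs[j]):
                cand = (
                    best[i][0] + hs[j].q_len,
                    best[i][1] + hs[j].bit_score,
                    best[i][2] - 1,
                )
                if cand > best[j]:
                    best[j] = cand
                    parent[j] = i
    end = max(range(n), key=lambda j: (best[j], -j))
    members = []
    while end != -1:
        members.append(hs[end])
        end = parent[end]
    members.reverse()
    return ChainedHit(hs[0].query_id, hs[0].target_id, members)


def chain_query_target(hsps: list[HSP]) -> ChainedHit:
    """Chain a query-target pair that may mix strands: chains each strand
    separately and keeps the better one (coverage, then bits)."""
    by_strand: dict[str, list[HSP]] = {}
    for h in hsps:
        by_strand.setdefault(h.strand, []).append(h)
    chains = [chain_hsps(group) for group in by_strand.values()]
    return max(chains, key=lambda c: (c.coverage, c.total_bits))


def resolve_gene(chain: ChainedHit, models: dict[str, GeneModel]) -> ChainedHit:
    """Attach the target transcript's gene and split coverage into CDS vs UTR.

    Each member HSP's target interval (transcript space) is intersected with
    the transcript's CDS; ``coding_bp`` is the summed intersection and
    ``utr_bp`` the remainder of the coverage.
    """
    model = models.get(chain.target_id)
    if model is None:
        raise KeyError(f"unknown transcript {chain.target_id}")
    chain.gene_id = model.gene_id
    coding = 0
    if model.cds_on_transcript is not None:
        cs, ce = model.cds_on_transcript
        for h in chain.members:
            coding += max(0, min(h.t_end, ce) - max(h.t_start, cs))
    chain.coding_bp = coding
    chain.utr_bp = chain.coverage - coding
    return chain


def classify_unique(chains: list[ChainedHit], ratio: float = 2.0) -> UniqueCall:
    """Apply the 2x unique-hit rule to one query's gene-resolved chains.

    Chains to the same gene are first merged (max coverage and max bits kept
    per gene, the same-locus exemption); the best gene is unique iff both its
    coverage and its bit score are at least ``ratio`` times the runner-up's.
    """
    if not chains:
        return UniqueCall("", "no-hit")
    query_id = chains[0].query_id
    per_gene: dict[str, tuple[int, float, ChainedHit]] = {}
    for c in chains:
        if c.gene_id is None:
            raise ChainingError(f"{query_id}: chains must be gene-resolved")
        cov, bits, rep = per_gene.get(c.gene_id, (0, 0.0, c))
        best_rep = max((rep, c), key=lambda x: (x.coverage, x.total_bits, x.target_id))
        per_gene[c.gene_id] = (max(cov, c.coverage), max(bits, c.total_bits), best_rep)

    ranked = sorted(
        per_gene.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0]), reverse=True
    )
    (best_gene, (b_cov, b_bits, b_rep)) = ranked[0]
    if len(ranked) == 1:
        return UniqueCall(query_id, "unique", b_rep)
    (_, (r_cov, r_bits, r_rep)) = ranked[1]
    size_ratio = b_cov / r_cov if r_cov else math.inf
    bits_ratio = b_bits / r_bits if r_bits else math.inf
    status = "unique" if (size_ratio >= ratio and bits_ratio >= ratio) else "ambiguous"
    return UniqueCall(query_id, status, b_rep, r_rep, size_ratio, bits_ratio)


def _genomic_footprint(chain: ChainedHit, model: GeneModel) -> list[tuple[int, int]]:
    intervals = []
    for h in chain.members:
        intervals.extend(model.transcript_to_genomic(h.t_start, h.t_end))
    intervals.sort()
    merged = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _disjoint(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> bool:
    for s1, e1 in a:
        for s2, e2 in b:
            if max(s1, s2) < min(e1, e2):
                return False
    return True


def cluster_by_gene(
    calls: list[UniqueCall], species: str, models: dict[str, GeneModel]
) -> list[GeneCluster]:
    """Group unique calls by target gene; pick the largest-coverage
    representative and a greedy non-overlapping subset of genomic footprints."""
    by_gene: dict[str, list[UniqueCall]] = {}
    for call in calls:
        if call.status != "unique" or call.best is None:
            continue
        by_gene.setdefault(call.best.gene_id, []).append(call)

    clusters = []
    for gene_id in sorted(by_gene):
        members = by_gene[gene_id]
        ranked = sorted(
            members,
            key=lambda c: (-c.best.coverage, -c.best.total_bits, c.query_id),
        )
        accepted, footprints = [], []
        for call in ranked:
            fp = _genomic_footprint(call.best, models[call.best.target_id])
            if all(_disjoint(fp, prev) for prev in footprints):
                accepted.append(call.query_id)
                footprints.append(fp)
        clusters.append(
            GeneCluster(
                species,
                gene_id,
                [c.query_id for c in members],
                ranked[0].query_id,
                accepted,
            )
        )
    return clusters


def assign_category(
    isotig_id: str,
    genes: dict[str, str | None],
    orthology: OrthologyTable,
    coding_bp: int | None = None,
    utr_bp: int | None = None,
) -> CategoryCall:
    """Classify cross-species annotation consistency.

    Category 3: all three species' genes share one ortholog group; category
    2: exactly one species pair shares; category 1 otherwise. Species with
    no unique call count as non-matching.
    """
    called = {sp: g for sp, g in genes.items() if g is not None}
    if not called:
        raise ValueError(f"{isotig_id}: no species has a unique call")
    groups = {
        sp: orthology.group_of(sp, g) or f"__none_{sp}_{g}" for sp, g in called.items()
    }
    species = sorted(groups)
    shared_pairs = sum(
        1
        for i in range(len(species))
        for j in range(i + 1, len(species))
        if groups[species[i]] == groups[species[j]]
    )
    if len(genes) >= 3 and len(called) == len(genes) and len(set(groups.values())) == 1:
        category = 3
    elif shared_pairs >= 1:
        category = 2
    else:
        category = 1
    call = CategoryCall(isotig_id, dict(genes), category)
    if coding_bp is not None and utr_bp is not None:
        total = coding_bp + utr_bp
        call.coding_portion = coding_bp / total if total else None
        call.aligned_total = total
    return call


SIZE_BINS = (0, 400, 800, 1600, math.inf)
PORTION_BINS = (0.0, 0.25, 0.5, 0.75, 1.0 + 1e-9)


def utr_profile(calls: list[CategoryCall]):
    """Per-category histograms of HSP coding portion and aligned length.

    Returns ``{category: {"coding_portion": counts, "aligned_total": counts}}``
    with coding-portion bins [0,.25,.5,.75,1] and size bins
    <400, 400-800, 800-1600, >=1600 bp.
    """
    out: dict[int, dict[str, np.ndarray]] = {}
    for cat in (1, 2, 3):
        sub = [c for c in calls if c.category == cat]
        portions = [c.coding_portion for c in sub if c.coding_portion is not None]
        sizes = [c.aligned_total for c in sub if c.aligned_total]
        out[cat] = {
            "coding_portion": np.histogram(portions, bins=PORTION_BINS)[0],
            "aligned_total": np.histogram(sizes, bins=SIZE_BINS)[0],
        }
    return out
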