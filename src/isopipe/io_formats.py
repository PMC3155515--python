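"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open. Conversion to the 1-based
inclusive conventions of BLAST tabular and GFF3 happens only at the file
boundary. Minus-strand local alignments are stored with ascending
coordinates plus a strand flag.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LIBRARIES = ("C.1", "C.2", "C.3", "C.4")
_VALID_CONSENSUS = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file; message carries file name and line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class ValidationError(ValueError):
    """Structurally valid file whose content violates a model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HSP:
    """One local-alignment segment pair between a query and a target."""

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str = "+"
    pct_identity: float = 100.0
    bit_score: float = 0.0
    e_value: float = 0.0

    def __post_init__(self):
        if not (0 <= self.q_start < self.q_end):
            raise ValidationError(f"bad query interval {self.q_start}..{self.q_end}")
        if not (0 <= self.t_start < self.t_end):
            raise ValidationError(f"bad target interval {self.t_start}..{self.t_end}")
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(f"bad pct_identity {self.pct_identity}")
        if self.bit_score < 0:
            raise ValidationError(f"negative bit score {self.bit_score}")

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_len(self) -> int:
        return self.t_end - self.t_start


@dataclass
class GeneModel:
    """A reference transcript with exon/CDS structure and an ortholog group.

    ``exons`` are genomic intervals on ``chrom`` in transcript order;
    ``cds_on_transcript`` is in transcript coordinates (0-based half-open)
    and includes the stop codon.
    """

    transcript_id: str
    gene_id: str
    species: str
    chrom: str
    exons: list[tuple[int, int]]
    cds_on_transcript: tuple[int, int] | None
    transcript_seq: str
    ortholog_group: str | None = None

    def __post_init__(self):
        exon_sum = sum(e - s for s, e in self.exons)
        if exon_sum != len(self.transcript_seq):
            raise ValidationError(
                f"{self.transcript_id}: exon lengths sum to {exon_sum}, "
                f"transcript length is {len(self.transcript_seq)}"
            )
        if self.cds_on_transcript is not None:
            s, e = self.cds_on_transcript
            if not (0 <= s < e <= len(self.transcript_seq)):
                raise ValidationError(
                    f"{self.transcript_id}: CDS {s}..{e} outside transcript"
                )

    @property
    def transcript_len(self) -> int:
        return len(self.transcript_seq)

    @property
    def cds_len(self) -> int:
        if self.cds_on_transcript is None:
            return 0
        s, e = self.cds_on_transcript
        return e - s

    def cds_seq(self) -> str:
        if self.cds_on_transcript is None:
            return ""
        s, e = self.cds_on_transcript
        return self.transcript_seq[s:e]

    def protein(self) -> str:
        """Conceptual translation of the CDS, stop codon stripped."""
        aa = str(Seq(self.cds_seq()).translate())
        return aa[:-1] if aa.endswith("*") else aa

    def transcript_to_genomic(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Project a transcript interval onto genomic exon intervals."""
        if not (0 <= t_start <= t_end <= self.transcript_len):
            raise ValidationError(
                f"{self.transcript_id}: interval {t_start}..{t_end} outside transcript"
            )
        out = []
        offset = 0
        for gs, ge in self.exons:
            elen = ge - gs
            lo = max(t_start, offset)
            hi = min(t_end, offset + elen)
            if lo < hi:
                out.append((gs + (lo - offset), gs + (hi - offset)))
            offset += elen
        return out


@dataclass
class AssemblyRead:
    read_id: str
    offset: int
    strand: str
    library: str
    seq: str


@dataclass
class IsotigAssembly:
    """Consensus plus placed reads; the SNP caller's substrate."""

    isotig_id: str
    consensus: str
    reads: list[AssemblyRead] = field(default_factory=list)

    def validate(self):
        bad = set(self.consensus) - _VALID_CONSENSUS
        if bad:
            raise ValidationError(
                f"{self.isotig_id}: disallowed consensus characters {sorted(bad)}"
            )
        for r in self.reads:
            if r.offset < 0 or r.offset + len(r.seq) > len(self.consensus):
                raise ValidationError(
                    f"{self.isotig_id}/{r.read_id}: read extends past consensus"
                )
            if r.library not in LIBRARIES:
                raise ValidationError(
                    f"{self.isotig_id}/{r.read_id}: unknown library {r.library!r}"
                )
            if set(r.seq) - _VALID_CONSENSUS:
                raise ValidationError(
                    f"{self.isotig_id}/{r.read_id}: disallowed read characters"
                )
        return self


class OrthologyTable:
    """(species, gene_id) -> ortholog group; at most one group per pair."""

    def __init__(self, mapping: dict[tuple[str, str], str] | None = None):
        self._map: dict[tuple[str, str], str] = dict(mapping or {})

    def add(self, species: str, gene_id: str, group: str):
        key = (species, gene_id)
        if key in self._map and self._map[key] != group:
            raise ValidationError(
                f"conflicting ortholog groups for {species}/{gene_id}: "
                f"{self._map[key]} vs {group}"
            )
        self._map[key] = group

    def group_of(self, species: str, gene_id: str) -> str | None:
        return self._map.get((species, gene_id))

    def __len__(self):
        return len(self._map)

    def items(self):
        return self._map.items()


@dataclass
class CountTable:
    """Per-gene read counts for the four libraries, plus library totals."""

    counts: pd.DataFrame  # index gene_id, columns n1..n4
    totals: tuple[int, int, int, int]

    def __post_init__(self):
        if list(self.counts.columns) != ["n1", "n2", "n3", "n4"]:
            raise ValidationError("count table must have columns n1..n4")
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts")
        sums = self.counts.sum(axis=0).to_numpy()
        if any(int(t) < int(s) for t, s in zip(self.totals, sums)):
            raise ValidationError("library totals smaller than column sums")


# ---------------------------------------------------------------------------
# BLAST tabular (12-column outfmt 6)
# ---------------------------------------------------------------------------

def read_blast_tabular(path) -> list[HSP]:
    """Read 12-column BLAST tabular hits into plus-strand-normalized HSPs.

    ``sstart > send`` denotes a minus-strand hit and is stored with ascending
    target coordinates and ``strand='-'``. Lines starting with '#' skipped.
    """
    hsps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(path, lineno, f"expected 12 columns, got {len(fields)}")
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue, bits = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric field: {exc}") from None
            if sstart > send:
                strand, t0, t1 = "-", send - 1, sstart
            else:
                strand, t0, t1 = "+", sstart - 1, send
            try:
                hsps.append(
                    HSP(qid, sid, qstart - 1, qend, t0, t1, strand, pident, bits, evalue)
                )
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return hsps


def write_blast_tabular(hsps: Iterable[HSP], path):
    with open(path, "w") as fh:
        for h in hsps:
            if h.strand == "+":
                sstart, send = h.t_start + 1, h.t_end
            else:
                sstart, send = h.t_end, h.t_start + 1
            mismatch = int(round(h.t_len * (1 - h.pct_identity / 100.0)))
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.target_id,
                        f"{h.pct_identity:.2f}",
                        str(h.q_len),
                        str(mismatch),
                        "0",
                        str(h.q_start + 1),
                        str(h.q_end),
                        str(sstart),
                        str(send),
                        f"{h.e_value:.2g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# ACE (minimal dialect + true Newbler-style ACE)
# ---------------------------------------------------------------------------

def _read_minimal_ace(path) -> list[IsotigAssembly]:
    assemblies = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, n = 0, len(lines)
    lineno = 0
    while i < n:
        line = lines[i].strip()
        lineno = i + 1
        i += 1
        if not line:
            continue
        if not line.startswith("CO "):
            raise ParseError(path, lineno, f"expected CO record, got {line[:20]!r}")
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(path, lineno, "CO line needs: CO <id> <len> <n_reads>")
        _, cid, clen, nreads = parts
        clen, nreads = int(clen), int(nreads)
        if i >= n:
            raise ParseError(path, lineno, "missing consensus sequence")
        consensus = lines[i].strip()
        i += 1
        if len(consensus) != clen:
            raise ParseError(path, lineno + 1, "consensus length mismatch")
        reads = []
        for _ in range(nreads):
            if i + 1 >= n + 1 or not lines[i].startswith("RD "):
                raise ParseError(path, i + 1, "expected RD record")
            rparts = lines[i].split()
            if len(rparts) != 5:
                raise ParseError(path, i + 1, "RD line needs: RD <id> <offset> <strand> <library>")
            _, rid, off, strand, lib = rparts
            seq = lines[i + 1].strip()
            reads.append(AssemblyRead(rid, int(off), strand, lib, seq))
            i += 2
        assemblies.append(IsotigAssembly(cid, consensus, reads).validate())
    return assemblies


def _read_true_ace(path) -> list[IsotigAssembly]:
    """Read AS/CO/AF/RD ACE files; pads ('*') stripped with offset adjustment.

    Newbler/phrap ACE stores read sequences already in consensus orientation
    ('C' reads are stored complemented); strand is kept as metadata only.
    Library tags are not part of ACE; reads default to C.1.
    """
    from Bio.Sequencing import Ace

    assemblies = []
    for contig in Ace.parse(path):
        padded = contig.sequence.upper()
        # consensus position of each padded column, pads removed
        unpadded_pos, keep = [], []
        cursor = 0
        for ch in padded:
            unpadded_pos.append(cursor)
            if ch != "*":
                keep.append(ch)
                cursor += 1
        consensus = "".join(keep).replace("X", "N").replace("-", "N")
        reads = []
        for rd, af in zip(contig.reads, contig.af):
            rseq = rd.rd.sequence.upper().replace("*", "")
            rseq = rseq.replace("X", "N").replace("-", "N")
            start_padded = af.padded_start - 1  # may be negative (overhang)
            if start_padded < 0 or start_padded >= len(padded):
                raise ParseError(path, 0, f"read {rd.rd.name} placed outside consensus")
            offset = unpadded_pos[start_padded]
            if offset + len(rseq) > len(consensus):
                raise ParseError(path, 0, f"read {rd.rd.name} extends past consensus")
            strand = "-" if af.coru == "C" else "+"
            reads.append(AssemblyRead(rd.rd.name, offset, strand, "C.1", rseq))
        assemblies.append(IsotigAssembly(contig.name, consensus, reads).validate())
    return assemblies


def read_ace(path) -> list[IsotigAssembly]:
    """Read assemblies from the minimal dialect or a true ACE file.

    Dialect auto-detected from the first token (``AS`` -> true ACE).
    """
    with open(path) as fh:
        first = fh.readline().split()
    if first and first[0] == "AS":
        return _read_true_ace(path)
    return _read_minimal_ace(path)


def write_ace(assemblies: Iterable[IsotigAssembly], path):
    """Write the minimal ACE dialect."""
    with open(path, "w") as fh:
        for asm in assemblies:
            fh.write(f"CO {asm.isotig_id} {len(asm.consensus)} {len(asm.reads)}\n")
            fh.write(asm.consensus + "\n")
            for r in asm.reads:
                fh.write(f"RD {r.read_id} {r.offset} {r.strand} {r.library}\n")
                fh.write(r.seq + "\n")


# ---------------------------------------------------------------------------
# FASTA / GFF3 / TSV / GMT
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Sequence[tuple[str, str]], path):
    if isinstance(seqs, dict):
        seqs = list(seqs.items())
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(models: Sequence[GeneModel], path):
    """Write gene/mRNA/exon/CDS features, 1-based inclusive, plus strand."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[GeneModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id in sorted(by_gene):
            group = by_gene[gene_id]
            chrom = group[0].chrom
            gmin = min(m.exons[0][0] for m in group)
            gmax = max(m.exons[-1][1] for m in group)
            fh.write(
                f"{chrom}\tisopipe\tgene\t{gmin + 1}\t{gmax}\t.\t+\t.\tID={gene_id}\n"
            )
            for m in group:
                fh.write(
                    f"{chrom}\tisopipe\tmRNA\t{m.exons[0][0] + 1}\t{m.exons[-1][1]}"
                    f"\t.\t+\t.\tID={m.transcript_id};Parent={gene_id}\n"
                )
                for s, e in m.exons:
                    fh.write(
                        f"{chrom}\tisopipe\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                        f"Parent={m.transcript_id}\n"
                    )
                if m.cds_on_transcript is not None:
                    for s, e in m.transcript_to_genomic(*m.cds_on_transcript):
                        fh.write(
                            f"{chrom}\tisopipe\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                            f"Parent={m.transcript_id}\n"
                        )


def read_gff3_models(gff_path, transcript_fasta_path, species: str,
                     orthology: OrthologyTable | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 + transcript FASTA (plus-strand features)."""
    import gffutils

    seqs = read_fasta(transcript_fasta_path)
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="error", keep_order=True
    )
    models = []
    seen = set()
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        if tid in seen:
            raise ValidationError(f"duplicate transcript id {tid}")
        seen.add(tid)
        gene_id = mrna.attributes["Parent"][0]
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_genomic = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if tid not in seqs:
            raise ValidationError(f"transcript {tid} missing from FASTA")
        seq = seqs[tid]
        cds_t = None
        if cds_genomic:
            # genomic CDS span -> transcript coordinates via the exon map
            offsets, acc = [], 0
            for s, e in exons:
                offsets.append((s, e, acc))
                acc += e - s
            def to_t(g):
                for s, e, off in offsets:
                    if s <= g <= e:
                        return off + (g - s)
                raise ValidationError(f"{tid}: CDS outside exons")
            cds_t = (to_t(cds_genomic[0][0]), to_t(cds_genomic[-1][1] - 1) + 1)
        group = orthology.group_of(species, gene_id) if orthology else None
        models.append(
            GeneModel(tid, gene_id, species, mrna.seqid, exons, cds_t, seq, group)
        )
    return models


def read_orthology(path) -> OrthologyTable:
    """Read the 3-column (gene_id, species, ortholog_group) TSV with header."""
    table = OrthologyTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_id", "species", "ortholog_group"]:
            raise ParseError(path, 1, f"unexpected header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(path, lineno, "expected 3 columns")
            gene, species, group = fields
            try:
                table.add(species, gene, group)
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return table


def write_orthology(table: OrthologyTable, path):
    with open(path, "w") as fh:
        fh.write("gene_id\tspecies\tortholog_group\n")
        for (species, gene), group in sorted(table.items()):
            fh.write(f"{gene}\t{species}\t{group}\n")


def read_counts(path) -> CountTable:
    """Read the counts TSV; first row after the header carries totals N1..N4."""
    df = pd.read_csv(path, sep="\t")
    expected = ["gene_id", "n1", "n2", "n3", "n4"]
    if list(df.columns) != expected:
        raise ParseError(path, 1, f"expected columns {expected}, got {list(df.columns)}")
    totals_row = df.iloc[0]
    if totals_row["gene_id"] != "__totals__":
        raise ParseError(path, 2, "first data row must be the __totals__ row")
    totals = tuple(int(totals_row[c]) for c in ["n1", "n2", "n3", "n4"])
    body = df.iloc[1:].set_index("gene_id").astype(int)
    return CountTable(body, totals)


def write_counts(table: CountTable, path):
    with open(path, "w") as fh:
        fh.write("gene_id\tn1\tn2\tn3\tn4\n")
        fh.write("__totals__\t" + "\t".join(str(t) for t in table.totals) + "\n")
        for gene_id, row in table.counts.iterrows():
            fh.write(
                f"{gene_id}\t{int(row.n1)}\t{int(row.n2)}\t{int(row.n3)}\t{int(row.n4)}\n"
            )


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT lines (term, description, members...) into term -> gene set."""
    terms = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "GMT line needs term, description, members")
            terms[fields[0]] = set(fields[2:])
    return terms


def write_tsv(records: Sequence[dict], path, columns: Sequence[str] | None = None):
    """Write a list of dicts as a TSV; atomic (temp file + rename)."""
    df = pd.DataFrame.from_records(records, columns=columns)
    tmp = str(path) + ".tmp"
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)
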