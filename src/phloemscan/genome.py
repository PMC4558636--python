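"""Genome FASTA / GFF3 input and strand-aware downstream-sequence extraction.

Because 3' UTR annotations are unreliable or absent in many plant genome
releases, the downstream sequence (DSS) — a fixed-length window immediately
3' of the stop codon of a gene's representative transcript — is used as a
3'-UTR proxy for motif screening.  Windows of 1000, 500 and 200 nt are
typical; a shorter window is always a prefix of a longer one for the same
gene.

Coordinates follow the GFF3 convention (1-based, inclusive) everywhere a
coordinate is exposed; conversions to Python slices are internal.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "DownstreamSequence",
    "AnnotationReport",
    "FormatError",
    "read_genome",
    "read_annotation",
    "extract_dss",
    "extract_all_dss",
    "dss_to_fasta",
    "dss_to_bed",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed FASTA/GFF3 input."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene reduced to what DSS extraction needs.

    ``coding_end`` is the 1-based genomic coordinate of the last base of the
    coding sequence of the representative transcript: the maximal CDS end on
    the plus strand, the minimal CDS start on the minus strand.  The DSS
    starts at the base immediately 3' of it (the stop codon itself is part of
    the CDS and excluded from the DSS).
    """

    gene_id: str
    contig: str
    strand: str
    coding_end: int
    transcript_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.coding_end < 1:
            raise ValueError("coding_end is a 1-based coordinate and must be >= 1")


@dataclass(frozen=True)
class DownstreamSequence:
    """Extracted DSS for one gene, 5'->3' in transcript orientation."""

    gene_id: str
    window: int
    sequence: str
    truncated: bool

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)

    def prefix(self, window: int) -> "DownstreamSequence":
        """The DSS at a shorter window is the prefix of this one."""
        if window > self.window:
            raise ValueError("prefix window must not exceed the extracted window")
        seq = self.sequence[:window]
        return DownstreamSequence(self.gene_id, window, seq, len(seq) < window)


@dataclass
class AnnotationReport:
    """What was kept and dropped while reducing a GFF3 to gene models."""

    n_genes: int = 0
    n_kept: int = 0
    n_no_cds: int = 0
    n_orphan_cds: int = 0


def _as_handle(source: str | os.PathLike) -> io.StringIO:
    """Accept a path or raw text content; FASTA content starts with '>'."""
    text = _as_text(source)
    return io.StringIO(text)


def _as_text(source: str | os.PathLike) -> str:
    if isinstance(source, str) and (
        "\n" in source or source.lstrip().startswith((">", "##")) or not source.strip()
    ):
        return source
    with open(source) as fh:
        return fh.read()


def read_genome(source: str | os.PathLike) -> dict[str, str]:
    """Parse FASTA into ``{contig: uppercase sequence}``.

    Contig names are the first whitespace-delimited token of each header.
    Accepts either a file path or the FASTA text itself.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(_as_handle(source), "fasta"):
        name = rec.id
        if name in contigs:
            raise FormatError(f"duplicate contig name {name!r} in FASTA input")
        contigs[name] = str(rec.seq).upper()
    if not contigs:
        raise FormatError("no FASTA records found in input")
    return contigs


_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def read_annotation(
    source: str | os.PathLike,
    representative_rule: str = "longest_cds",
    with_report: bool = False,
) -> list[GeneModel] | tuple[list[GeneModel], AnnotationReport]:
    """Reduce a GFF3 to one :class:`GeneModel` per CDS-bearing gene.

    The representative transcript is chosen per ``representative_rule``:

    - ``"longest_cds"`` (default): largest summed CDS length, ties broken by
      lexicographically smallest transcript id;
    - ``"first"``: lexicographically smallest transcript id.

    Genes with no CDS-bearing transcript are excluded and counted in the
    report; CDS features whose Parent cannot be resolved are skipped with a
    logged warning.
    """
    if representative_rule not in ("longest_cds", "first"):
        raise ValueError(f"unknown representative_rule {representative_rule!r}")

    db = gffutils.create_db(
        _as_text(source),
        ":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    report = AnnotationReport()

    known_tx = {
        f.id for t in _TRANSCRIPT_TYPES for f in db.features_of_type(t)
    }
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not any(p in known_tx for p in parents):
            report.n_orphan_cds += 1
            logger.warning(
                "CDS at %s:%d-%d has no resolvable transcript parent; skipped",
                cds.seqid, cds.start, cds.end,
            )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        report.n_genes += 1
        candidates = []
        for ttype in _TRANSCRIPT_TYPES:
            for tx in db.children(gene, featuretype=ttype):
                cds = list(db.children(tx, featuretype="CDS"))
                if not cds:
                    continue
                total = sum(c.end - c.start + 1 for c in cds)
                candidates.append((tx.id, total, cds))
        if not candidates:
            report.n_no_cds += 1
            continue
        if representative_rule == "longest_cds":
            tx_id, _, cds = min(candidates, key=lambda c: (-c[1], c[0]))
        else:
            tx_id, _, cds = min(candidates, key=lambda c: c[0])
        if gene.strand == "+":
            coding_end = max(c.end for c in cds)
        elif gene.strand == "-":
            coding_end = min(c.start for c in cds)
        else:
            logger.warning("gene %s has no strand; skipped", gene.id)
            report.n_no_cds += 1
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                coding_end=coding_end,
                transcript_id=tx_id,
            )
        )
        report.n_kept += 1

    if with_report:
        return genes, report
    return genes


def extract_dss(
    gene: GeneModel, contigs: Mapping[str, str], window: int
) -> DownstreamSequence:
    """Extract the DSS of ``gene`` at ``window`` nt, 5'->3' for the transcript.

    Plus strand: genomic interval [coding_end+1, coding_end+window], clipped
    at the contig end.  Minus strand: [coding_end-window, coding_end-1],
    clipped at 1, then reverse-complemented.  ``truncated`` is set whenever
    clipping shortened the window; a gene whose coding end sits at the contig
    boundary yields an empty, truncated DSS (not an error).
    """
    if window < 1:
        raise ValueError("window must be a positive number of nucleotides")
    if gene.contig not in contigs:
        raise KeyError(f"contig {gene.contig!r} not present in genome")
    contig = contigs[gene.contig]
    if gene.strand == "+":
        start0 = gene.coding_end  # 0-based index of the base after the stop
        frag = contig[start0 : start0 + window]
    else:
        lo = max(0, gene.coding_end - 1 - window)
        frag = reverse_complement(contig[lo : gene.coding_end - 1])
    return DownstreamSequence(
        gene_id=gene.gene_id,
        window=window,
        sequence=frag,
        truncated=len(frag) < window,
    )


def extract_all_dss(
    genes: Iterable[GeneModel], contigs: Mapping[str, str], window: int
) -> list[DownstreamSequence]:
    return [extract_dss(g, contigs, window) for g in genes]


def dss_to_fasta(records: Iterable[DownstreamSequence], line_width: int = 60) -> str:
    """FASTA export with ``>gene_id|window|truncated`` headers."""
    out: list[str] = []
    for r in records:
        out.append(f">{r.gene_id}|{r.window}|{str(r.truncated).lower()}")
        for i in range(0, len(r.sequence), line_width):
            out.append(r.sequence[i : i + line_width])
        if not r.sequence:
            out.append("")
    return "\n".join(out) + "\n"


def dss_to_bed(
    genes: Iterable[GeneModel], contigs: Mapping[str, str], window: int
) -> str:
    """BED6 (0-based, half-open) of the genomic DSS intervals."""
    lines = []
    for g in genes:
        clen = len(contigs[g.contig])
        if g.strand == "+":
            start = min(g.coding_end, clen)
            end = min(g.coding_end + window, clen)
        else:
            start = max(0, g.coding_end - 1 - window)
            end = g.coding_end - 1
        lines.append(f"{g.contig}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}")
    return "\n".join(lines) + "\n"
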