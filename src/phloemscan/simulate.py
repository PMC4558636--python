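"""Synthetic genomes, annotations and count matrices with known ground truth.

The generator emulates the statistical structure of the real study inputs:
a multi-contig DNA genome carrying protein-coding genes on both strands,
RNA-binding-protein motifs planted at known offsets inside each gene's
downstream sequence (DSS), and negative-binomial read-count matrices with
replicate structure, unequal library depths and optional group-unique
genes.  Everything is driven by one seeded :class:`numpy.random.Generator`,
so outputs are byte-identical across runs with the same spec.

Genes are laid out in non-overlapping slots with a full DSS window of
clearance on both sides, so a DSS never truncates unless a test places a
gene near a contig end on purpose; each synthetic gene has exactly one
transcript.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import motifs as _motifs
from .genome import GeneModel, reverse_complement

__all__ = [
    "SyntheticSpec",
    "SyntheticGenome",
    "GenerationError",
    "generate_genome",
    "generate_counts",
    "motif_instance",
]


class GenerationError(RuntimeError):
    """Raised when a valid placement cannot be produced for the spec."""


# concrete plantable instances are drawn from these consensus patterns;
# "cu_run" is the single maximal CU run the PTB cluster rule counts
_PLANTABLE = {
    "pumilio": _motifs.PUMILIO_PATTERN,
    "nova": _motifs.NOVA_PATTERN,
    "rbp50": "TTCTCTCT[CT][CT][CT]TCTT",
    "cu_run": "[CT][CT][CT][CT]",
}


def motif_instance(name: str, rng: np.random.Generator) -> str:
    """A concrete DNA string matching the named motif (or a raw pattern)."""
    pattern = _PLANTABLE.get(name.lower(), name)
    positions = _motifs.parse_consensus(pattern)
    return "".join(rng.choice(sorted(allowed)) for allowed in positions)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``planted_motifs`` is a list of ``(motif_name, gene_index, dss_offset)``
    triples; the named motif is written into the DSS of that gene so that a
    transcript-oriented scan finds it exactly at ``dss_offset`` regardless of
    strand.  ``background_alphabet`` restricts background bases (e.g. ``"AG"``
    makes a purine-only background in which no CU run and none of the four
    study motifs can occur by chance); when unset, background bases are drawn
    from A/C/G/T at ``background_gc`` GC content.  ``unique_genes`` maps a
    gene index to the single group expressing it (mean zero elsewhere).
    """

    n_contigs: int = 1
    contig_length: int = 50_000
    n_genes: int = 10
    frac_minus_strand: float = 0.5
    planted_motifs: tuple[tuple[str, int, int], ...] = ()
    background_gc: float = 0.5
    background_alphabet: str | None = None
    n_libraries_per_group: int = 3
    nb_mean: float = 100.0
    nb_dispersion: float = 5.0
    library_size_factors: tuple[float, ...] | None = None
    dss_window: int = 1000
    gene_length: int = 300
    unique_genes: Mapping[int, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_contigs, self.contig_length, self.n_genes) < 1:
            raise ValueError("n_contigs, contig_length and n_genes must be positive")
        if not 0 <= self.frac_minus_strand <= 1:
            raise ValueError("frac_minus_strand must be in [0, 1]")
        if not 0 <= self.background_gc <= 1:
            raise ValueError("background_gc must be in [0, 1]")
        if self.dss_window < 1 or self.gene_length < 10:
            raise ValueError("dss_window must be >=1 and gene_length >=10")
        for name, gene_idx, offset in self.planted_motifs:
            if not 0 <= gene_idx < self.n_genes:
                raise ValueError(f"planted motif gene index {gene_idx} out of range")
            if offset < 0:
                raise ValueError("planted motif offset must be non-negative")
            width = len(_motifs.parse_consensus(_PLANTABLE.get(name.lower(), name)))
            if offset + width > self.dss_window:
                raise ValueError(
                    f"motif {name!r} at offset {offset} overruns the "
                    f"{self.dss_window}-nt DSS"
                )


@dataclass(frozen=True)
class SyntheticGenome:
    """Generated genome: FASTA text, GFF3 text, truth table and gene models."""

    fasta: str
    gff3: str
    truth: pd.DataFrame  # gene_id, motif, offset (within DSS)
    genes: tuple[GeneModel, ...]


def _background(spec: SyntheticSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if spec.background_alphabet:
        letters = np.array(sorted(set(spec.background_alphabet.upper())))
        return rng.choice(letters, size=n)
    gc = spec.background_gc
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(["A", "C", "G", "T"]), size=n, p=p)


def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Build a seeded genome with planted motifs and matching GFF3 annotation.

    Each gene occupies a slot of ``gene_length + 2 * dss_window`` nt with the
    CDS centered, so the DSS fits untruncated on either strand.  Planted
    motifs are written into the genome post hoc: on the plus strand at
    ``coding_end + offset`` and on the minus strand as the reverse complement
    upstream of the CDS, so that strand-aware extraction recovers the
    instance at exactly the stated DSS offset.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    slot = spec.gene_length + 2 * spec.dss_window
    per_contig = spec.contig_length // slot
    if per_contig * spec.n_contigs < spec.n_genes:
        raise GenerationError(
            f"cannot place {spec.n_genes} genes: {spec.n_contigs} contig(s) of "
            f"{spec.contig_length} nt hold at most {per_contig * spec.n_contigs} "
            f"slots of {slot} nt (gene_length + 2*dss_window)"
        )

    contig_names = [f"contig{c + 1}" for c in range(spec.n_contigs)]
    arrays = {
        name: _background(spec, rng, spec.contig_length) for name in contig_names
    }

    n_minus = int(round(spec.frac_minus_strand * spec.n_genes))
    strands = np.array(["-"] * n_minus + ["+"] * (spec.n_genes - n_minus))
    rng.shuffle(strands)

    genes: list[GeneModel] = []
    placements: list[tuple[str, int, int, str]] = []  # contig, cds0, cds1, strand
    for i in range(spec.n_genes):
        contig = contig_names[i // per_contig]
        base = (i % per_contig) * slot
        cds0 = base + spec.dss_window          # 0-based inclusive start
        cds1 = cds0 + spec.gene_length         # 0-based exclusive end
        strand = str(strands[i])
        arr = arrays[contig]
        if strand == "+":
            arr[cds0:cds0 + 3] = list("ATG")
            arr[cds1 - 3:cds1] = list("TAA")
            coding_end = cds1                  # 1-based last CDS base
        else:
            arr[cds1 - 3:cds1] = list("CAT")   # revcomp ATG
            arr[cds0:cds0 + 3] = list("TTA")   # revcomp TAA
            coding_end = cds0 + 1
        gid = f"gene{i:04d}"
        genes.append(GeneModel(gid, contig, strand, coding_end, f"{gid}.1"))
        placements.append((contig, cds0, cds1, strand))

        # a restricted background alphabet is a guarantee about the DSS as
        # *read by the transcript*; on the minus strand the genomic region is
        # therefore redrawn from the complement alphabet so that the
        # reverse-complemented DSS stays within the requested alphabet
        if spec.background_alphabet and strand == "-":
            comp = sorted({reverse_complement(c) for c in set(spec.background_alphabet.upper())})
            arr[cds0 - spec.dss_window : cds0] = rng.choice(np.array(comp), size=spec.dss_window)

    # plant motifs, refusing overlaps within a gene's DSS
    occupied: dict[int, list[tuple[int, int]]] = {}
    truth_rows = []
    for name, gene_idx, offset in spec.planted_motifs:
        instance = motif_instance(name, rng)
        width = len(instance)
        for s, e in occupied.get(gene_idx, []):
            if offset < e and offset + width > s:
                raise GenerationError(
                    f"planted motifs overlap in gene {gene_idx} "
                    f"(offset {offset}, width {width})"
                )
        occupied.setdefault(gene_idx, []).append((offset, offset + width))
        contig, cds0, cds1, strand = placements[gene_idx]
        arr = arrays[contig]
        if strand == "+":
            start = cds1 + offset              # 0-based genomic start
            arr[start:start + width] = list(instance)
        else:
            # DSS base at offset k sits at genomic index cds0 - 1 - k
            start = cds0 - offset - width
            arr[start:start + width] = list(reverse_complement(instance))
        truth_rows.append(
            {"gene_id": genes[gene_idx].gene_id, "motif": name.lower(), "offset": offset}
        )

    fasta = _to_fasta({n: "".join(arrays[n]) for n in contig_names})
    gff3 = _to_gff3(contig_names, spec.contig_length, genes, placements)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "motif", "offset"])
    truth = truth.sort_values(["gene_id", "motif", "offset"], ignore_index=True)
    return SyntheticGenome(fasta, gff3, truth, tuple(genes))


def _to_fasta(contigs: Mapping[str, str], width: int = 60) -> str:
    lines = []
    for name, seq in contigs.items():
        lines.append(f">{name}")
        lines.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(lines) + "\n"


def _to_gff3(
    contig_names: Sequence[str],
    contig_length: int,
    genes: Sequence[GeneModel],
    placements: Sequence[tuple[str, int, int, str]],
) -> str:
    lines = ["##gff-version 3"]
    lines.extend(
        f"##sequence-region {name} 1 {contig_length}" for name in contig_names
    )
    for gene, (contig, cds0, cds1, strand) in zip(genes, placements):
        start, end = cds0 + 1, cds1  # 1-based inclusive
        gid, tid = gene.gene_id, gene.transcript_id
        lines.append(
            f"{contig}\tphloemscan\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
        )
        lines.append(
            f"{contig}\tphloemscan\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gid}"
        )
        lines.append(
            f"{contig}\tphloemscan\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
            f"ID={tid}.cds;Parent={tid}"
        )
    return "\n".join(lines) + "\n"


def generate_counts(
    spec: SyntheticSpec,
    group_design: Mapping[str, int] | None = None,
    gene_means: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Negative-binomial count matrix with replicate and library-size structure.

    ``group_design`` maps group label -> number of replicate libraries
    (default: two groups ``A``/``B`` at ``n_libraries_per_group`` each).
    Per-library expected counts are ``mean x size_factor`` where the gene
    mean defaults to ``nb_mean`` (overridable per gene via ``gene_means``)
    and is zero in groups a ``unique_genes`` entry switches off.  Counts are
    negative binomial with dispersion ``nb_dispersion``; an infinite
    dispersion is the Poisson limit.  Returns ``(counts, groups)`` with a
    library -> group mapping.
    """
    spec.validate()
    if spec.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive (use math.inf for Poisson)")
    if group_design is None:
        group_design = {"A": spec.n_libraries_per_group, "B": spec.n_libraries_per_group}
    libraries = [
        (f"{group}_{k + 1}", group)
        for group, n in group_design.items()
        for k in range(n)
    ]
    n_libs = len(libraries)
    factors = spec.library_size_factors or tuple([1.0] * n_libs)
    if len(factors) != n_libs:
        raise ValueError(
            f"library_size_factors has {len(factors)} entries for {n_libs} libraries"
        )
    if any(f <= 0 for f in factors):
        raise ValueError("library size factors must be positive")

    base = np.full(spec.n_genes, spec.nb_mean, dtype=float)
    if gene_means is not None:
        if len(gene_means) != spec.n_genes:
            raise ValueError("gene_means length must equal n_genes")
        base = np.asarray(gene_means, dtype=float)

    mean = np.tile(base[:, None], (1, n_libs)) * np.asarray(factors)
    for gene_idx, on_group in spec.unique_genes.items():
        for j, (_, group) in enumerate(libraries):
            if group != on_group:
                mean[gene_idx, j] = 0.0

    rng = np.random.default_rng(spec.seed + 1)
    if math.isinf(spec.nb_dispersion):
        counts = rng.poisson(mean)
    else:
        r = spec.nb_dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)

    gene_ids = [f"gene{i:04d}" for i in range(spec.n_genes)]
    lib_ids = [lib for lib, _ in libraries]
    frame = pd.DataFrame(counts, index=gene_ids, columns=lib_ids)
    frame.index.name = "gene_id"
    return frame, dict(libraries)
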