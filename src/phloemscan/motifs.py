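"""RNA-binding-protein motif screens over downstream sequences (DSS).

Four screens are implemented:

* degenerate-consensus scanning — Pumilio (``UGUA[UCA]AUA``) and Nova
  (``[UCA]CAUUUCA[CU]``) binding elements, with every overlapping match
  counted;
* position-weight-matrix (PWM) scanning with a log-odds score threshold,
  for user-supplied matrices;
* the polypyrimidine-tract (PTB) cluster rule — a transcript is a PTB
  target when its 200-nt DSS contains at least four maximal CU runs
  (C/T in DNA) of at least 4 nt each;
* the RBP50 15-mer screen (``UUCUCUCUccuUCUU``), where the lowercase
  positions are weakly conserved and default to pyrimidine-ambiguous.

Motifs are RNA elements read off the sense strand, so scanning is on the
transcript-oriented DSS only.  Motif definitions written in RNA letters are
mapped U->T at load time; an ``N`` in the sequence never matches any motif
position.

Summary statistics: per-gene hit multiplicity histograms, motif
co-occurrence tables (inclusion and exclusive counts), and positional
profiles with a Pearson chi-square test against a uniform distribution of
hit starts across the window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import DownstreamSequence

__all__ = [
    "MotifDefinition",
    "MotifHitSet",
    "PositionalProfile",
    "CuParams",
    "PUMILIO_PATTERN",
    "NOVA_PATTERN",
    "RBP50_PATTERN",
    "builtin_motifs",
    "rbp50_definition",
    "parse_consensus",
    "load_pwm",
    "scan_consensus",
    "scan_pwm",
    "find_cu_runs",
    "ptb_cluster_call",
    "rbp50_screen",
    "multiplicity_histogram",
    "cooccurrence_table",
    "positional_profile",
    "hits_to_frame",
]

# Consensus patterns in DNA letters (U->T), bracket degeneracy.
PUMILIO_PATTERN = "TGTA[TCA]ATA"
NOVA_PATTERN = "[TCA]CATTTCA[CT]"
RBP50_PATTERN = "UUCUCUCUccuUCUU"  # lowercase = weakly conserved positions

_BASES = frozenset("ACGT")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class CuParams:
    """Parameters of the PTB CU-run cluster rule."""

    min_run_length: int = 4
    min_runs: int = 4
    window: int = 200

    def __post_init__(self) -> None:
        if self.min_run_length < 1 or self.min_runs < 1 or self.window < 1:
            raise ValueError("CU-cluster parameters must be positive")


@dataclass(frozen=True)
class MotifDefinition:
    """A motif as a degenerate consensus, a scored PWM, or the CU-cluster rule."""

    name: str
    kind: str  # {"consensus", "pwm", "cu_cluster"}
    positions: tuple[frozenset[str], ...] = ()
    pwm_scores: tuple[tuple[float, ...], ...] = ()
    threshold: float = 0.0
    cu_params: CuParams | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("consensus", "pwm", "cu_cluster"):
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if self.kind == "consensus":
            if not self.positions:
                raise ValueError("consensus motif needs at least one position")
            for s in self.positions:
                if not s or not s <= _BASES:
                    raise ValueError(
                        "consensus positions must be non-empty subsets of {A,C,G,T}"
                    )
        if self.kind == "pwm" and not self.pwm_scores:
            raise ValueError("pwm motif needs a score matrix")
        if self.kind == "cu_cluster" and self.cu_params is None:
            object.__setattr__(self, "cu_params", CuParams())

    def __len__(self) -> int:
        if self.kind == "consensus":
            return len(self.positions)
        if self.kind == "pwm":
            return len(self.pwm_scores)
        raise TypeError("cu_cluster motifs have no fixed length")

    @classmethod
    def consensus(cls, name: str, pattern: str) -> "MotifDefinition":
        return cls(name=name, kind="consensus", positions=parse_consensus(pattern))

    @classmethod
    def pwm(
        cls,
        name: str,
        matrix: Sequence[Sequence[float]],
        threshold: float | None = None,
        threshold_frac: float = 0.8,
    ) -> "MotifDefinition":
        """A PWM motif from a positions x (A,C,G,T) log-odds matrix.

        When no absolute ``threshold`` is given, it defaults to
        ``threshold_frac`` times the maximal attainable score.
        """
        arr = np.asarray(matrix, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4 (A, C, G, T)")
        if threshold is None:
            best = arr.max(axis=1).sum()
            threshold = threshold_frac * best
        return cls(
            name=name,
            kind="pwm",
            pwm_scores=tuple(tuple(row) for row in arr),
            threshold=float(threshold),
        )

    @classmethod
    def cu_cluster(cls, name: str = "ptb", params: CuParams | None = None) -> "MotifDefinition":
        return cls(name=name, kind="cu_cluster", cu_params=params or CuParams())


@dataclass(frozen=True)
class MotifHitSet:
    """All hits of one motif in one DSS.

    For consensus/PWM motifs ``count`` is the number of (overlapping) match
    offsets and ``is_target`` means at least one hit.  For the CU-cluster
    rule ``hit_positions`` are the starts of qualifying maximal CU runs and
    ``is_target`` requires at least ``min_runs`` of them.
    """

    gene_id: str
    motif_name: str
    hit_positions: tuple[int, ...]
    count: int
    is_target: bool

    def __post_init__(self) -> None:
        if self.count != len(self.hit_positions):
            raise ValueError("count must equal the number of hit positions")
        if any(b <= a for a, b in zip(self.hit_positions, self.hit_positions[1:])):
            raise ValueError("hit positions must be strictly increasing")


@dataclass(frozen=True)
class PositionalProfile:
    """Binned distribution of hit starts across the DSS window."""

    motif_name: str
    bin_width: int
    bin_counts: tuple[int, ...]
    statistic: float
    enrichment_p: float


def parse_consensus(pattern: str) -> tuple[frozenset[str], ...]:
    """Parse a bracket-degenerate pattern like ``TGTA[TCA]ATA`` (RNA letters ok)."""
    pattern = pattern.upper().replace("U", "T")
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            allowed = frozenset(pattern[i + 1 : j])
            i = j + 1
        else:
            allowed = frozenset(ch)
            i += 1
        if not allowed or not allowed <= _BASES:
            raise ValueError(f"invalid consensus position {sorted(allowed)!r}")
        positions.append(allowed)
    return tuple(positions)


def rbp50_definition(lowercase_policy: str = "pyrimidine") -> MotifDefinition:
    """The RBP50 15-mer with lowercase positions resolved per policy.

    Policies: ``"pyrimidine"`` (default; lowercase matches C or T),
    ``"exact"`` (lowercase matches only the written base) and ``"any"``
    (lowercase matches any base).
    """
    positions: list[frozenset[str]] = []
    for ch in RBP50_PATTERN:
        base = ch.upper().replace("U", "T")
        if ch.isupper():
            positions.append(frozenset(base))
        elif lowercase_policy == "pyrimidine":
            positions.append(frozenset("CT"))
        elif lowercase_policy == "exact":
            positions.append(frozenset(base))
        elif lowercase_policy == "any":
            positions.append(_BASES)
        else:
            raise ValueError(f"unknown lowercase_policy {lowercase_policy!r}")
    return MotifDefinition(name="rbp50", kind="consensus", positions=tuple(positions))


def builtin_motifs(
    lowercase_policy: str = "pyrimidine", cu_params: CuParams | None = None
) -> dict[str, MotifDefinition]:
    """The four study motifs keyed by short name."""
    return {
        "pumilio": MotifDefinition.consensus("pumilio", PUMILIO_PATTERN),
        "nova": MotifDefinition.consensus("nova", NOVA_PATTERN),
        "ptb": MotifDefinition.cu_cluster("ptb", cu_params),
        "rbp50": rbp50_definition(lowercase_policy),
    }


def load_pwm(
    source: str,
    name: str = "pwm",
    threshold: float | None = None,
    threshold_frac: float = 0.8,
    as_probabilities: bool = False,
    pseudocount: float = 1e-3,
) -> MotifDefinition:
    """Load a PWM from a whitespace table with an ``A C G T`` header row.

    Values are log-odds scores unless ``as_probabilities`` is set, in which
    case rows are renormalized (with a pseudocount) and converted to log2
    odds against a uniform background.
    """
    text = source
    if "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    if [h.upper() for h in header] != ["A", "C", "G", "T"]:
        raise ValueError("PWM table must have header 'A C G T'")
    rows = [[float(x) for x in ln.split()] for ln in lines[1:]]
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("PWM rows must have exactly four columns")
    if as_probabilities:
        arr = arr + pseudocount
        arr = arr / arr.sum(axis=1, keepdims=True)
        arr = np.log2(arr / 0.25)
    return MotifDefinition.pwm(name, arr, threshold=threshold, threshold_frac=threshold_frac)


# --- scanning ---------------------------------------------------------------


@lru_cache(maxsize=256)
def _compiled(positions: tuple[frozenset[str], ...]) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    body = "".join("[" + "".join(sorted(s)) + "]" for s in positions)
    return re.compile(f"(?=({body}))")


def consensus_hit_positions(sequence: str, positions: tuple[frozenset[str], ...]) -> tuple[int, ...]:
    """Offsets of all (overlapping) matches of a degenerate consensus."""
    if len(sequence) < len(positions):
        return ()
    return tuple(m.start() for m in _compiled(positions).finditer(sequence))


def _resolve_dss(dss: DownstreamSequence | str, gene_id: str | None) -> tuple[str, str]:
    if isinstance(dss, DownstreamSequence):
        return dss.sequence, dss.gene_id
    return dss, gene_id or ""


def scan_consensus(
    dss: DownstreamSequence | str,
    motif: MotifDefinition,
    gene_id: str | None = None,
) -> MotifHitSet:
    """All overlapping hits of a consensus motif in one DSS."""
    if motif.kind != "consensus":
        raise ValueError(f"scan_consensus requires a consensus motif, got {motif.kind}")
    seq, gid = _resolve_dss(dss, gene_id)
    hits = consensus_hit_positions(seq.upper(), motif.positions)
    return MotifHitSet(gid, motif.name, hits, len(hits), len(hits) >= 1)


def scan_pwm(
    dss: DownstreamSequence | str,
    motif: MotifDefinition,
    gene_id: str | None = None,
) -> MotifHitSet:
    """PWM hits: offsets where the summed log-odds score meets the threshold.

    An ``N`` (or any non-ACGT character) anywhere under the motif window
    disqualifies that offset.
    """
    if motif.kind != "pwm":
        raise ValueError(f"scan_pwm requires a pwm motif, got {motif.kind}")
    seq, gid = _resolve_dss(dss, gene_id)
    seq = seq.upper()
    width = len(motif.pwm_scores)
    n = len(seq) - width + 1
    if n <= 0:
        return MotifHitSet(gid, motif.name, (), 0, False)
    idx = np.fromiter((_BASE_INDEX.get(c, -1) for c in seq), dtype=np.int64, count=len(seq))
    mat = np.asarray(motif.pwm_scores, dtype=float)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(width):
        col = idx[j : j + n]
        bad = col < 0
        valid &= ~bad
        scores += mat[j, np.where(bad, 0, col)]
    with np.errstate(invalid="ignore"):
        ok = valid & (scores >= motif.threshold)
    hits = tuple(int(i) for i in np.nonzero(ok)[0])
    return MotifHitSet(gid, motif.name, hits, len(hits), len(hits) >= 1)


_CU_RUN_CACHE: dict[int, re.Pattern] = {}


def find_cu_runs(sequence: str, min_run_length: int = 4) -> list[tuple[int, int]]:
    """Maximal runs of consecutive C/T bases of at least ``min_run_length`` nt.

    Maximality means a run cannot be extended in either direction, so one
    long pyrimidine tract is a single run, never several.
    """
    if min_run_length < 1:
        raise ValueError("min_run_length must be >= 1")
    pat = _CU_RUN_CACHE.get(min_run_length)
    if pat is None:
        pat = re.compile("[CT]{%d,}" % min_run_length)
        _CU_RUN_CACHE[min_run_length] = pat
    return [(m.start(), m.end() - m.start()) for m in pat.finditer(sequence.upper())]


def ptb_cluster_call(
    dss: DownstreamSequence | str,
    cu_params: CuParams | None = None,
    gene_id: str | None = None,
) -> MotifHitSet:
    """PTB target call: >= ``min_runs`` maximal CU runs in the DSS window.

    ``hit_positions`` are the starts of the qualifying runs and ``count`` is
    the number of runs (not of matches of a fixed-width pattern).
    """
    params = cu_params or CuParams()
    seq, gid = _resolve_dss(dss, gene_id)
    if isinstance(dss, DownstreamSequence) and dss.window != params.window:
        raise ValueError(
            f"PTB call expects a {params.window}-nt DSS, got window {dss.window}"
        )
    runs = find_cu_runs(seq, params.min_run_length)
    starts = tuple(s for s, _ in runs)
    return MotifHitSet(gid, "ptb", starts, len(starts), len(starts) >= params.min_runs)


def rbp50_screen(
    dss: DownstreamSequence | str,
    lowercase_policy: str = "pyrimidine",
    gene_id: str | None = None,
) -> MotifHitSet:
    """Screen one DSS for the RBP50 15-mer (intended for the PTB-positive pool)."""
    return scan_consensus(dss, rbp50_definition(lowercase_policy), gene_id=gene_id)


# --- summary statistics ------------------------------------------------------


def multiplicity_histogram(hits: Iterable[MotifHitSet]) -> dict[int, int]:
    """Per-gene hit-count histogram ``{count: n_genes}``, zero-hit genes excluded."""
    hist: dict[int, int] = {}
    motif = None
    for hs in hits:
        if motif is None:
            motif = hs.motif_name
        elif hs.motif_name != motif:
            raise ValueError(
                f"mixed motifs in multiplicity input: {motif!r} vs {hs.motif_name!r}"
            )
        if hs.count >= 1:
            hist[hs.count] = hist.get(hs.count, 0) + 1
    return dict(sorted(hist.items()))


def cooccurrence_table(positives: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Gene counts for every non-empty combination of motif-positive sets.

    ``inclusion`` counts genes positive for *at least* the motifs of the
    combination (a gene with all three motifs contributes to every applicable
    row); ``exclusive`` counts genes positive for exactly that combination.
    """
    sets = {m: frozenset(g) for m, g in positives.items()}
    names = sorted(sets)
    rows = []
    for mask in range(1, 2 ** len(names)):
        combo = [names[i] for i in range(len(names)) if mask >> i & 1]
        inter = frozenset.intersection(*(sets[m] for m in combo))
        others = [sets[m] for m in names if m not in combo]
        excl = inter.difference(*others) if others else inter
        rows.append(
            {
                "combination": "+".join(combo),
                "n_motifs": len(combo),
                "inclusion": len(inter),
                "exclusive": len(excl),
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["n_motifs", "combination"], ignore_index=True
    )


def positional_profile(
    hits: Iterable[MotifHitSet],
    window: int,
    bin_width: int = 100,
    motif_name: str | None = None,
) -> PositionalProfile:
    """Bin hit start offsets and test them against a uniform distribution.

    The test is a Pearson chi-square goodness-of-fit with
    ``window/bin_width - 1`` degrees of freedom; a profile with no hits has
    all-zero bins and p = 1.
    """
    if window % bin_width != 0:
        raise ValueError("bin_width must divide the window")
    nbins = window // bin_width
    offsets: list[int] = []
    for hs in hits:
        if motif_name is None:
            motif_name = hs.motif_name
        offsets.extend(p for p in hs.hit_positions if 0 <= p < window)
    counts = np.bincount(
        np.asarray(offsets, dtype=int) // bin_width, minlength=nbins
    ) if offsets else np.zeros(nbins, dtype=int)
    total = int(counts.sum())
    if total == 0:
        return PositionalProfile(motif_name or "", bin_width, tuple(int(c) for c in counts), 0.0, 1.0)
    stat, p = stats.chisquare(counts)
    return PositionalProfile(
        motif_name or "",
        bin_width,
        tuple(int(c) for c in counts),
        float(stat),
        float(p),
    )


def hits_to_frame(hits: Iterable[MotifHitSet], window: int) -> pd.DataFrame:
    """Long-format hit table (gene_id, motif, position, window) for TSV export."""
    rows = [
        {"gene_id": hs.gene_id, "motif": hs.motif_name, "position": p, "window": window}
        for hs in hits
        for p in hs.hit_positions
    ]
    return pd.DataFrame(rows, columns=["gene_id", "motif", "position", "window"])
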