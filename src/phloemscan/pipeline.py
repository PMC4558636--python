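"""End-to-end orchestration: genome -> DSS -> motif screens -> expression -> join.

One :class:`RunConfig` (usually loaded from a YAML file) drives the whole
run.  The stage order mirrors the screening protocol: downstream sequences
are extracted at every configured window (longest first); Pumilio and Nova
consensus scans run at each window, the PTB CU-cluster call at its own
200-nt window, and the RBP50 15-mer screen over the PTB-positive pool at
the longest window; count normalization, group means and abundance /
specificity classification follow; finally motif target calls are joined
with the expression strata and any user gene lists.

All outputs are plain TSV (plus a FASTA per DSS window) under one output
directory, together with a ``manifest.json`` recording the config hash,
input checksums, seed and row counts.  Runs are deterministic: identical
inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import expression as expr
from . import genome as gio
from . import motifs as mot

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "load_config", "run_pipeline",
           "read_counts_tsv", "read_design_tsv"]


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    genome_fasta: str
    annotation_gff: str
    counts_tsv: str
    design_tsv: str
    out_dir: str
    windows: tuple[int, ...] = (1000, 500, 200)
    motif_names: tuple[str, ...] = ("pumilio", "nova", "ptb", "rbp50")
    pwm_files: Mapping[str, str] = field(default_factory=dict)
    pwm_threshold_frac: float = 0.8
    gene_lists: Mapping[str, str] = field(default_factory=dict)
    de_labels_tsv: str | None = None
    quantile: float = 0.75
    abundance_thresholds: tuple[float, ...] = (10, 500, 1000)
    present_threshold: float = 10
    absent_threshold: float = 0
    lowercase_policy: str = "pyrimidine"
    cu_min_run_length: int = 4
    cu_min_runs: int = 4
    cu_window: int = 200
    bin_width: int = 100
    seed: int = 0

    def validate(self) -> None:
        required = {
            "genome_fasta": self.genome_fasta,
            "annotation_gff": self.annotation_gff,
            "counts_tsv": self.counts_tsv,
            "design_tsv": self.design_tsv,
        }
        for key, path in required.items():
            if not Path(path).is_file():
                raise ConfigError(f"{key} does not exist: {path}")
        for name, path in {**dict(self.pwm_files), **dict(self.gene_lists)}.items():
            if not Path(path).is_file():
                raise ConfigError(f"file for {name!r} does not exist: {path}")
        if self.de_labels_tsv and not Path(self.de_labels_tsv).is_file():
            raise ConfigError(f"de_labels_tsv does not exist: {self.de_labels_tsv}")
        if list(self.windows) != sorted(self.windows, reverse=True):
            raise ConfigError("windows must be sorted descending")
        if self.cu_window not in self.windows:
            raise ConfigError("cu_window must be one of the configured windows")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("windows", "motif_names", "abundance_thresholds"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    return counts


def read_design_tsv(path: str | Path) -> dict[str, str]:
    design = pd.read_csv(path, sep="\t")
    cols = list(design.columns)
    if cols[:2] != ["library_id", "group"]:
        # header-less two-column file
        design = pd.read_csv(path, sep="\t", header=None, names=["library_id", "group"])
    return dict(zip(design["library_id"].astype(str), design["group"].astype(str)))


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> int:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g", lineterminator="\n")
    return len(frame)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        # out_dir is where the manifest itself lives; keeping it out of the
        # manifest lets two runs into different directories stay byte-identical
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if k != "out_dir"
        },
        "seed": config.seed,
        "inputs": {
            "genome_fasta": _sha256_file(config.genome_fasta),
            "annotation_gff": _sha256_file(config.annotation_gff),
            "counts_tsv": _sha256_file(config.counts_tsv),
            "design_tsv": _sha256_file(config.design_tsv),
        },
        "outputs": {},
        "stages": [],
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    def stage(name: str) -> None:
        # timings go to the log only, so manifests stay byte-identical across runs
        manifest["stages"].append(name)
        logger.info("stage %s done (%.2fs)", name, time.time() - t0)

    # --- genome and DSS -----------------------------------------------------
    contigs = gio.read_genome(config.genome_fasta)
    genes, report = gio.read_annotation(config.annotation_gff, with_report=True)
    genes = sorted(genes, key=lambda g: g.gene_id)
    manifest["annotation"] = vars(report)
    max_window = max(config.windows)
    dss_max = {g.gene_id: gio.extract_dss(g, contigs, max_window) for g in genes}
    dss_by_window: dict[int, dict[str, gio.DownstreamSequence]] = {max_window: dss_max}
    for w in config.windows:
        if w != max_window:
            dss_by_window[w] = {gid: d.prefix(w) for gid, d in dss_max.items()}
    for w in config.windows:
        path = out / f"dss_{w}.fasta"
        path.write_text(gio.dss_to_fasta(dss_by_window[w].values()))
        manifest["outputs"][path.name] = len(dss_by_window[w])
    stage("extract_dss")

    # --- motif scans ---------------------------------------------------------
    cu_params = mot.CuParams(config.cu_min_run_length, config.cu_min_runs, config.cu_window)
    defs = mot.builtin_motifs(config.lowercase_policy, cu_params)
    for name, path in config.pwm_files.items():
        defs[name] = mot.load_pwm(
            str(path), name=name, threshold_frac=config.pwm_threshold_frac
        )

    hits: dict[tuple[str, int], dict[str, mot.MotifHitSet]] = {}
    for name in config.motif_names:
        if name not in defs:
            raise ConfigError(f"unknown motif {name!r}; known: {sorted(defs)}")
        d = defs[name]
        if d.kind == "cu_cluster":
            scan_windows = [config.cu_window]
        elif name == "rbp50":
            scan_windows = [max_window]  # screened over the PTB-positive pool below
        else:
            scan_windows = list(config.windows)
        for w in scan_windows:
            per_gene = {}
            for gid, dss in dss_by_window[w].items():
                if d.kind == "consensus":
                    per_gene[gid] = mot.scan_consensus(dss, d)
                elif d.kind == "pwm":
                    per_gene[gid] = mot.scan_pwm(dss, d)
                else:
                    per_gene[gid] = mot.ptb_cluster_call(dss, cu_params)
            hits[(name, w)] = per_gene

    if ("rbp50", max_window) in hits and ("ptb", config.cu_window) in hits:
        ptb_pool = {
            gid for gid, hs in hits[("ptb", config.cu_window)].items() if hs.is_target
        }
        hits[("rbp50", max_window)] = {
            gid: hs for gid, hs in hits[("rbp50", max_window)].items() if gid in ptb_pool
        }

    for (name, w), per_gene in hits.items():
        frame = mot.hits_to_frame(per_gene.values(), w)
        manifest["outputs"][f"hits_{name}_{w}.tsv"] = _write_tsv(
            frame, out / f"hits_{name}_{w}.tsv", index=False
        )
    stage("scan")

    # study windows used for target calls and downstream joins
    call_window = {
        name: (config.cu_window if defs[name].kind == "cu_cluster"
               else max_window if name == "rbp50"
               else min(config.windows, key=lambda w: abs(w - 500)))
        for name in config.motif_names
    }

    for name in config.motif_names:
        per_gene = hits[(name, call_window[name])]
        hist = mot.multiplicity_histogram(
            [h for h in per_gene.values() if h.count >= 1]
        )
        frame = pd.DataFrame(
            {"hits_per_gene": list(hist), "n_genes": list(hist.values())}
        )
        manifest["outputs"][f"multiplicity_{name}.tsv"] = _write_tsv(
            frame, out / f"multiplicity_{name}.tsv", index=False
        )

    positives = {
        name: {gid for gid, hs in hits[(name, call_window[name])].items() if hs.is_target}
        for name in config.motif_names
    }
    cooc = mot.cooccurrence_table(positives)
    manifest["outputs"]["cooccurrence.tsv"] = _write_tsv(
        cooc, out / "cooccurrence.tsv", index=False
    )

    for name in config.motif_names:
        if defs[name].kind == "cu_cluster":
            w = config.cu_window
        else:
            w = max_window
        prof = mot.positional_profile(
            hits[(name, w)].values(), w, config.bin_width, motif_name=name
        )
        frame = pd.DataFrame(
            {
                "bin_start": [i * config.bin_width for i in range(len(prof.bin_counts))],
                "count": prof.bin_counts,
            }
        )
        frame["chi2"] = prof.statistic
        frame["p_uniform"] = prof.enrichment_p
        manifest["outputs"][f"positional_{name}.tsv"] = _write_tsv(
            frame, out / f"positional_{name}.tsv", index=False
        )
    stage("motif_stats")

    # --- expression -----------------------------------------------------------
    counts = read_counts_tsv(config.counts_tsv)
    groups = read_design_tsv(config.design_tsv)
    normalized = expr.upper_quantile_normalize(counts, config.quantile)
    means = expr.group_means(normalized, groups)
    classes, class_counts = expr.classify_abundance(means, config.abundance_thresholds)
    summary = pd.concat(
        [means.add_prefix("mean_"), classes.add_prefix("class_")], axis=1
    )
    if means.shape[1] == 2:
        summary["specificity"] = expr.classify_specificity(
            means,
            present_threshold=config.present_threshold,
            absent_threshold=config.absent_threshold,
        )
    summary.index.name = "gene_id"
    manifest["outputs"]["expression_summary.tsv"] = _write_tsv(
        summary, out / "expression_summary.tsv"
    )
    manifest["abundance_counts"] = {
        str(col): {str(t): int(n) for t, n in class_counts[col].items()}
        for col in class_counts.columns
    }
    stage("expression")

    # --- join -----------------------------------------------------------------
    universe = sorted(dss_max)
    targets = pd.DataFrame(
        {
            name: pd.Series(
                {gid: hs.is_target for gid, hs in hits[(name, call_window[name])].items()},
                dtype=bool,
            ).reindex(universe, fill_value=False)
            for name in config.motif_names
        }
    )
    gene_lists = {
        name: [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        for name, path in config.gene_lists.items()
    }
    de_labels = None
    if config.de_labels_tsv:
        de = pd.read_csv(config.de_labels_tsv, sep="\t", index_col=0)
        de_labels = de.iloc[:, 0].astype(bool)
    per_gene, joined = expr.category_join(
        means,
        targets,
        gene_lists=gene_lists,
        de_labels=de_labels,
        abundance_thresholds=tuple(
            t for t in config.abundance_thresholds if t in (10, 500)
        ) or tuple(config.abundance_thresholds[:2]),
    )
    manifest["outputs"]["joined_report.tsv"] = _write_tsv(joined, out / "joined_report.tsv")
    manifest["outputs"]["gene_report.tsv"] = _write_tsv(per_gene, out / "gene_report.tsv")
    stage("join")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
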