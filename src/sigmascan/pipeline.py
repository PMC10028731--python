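"""End-to-end orchestration: simulate -> peaks -> motif -> scan.

Every stage reads and writes only the flat-text formats in `sigmascan.io`,
logs the choke-point counts (peaks called, peaks passing the shape screen,
windows used, hits below threshold), and a run manifest records the resolved
configuration, per-stage counts and output checksums so a run can be audited
and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as sio
from .coverage import (
    CoverageTrack,
    Peak,
    PeakCallerParams,
    apply_exclusions,
    call_peaks,
    extract_site_windows,
    normalize_coverage,
    peaks_to_bed6,
    peaks_to_tsv,
)
from .motif import (
    MotifModel,
    build_count_matrix,
    counts_to_probabilities,
    discover_motif_zoops,
    information_content,
    read_meme_motif,
    write_meme_motif,
)
from .scan import extract_promoters, hits_to_tsv, scan_queries, scan_report
from .simulate import SyntheticRegulonConfig, simulate_regulon, write_fixture_bundle

logger = logging.getLogger(__name__)


@dataclass
class MotifParams:
    mode: str = "discover"  # "discover" (ZOOPS-EM) or "direct" (PPM from windows)
    width: int = 20
    n_starts: int = 5
    max_iter: int = 200
    tol: float = 1e-6
    pseudocount: float = 0.0
    r_threshold: float = 1.0
    # peak windows are unstranded, so discovery searches both orientations
    both_strands: bool = True
    min_windows: int = 2


@dataclass
class ScanParams:
    p_threshold: float = 1e-4
    q_threshold: float = 0.6
    background: str = "query"  # or "uniform"
    both_strands: bool = True
    promoter_length: int = 100
    targets: str = "promoters"  # "promoters", "genome" or "both"
    smoothing: float = 1e-4
    step: float = 1e-3


@dataclass
class PipelineConfig:
    output_dir: str = "sigmascan_out"
    seed: int = 0
    genome_fasta: str | None = None
    ip_bedgraph: str | None = None
    control_bedgraphs: list[str] = field(default_factory=list)
    gff3: str | None = None
    normalize_before_exclusion: bool = False
    peaks: PeakCallerParams = field(default_factory=PeakCallerParams)
    motif: MotifParams = field(default_factory=MotifParams)
    scan: ScanParams = field(default_factory=ScanParams)
    simulate: SyntheticRegulonConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "peaks" in kwargs and isinstance(kwargs["peaks"], dict):
            pk = dict(kwargs["peaks"])
            if "exclusions" in pk:
                pk["exclusions"] = [tuple(e) for e in pk["exclusions"]]
            kwargs["peaks"] = PeakCallerParams(**pk)
        if "motif" in kwargs and isinstance(kwargs["motif"], dict):
            kwargs["motif"] = MotifParams(**kwargs["motif"])
        if "scan" in kwargs and isinstance(kwargs["scan"], dict):
            kwargs["scan"] = ScanParams(**kwargs["scan"])
        if kwargs.get("simulate") is not None and isinstance(kwargs["simulate"], dict):
            kwargs["simulate"] = SyntheticRegulonConfig(**kwargs["simulate"])
        return cls(**kwargs)

    def validate(self) -> None:
        """Fail fast before any stage runs: required inputs must exist."""
        if self.simulate is None:
            missing = [
                p
                for p in [self.genome_fasta, self.ip_bedgraph, *self.control_bedgraphs]
                if p is None or not Path(p).exists()
            ]
            if missing or self.ip_bedgraph is None or self.genome_fasta is None:
                raise FileNotFoundError(
                    f"missing inputs and simulator disabled: {missing}"
                )


def _resolved_config(cfg: PipelineConfig) -> dict:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, MotifModel):
            return {"consensus": o.consensus(), "width": o.width}
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, dict):
            return {k: enc(v) for k, v in o.items()}
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return o

    d = {f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)}
    if isinstance(d.get("simulate"), SyntheticRegulonConfig):
        sim = {
            f.name: getattr(d["simulate"], f.name)
            for f in dataclasses.fields(d["simulate"])
        }
        sim["motif"] = {"consensus": d["simulate"].motif.consensus(),
                        "width": d["simulate"].motif.width}
        d["simulate"] = sim
    return enc(d)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages

def run_simulate_stage(cfg: PipelineConfig) -> dict[str, str]:
    sim = dataclasses.replace(cfg.simulate, seed=cfg.simulate.seed)
    genome, truth, ip, control = simulate_regulon(sim)
    out = Path(cfg.output_dir) / "fixture"
    paths = write_fixture_bundle(genome, truth, ip, control, out)
    logger.info("simulated %d sites, %d genes", truth.n_sites, len(truth.gene_records))
    cfg.genome_fasta = paths["genome_fasta"]
    cfg.ip_bedgraph = paths["ip_bedgraph"]
    cfg.control_bedgraphs = [paths["control_bedgraph"]]
    cfg.gff3 = paths["gff3"]
    return paths


def _load_track(path: str, length: int) -> CoverageTrack:
    chrom, values = sio.read_bedgraph(path, length)
    return CoverageTrack(chrom, values)


def run_peaks_stage(cfg: PipelineConfig) -> tuple[list[Peak], list[str], dict]:
    """normalize -> exclude -> call -> shape screen -> summit windows."""
    genome = sio.read_fasta(cfg.genome_fasta)
    (chrom, seq), = genome.items()
    L = len(seq)

    raw_ip = _load_track(cfg.ip_bedgraph, L)
    if raw_ip.values.max() == 0:
        # an empty/failed IP sample yields nothing rather than a
        # zero-median normalization error at the pipeline level
        logger.warning("IP track is empty; reporting 0 peaks")
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "peaks.bed").write_text("")
        (out / "peaks.tsv").write_text(peaks_to_tsv([]))
        sio.write_fasta([], out / "site_windows.fa")
        return [], [], {"peaks_called": 0, "peaks_passing_shape": 0,
                        "windows_extracted": 0}

    def prep(path: str) -> CoverageTrack:
        t = _load_track(path, L)
        t.chrom = chrom if t.chrom == "" else t.chrom
        if cfg.normalize_before_exclusion:
            t = normalize_coverage(t)
            t = apply_exclusions(t, cfg.peaks.exclusions)
        else:
            t = apply_exclusions(t, cfg.peaks.exclusions)
            t = normalize_coverage(t)
        return t

    ip = prep(cfg.ip_bedgraph)
    controls = [prep(p) for p in cfg.control_bedgraphs]
    peaks = call_peaks(ip, controls, cfg.peaks)
    kept = [p for p in peaks if p.passed_shape]
    logger.info(
        "called %d putative peaks; %d pass the triangularity screen (>= %.2f)",
        len(peaks), len(kept), cfg.peaks.triangularity_min,
    )
    windows = extract_site_windows(seq, kept, cfg.peaks.window_width)
    logger.info("extracted %d summit windows of %d bp", len(windows), cfg.peaks.window_width)

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "peaks.bed").write_text(peaks_to_bed6(kept))
    (out / "peaks.tsv").write_text(peaks_to_tsv(peaks))
    sio.write_fasta(
        [(f"peak{i:03d}|{chrom}:{p.start}-{p.end}|summit={p.summit}", wseq)
         for i, (p, wseq) in enumerate(zip(kept, windows))],
        out / "site_windows.fa",
    )
    counts = {
        "peaks_called": len(peaks),
        "peaks_passing_shape": len(kept),
        "windows_extracted": len(windows),
    }
    return kept, windows, counts


def run_motif_stage(cfg: PipelineConfig, windows: list[str]) -> tuple[MotifModel, dict]:
    mp = cfg.motif
    if len(windows) < mp.min_windows:
        raise ValueError(
            f"motif stage needs >= {mp.min_windows} windows, got {len(windows)}"
        )
    if mp.mode == "discover":
        result = discover_motif_zoops(
            windows, mp.width, n_starts=mp.n_starts, max_iter=mp.max_iter,
            tol=mp.tol, seed=cfg.seed, both_strands=mp.both_strands,
        )
        model = result.model
        n_contrib = sum(1 for _, _, pr in result.site_calls if pr > 0.5)
        logger.info(
            "ZOOPS-EM: gamma=%.3f, %d/%d windows contribute a site, consensus %s",
            result.gamma, n_contrib, len(windows), model.consensus(),
        )
    elif mp.mode == "direct":
        counts = build_count_matrix(windows)
        model = counts_to_probabilities(counts, mp.pseudocount)
        n_contrib = len(windows)
        logger.info("direct PPM from %d aligned windows", len(windows))
    else:
        raise ValueError(f"unknown motif mode {mp.mode!r}")

    r = information_content(model)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "motif.meme").write_text(write_meme_motif(model, name="SIGMA_MOTIF"))
    lines = ["position\tR_seq\tmasked"]
    for i, ri in enumerate(r):
        lines.append(f"{i}\t{ri:.4f}\t{int(ri <= mp.r_threshold)}")
    (out / "information_profile.tsv").write_text("\n".join(lines) + "\n")
    counts = {
        "windows_used": len(windows),
        "windows_contributing": n_contrib,
        "mode": mp.mode,
        "consensus": model.consensus(),
        "positions_below_r_threshold": int((r <= mp.r_threshold).sum()),
    }
    return model, counts


def run_scan_stage(
    cfg: PipelineConfig, model: MotifModel
) -> tuple["pd.DataFrame", "pd.DataFrame", dict]:
    import pandas as pd  # noqa: F401  (re-export convenience)

    genome = sio.read_fasta(cfg.genome_fasta)
    sp = cfg.scan
    queries: dict[str, str] = {}
    promoter_genes: dict[str, str] = {}
    if sp.targets in ("promoters", "both"):
        ann = sio.read_gff3_cds(cfg.gff3)
        for rec in extract_promoters(ann, genome, sp.promoter_length):
            queries[rec.fasta_id] = rec.sequence
            promoter_genes[rec.fasta_id] = rec.gene_id
    if sp.targets in ("genome", "both"):
        for chrom, seq in genome.items():
            queries[chrom] = seq

    hits, pool = scan_queries(
        model, queries,
        p_threshold=sp.p_threshold, both_strands=sp.both_strands,
        background=sp.background, mask_r_threshold=cfg.motif.r_threshold,
        smoothing=sp.smoothing, step=sp.step,
    )
    filtered, full = scan_report(hits, sp.q_threshold)
    for df in (filtered, full):
        if not df.empty:
            df["gene_id"] = df["seq_id"].map(promoter_genes)
    logger.info(
        "scanned %d queries (%d windows); %d hits at p<=%g, %d below q<=%g",
        len(queries), pool.size, len(full), sp.p_threshold, len(filtered), sp.q_threshold,
    )
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "hits_full.tsv").write_text(hits_to_tsv(full))
    (out / "hits_filtered.tsv").write_text(hits_to_tsv(filtered))
    counts = {
        "queries_scanned": len(queries),
        "windows_scored": int(pool.size),
        "hits_reported": len(full),
        "hits_below_q_threshold": len(filtered),
    }
    return filtered, full, counts


def run_all(cfg: PipelineConfig) -> dict:
    """Full pipeline; returns the run manifest (also written as JSON)."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "sigmascan_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "stages": {},
    }
    if cfg.simulate is not None:
        paths = run_simulate_stage(cfg)
        manifest["stages"]["simulate"] = {"outputs": {k: _sha256(v) for k, v in paths.items()}}
    peaks, windows, peak_counts = run_peaks_stage(cfg)
    manifest["stages"]["peaks"] = {
        "counts": peak_counts,
        "outputs": {n: _sha256(out / n) for n in ("peaks.bed", "peaks.tsv", "site_windows.fa")},
    }
    model, motif_counts = run_motif_stage(cfg, windows)
    manifest["stages"]["motif"] = {
        "counts": motif_counts,
        "outputs": {n: _sha256(out / n) for n in ("motif.meme", "information_profile.tsv")},
    }
    _, _, scan_counts = run_scan_stage(cfg, model)
    manifest["stages"]["scan"] = {
        "counts": scan_counts,
        "outputs": {n: _sha256(out / n) for n in ("hits_full.tsv", "hits_filtered.tsv")},
    }
    manifest["resolved_config"] = _resolved_config(cfg)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
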