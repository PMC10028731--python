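"""Synthetic ChIP-seq regulon generator.

Emulates the data the coverage-to-motif analysis assumes: a random genome
with motif instances planted at known positions, an annotation with some
genes whose 100-bp upstream region contains a planted site, an IP coverage
track whose planted-site pileups are sharply peaked and near-triangular, and
a featureless control track.

IP signal model: each planted site receives a Poisson-distributed number of
immunoprecipitated fragments (mean ``enrichment``); fragment midpoints are
Laplace-displaced around the site center with scale ``peak_spread`` and each
fragment contributes 1x coverage over its ``fragment_length`` bases. On top
sits uniform per-base Poisson background of mean ``background_depth``. The
control track is background only. Defaults correspond to a strongly induced,
epitope-tagged sigma factor (site pileups ~50x the background median).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .coverage import CoverageTrack
from .motif import MotifModel


def default_sigma_motif() -> MotifModel:
    """A width-20 sigma-factor-like motif: two conserved blocks (-35/-10
    analogue, letter probability 0.95) separated by a 4-column degenerate
    spacer (letter probability 0.55). Mean column R_seq ~= 1.37 bits; the
    spacer columns fall below 1 bit and exercise the masking rule."""
    consensus = "TGGAACGTACGTCGTCTATA"
    strong = set(range(8)) | set(range(12, 20))
    p = np.zeros((20, 4))
    for i, c in enumerate(consensus):
        s = "ACGT".index(c)
        major = 0.95 if i in strong else 0.55
        p[i] = (1.0 - major) / 3.0
        p[i, s] = major
    return MotifModel(probabilities=p, n_sites=0)


@dataclass
class SyntheticRegulonConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    n_sites: int = 12
    motif: MotifModel = field(default_factory=default_sigma_motif)
    site_placement: list[tuple[int, int]] | str = "random"
    n_genes: int = 8
    n_genes_with_sites: int = 3
    gene_length: int = 600
    enrichment: float = 600.0
    background_depth: float = 10.0
    fragment_length: int = 50
    peak_spread: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.fragment_length < self.motif.width:
            raise ValueError("fragment_length must be >= motif width")
        if self.background_depth < 0 or self.enrichment < 0:
            raise ValueError("depths must be >= 0")
        if self.n_genes_with_sites > min(self.n_genes, max(self.n_sites, 0)):
            raise ValueError("n_genes_with_sites exceeds n_genes or n_sites")


@dataclass
class GroundTruth:
    """Planted-site manifest: sites as (start, end, strand, sequence) in
    0-based half-open genome coordinates; peak_centers are site midpoints;
    gene_records carry a has_planted_site_in_promoter flag."""

    sites: pd.DataFrame
    peak_centers: list[int]
    gene_records: pd.DataFrame

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def simulate_genome(length: int, gc_fraction: float, seed: int) -> str:
    """i.i.d. genome with P(G) = P(C) = gc_fraction / 2."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    draws = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join("ACGT"[i] for i in draws)


def _sample_site(motif: MotifModel, rng: np.random.Generator) -> str:
    letters = [
        "ACGT"[rng.choice(4, p=motif.probabilities[i])] for i in range(motif.width)
    ]
    return "".join(letters)


def sample_sites_and_plant(
    config: SyntheticRegulonConfig, genome: str
) -> tuple[str, GroundTruth]:
    """Sample n_sites sequences from the motif PPM, plant them at
    non-overlapping positions (uniform strand; minus-strand sites planted as
    the reverse complement), and lay out gene annotations so that
    n_genes_with_sites genes have a planted site inside their upstream
    100 bp. Returns the modified genome and the ground truth."""
    w = config.motif.width
    L = len(genome)
    if w > L:
        raise ValueError("motif wider than genome")
    rng = np.random.default_rng(config.seed)

    # --- site placement
    if config.site_placement == "random":
        placed: list[int] = []
        # keep sites and their flanking peak footprint apart; margin also
        # leaves room for gene placement downstream of each site
        margin = max(4 * config.fragment_length, 2 * w, 200)
        attempts, cap = 0, 1000 * max(config.n_sites, 1)
        lo, hi = 2 * margin, L - 2 * margin - w
        if config.n_sites > 0 and hi <= lo:
            raise ValueError("genome too short for requested sites")
        while len(placed) < config.n_sites:
            attempts += 1
            if attempts > cap:
                raise RuntimeError(
                    f"could not place {config.n_sites} non-overlapping sites "
                    f"in {cap} attempts"
                )
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - q) >= margin for q in placed):
                placed.append(pos)
        placed.sort()
    else:
        placed = [int(s) for s, _ in config.site_placement]
        if len(placed) != config.n_sites:
            raise ValueError("site_placement length must equal n_sites")
        ends = sorted((s, s + w) for s in placed)
        for (s1, e1), (s2, e2) in zip(ends, ends[1:]):
            if s2 < e1:
                raise ValueError("requested site placements overlap")
        if placed and (min(placed) < 0 or max(placed) + w > L):
            raise ValueError("site placement outside genome")

    seq = list(genome)
    rows = []
    for k, start in enumerate(placed):
        site_seq = _sample_site(config.motif, rng)
        strand = "+" if rng.integers(2) == 0 else "-"
        planted = site_seq if strand == "+" else sio.reverse_complement(site_seq)
        seq[start : start + w] = planted
        rows.append(
            dict(
                site_id=f"site{k:03d}",
                chrom="synthetic_chr",
                start=start,
                end=start + w,
                strand=strand,
                sequence=site_seq,
            )
        )
    sites = pd.DataFrame(rows, columns=sio.TRUTH_COLUMNS)
    centers = [int(s + w // 2) for s in placed]

    # --- gene layout: first n_genes_with_sites genes sit just downstream of
    # a planted site so the site falls inside their 100-bp upstream window
    genes = []
    used: list[tuple[int, int]] = []
    gl = config.gene_length
    for g in range(config.n_genes_with_sites):
        s_start, s_end = placed[g], placed[g] + w
        offset = int(rng.integers(5, max(6, 100 - w - 5)))
        cds_start = s_end + offset  # site within [cds_start-100, cds_start)
        cds_end = min(cds_start + gl, L)
        genes.append(("+", cds_start, cds_end, True))
        used.append((cds_start - 150, cds_end))
    tries = 0
    while len(genes) < config.n_genes:
        tries += 1
        if tries > 1000 * config.n_genes:
            raise RuntimeError("could not place site-free genes")
        cds_start = int(rng.integers(150, L - gl - 150))
        cds_end = cds_start + gl
        strand = "+" if rng.integers(2) == 0 else "-"
        prom = (cds_start - 100, cds_start) if strand == "+" else (cds_end, cds_end + 100)
        span = (min(cds_start, prom[0]), max(cds_end, prom[1]))
        if any(span[0] < e and s < span[1] for s, e in used):
            continue
        # promoter and gene body must stay clear of planted peaks
        if any(span[0] - 2 * config.fragment_length < c < span[1] + 2 * config.fragment_length for c in centers):
            continue
        genes.append((strand, cds_start, cds_end, False))
        used.append(span)
    gene_records = pd.DataFrame(
        [
            dict(
                gene_id=f"gene{g:03d}",
                chrom="synthetic_chr",
                start=s,
                end=e,
                strand=strand,
                has_planted_site_in_promoter=flag,
            )
            for g, (strand, s, e, flag) in enumerate(genes)
        ]
    )
    truth = GroundTruth(sites=sites, peak_centers=centers, gene_records=gene_records)
    return "".join(seq), truth


def simulate_chip_coverage(
    config: SyntheticRegulonConfig, truth: GroundTruth
) -> tuple[CoverageTrack, CoverageTrack]:
    """IP and control coverage tracks (raw counts, one chromosome).

    IP = per-base Poisson background + pileup of Poisson(enrichment)
    Laplace-displaced fragments per planted site; control = background only.
    """
    L = config.genome_length
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    control = rng.poisson(config.background_depth, size=L).astype(np.float64)
    ip = rng.poisson(config.background_depth, size=L).astype(np.float64)

    diff = np.zeros(L + 1)
    half = config.fragment_length / 2.0
    for center in truth.peak_centers:
        n_frag = rng.poisson(config.enrichment)
        mids = center + rng.laplace(0.0, config.peak_spread, size=n_frag)
        lo = np.clip(np.rint(mids - half).astype(np.int64), 0, L)
        hi = np.clip(np.rint(mids + half).astype(np.int64), 0, L)
        np.add.at(diff, lo, 1.0)
        np.add.at(diff, hi, -1.0)
    ip += np.cumsum(diff[:-1])

    chrom = "synthetic_chr"
    return CoverageTrack(chrom, ip), CoverageTrack(chrom, control)


def expected_fragment_overlap(
    offset: float, fragment_length: int, peak_spread: float
) -> float:
    """Closed-form probability that a fragment whose Laplace(peak_spread)
    midpoint is displaced from the site center covers the base at ``offset``
    from the center: F(offset + L/2) - F(offset - L/2)."""

    def cdf(x):
        return 0.5 * np.exp(x / peak_spread) if x < 0 else 1.0 - 0.5 * np.exp(-x / peak_spread)

    half = fragment_length / 2.0
    return cdf(offset + half) - cdf(offset - half)


def write_fixture_bundle(
    genome: str,
    truth: GroundTruth,
    ip: CoverageTrack,
    control: CoverageTrack,
    out_dir: str | Path,
) -> dict[str, str]:
    """Write genome FASTA, IP/control bedGraph, GFF3 CDS annotation and the
    truth manifest TSV; returns {name: path}. Round-trips through the module
    readers losslessly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_fasta": str(out / "genome.fa"),
        "ip_bedgraph": str(out / "ip.bedgraph"),
        "control_bedgraph": str(out / "control.bedgraph"),
        "gff3": str(out / "genes.gff3"),
        "truth_tsv": str(out / "truth.tsv"),
    }
    sio.write_fasta({ip.chrom: genome}, paths["genome_fasta"])
    sio.write_bedgraph(ip.chrom, ip.values, paths["ip_bedgraph"])
    sio.write_bedgraph(control.chrom, control.values, paths["control_bedgraph"])
    sio.write_gff3_cds(truth.gene_records, paths["gff3"])
    sio.write_truth_tsv(truth.sites, paths["truth_tsv"])
    return paths


def simulate_regulon(
    config: SyntheticRegulonConfig,
) -> tuple[str, GroundTruth, CoverageTrack, CoverageTrack]:
    """Convenience wrapper: genome -> plant sites -> coverage tracks."""
    genome = simulate_genome(config.genome_length, config.gc_fraction, config.seed)
    genome, truth = sample_sites_and_plant(config, genome)
    ip, control = simulate_chip_coverage(config, truth)
    return genome, truth, ip, control
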