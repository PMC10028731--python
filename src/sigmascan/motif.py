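"""Position-probability motif models: construction from aligned site windows,
per-position information content (R_seq), low-information masking, ZOOPS-EM
de novo discovery, and minimal MEME motif format I/O.

A motif column is a probability vector over (A, C, G, T). Information content
per column is R_seq = 2 - H(column) bits against a uniform background; columns
with R_seq at or below a threshold (default 1 bit) can be masked, i.e.
replaced by the background composition of the sequence that will be scanned,
so that under-sampled positions contribute nothing to match scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import ALPHABET, encode_sequence

UNIFORM = np.full(4, 0.25)


@dataclass(frozen=True)
class MotifModel:
    """A probability-matrix motif.

    probabilities: (width, 4) array, rows summing to 1.
    counts: optional (width, 4) letter counts the probabilities came from.
    background: letter frequencies used for information / log-odds.
    masked_positions: column indices replaced by background frequencies.
    n_sites: number of contributing sites (for MEME nsites).
    """

    probabilities: np.ndarray
    counts: np.ndarray | None = None
    pseudocount: float = 0.0
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    masked_positions: frozenset[int] = frozenset()
    n_sites: int = 0

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError("probabilities must be a (width, 4) matrix")
        if np.any(p < 0):
            raise ValueError("negative probability")
        # tolerance accommodates matrices read back from 6-decimal MEME text
        if not np.allclose(p.sum(axis=1), 1.0, atol=2e-6):
            raise ValueError("probability columns must sum to 1")
        if any(i < 0 or i >= p.shape[0] for i in self.masked_positions):
            raise ValueError("masked position outside motif")

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probabilities.argmax(axis=1))

    def reverse_complement(self) -> "MotifModel":
        rc = self.probabilities[::-1, ::-1].copy()
        w = self.width
        return replace(
            self,
            probabilities=rc,
            counts=None if self.counts is None else self.counts[::-1, ::-1].copy(),
            masked_positions=frozenset(w - 1 - i for i in self.masked_positions),
        )


# ---------------------------------------------------------------------------
# matrix construction

def build_count_matrix(sites: list[str]) -> np.ndarray:
    """Per-position letter counts of equal-length ACGT site sequences."""
    if not sites:
        raise ValueError("no sites")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("sites must all have the same length")
    enc = np.stack([encode_sequence(s) for s in sites])
    if np.any(enc > 3):
        raise ValueError("sites must contain only A, C, G, T")
    counts = np.zeros((w, 4), dtype=np.int64)
    for s in range(4):
        counts[:, s] = (enc == s).sum(axis=0)
    return counts


def counts_to_probabilities(counts: np.ndarray, pseudocount: float = 0.0) -> MotifModel:
    """p[i,s] = (counts[i,s] + pseudocount) / (n + 4*pseudocount)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = np.asarray(counts, dtype=np.float64)
    totals = counts.sum(axis=1)
    denom = totals + 4.0 * pseudocount
    if np.any(denom == 0):
        raise ValueError("zero column total with zero pseudocount")
    p = (counts + pseudocount) / denom[:, None]
    return MotifModel(
        probabilities=p,
        counts=counts,
        pseudocount=pseudocount,
        n_sites=int(round(totals.max())) if totals.size else 0,
    )


def background_composition(sequence: str) -> np.ndarray:
    """Mononucleotide frequencies of a sequence; non-ACGT letters are skipped
    with a warning."""
    enc = encode_sequence(sequence)
    n_bad = int((enc > 3).sum())
    if n_bad:
        warnings.warn(f"skipping {n_bad} non-ACGT letters in background computation")
    good = enc[enc <= 3]
    if good.size == 0:
        raise ValueError("empty or all-ambiguous sequence")
    return np.bincount(good, minlength=4) / good.size


# ---------------------------------------------------------------------------
# information content and masking

def information_content(model: MotifModel, small_sample_correction: bool = False) -> np.ndarray:
    """Per-position R_seq in bits: 2 + sum_s p log2 p, with 0*log2(0) = 0.

    ``small_sample_correction`` subtracts the first-order small-sample bias
    term 3 / (2 ln 2 n) when the number of contributing sites n is known.
    """
    p = model.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    r = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        if model.n_sites <= 0:
            raise ValueError("small-sample correction requires n_sites > 0")
        r = r - 3.0 / (2.0 * np.log(2.0) * model.n_sites)
    return r


def mask_motif(
    model: MotifModel, background: np.ndarray, r_threshold: float = 1.0
) -> MotifModel:
    """Replace probability columns with R_seq <= r_threshold by the query
    background frequencies; other columns are untouched."""
    background = np.asarray(background, dtype=np.float64)
    if background.shape != (4,) or not np.isclose(background.sum(), 1.0, atol=1e-9):
        raise ValueError("background must be 4 frequencies summing to 1")
    r = information_content(model)
    masked = np.flatnonzero(r <= r_threshold)
    p = model.probabilities.copy()
    p[masked] = background
    return replace(
        model,
        probabilities=p,
        counts=None,
        masked_positions=frozenset(int(i) for i in masked),
    )


# ---------------------------------------------------------------------------
# ZOOPS-EM motif discovery (MEME-style)

@dataclass
class ZoopsResult:
    """Converged ZOOPS-EM fit.

    model: the discovered motif; gamma: fitted probability a sequence carries
    a site; site_posteriors: per sequence, posterior over (no site, each
    candidate placement); site_calls: per sequence (offset, strand, posterior
    site probability) for the best placement; objective_trace: MAP objective
    per iteration of the winning start (non-decreasing).
    """

    model: MotifModel
    gamma: float
    site_posteriors: list[np.ndarray]
    site_calls: list[tuple[int, str, float]]
    objective_trace: np.ndarray
    log_likelihood: float
    converged: bool


def _window_matrix(enc: np.ndarray, width: int) -> np.ndarray:
    if enc.size < width:
        raise ValueError("sequence shorter than motif width")
    return sliding_window_view(enc, width)


def _zoops_estep(
    windows_list, logratio, gamma, n_strands
):
    """Per-sequence responsibilities and total log-likelihood increment over
    the background-only model (the constant background term cancels)."""
    w = logratio.shape[0]
    idx = np.arange(w)
    rc = logratio[::-1, ::-1]
    z_list, rel_ll = [], 0.0
    for win in windows_list:
        m = win.shape[0]
        s_fwd = logratio[idx, win].sum(axis=1)
        scores = s_fwd
        if n_strands == 2:
            s_rev = rc[idx, win].sum(axis=1)
            scores = np.concatenate([s_fwd, s_rev])
        a = np.concatenate(
            ([np.log1p(-gamma)], np.log(gamma / (n_strands * m)) + scores)
        )
        mx = a.max()
        lse = mx + np.log(np.exp(a - mx).sum())
        z_list.append(np.exp(a - lse))
        rel_ll += lse
    return z_list, rel_ll


def discover_motif_zoops(
    sequences: list[str],
    width: int,
    n_starts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = 0,
    both_strands: bool = False,
    prior_strength: float = 0.5,
    max_seed_words: int = 1000,
) -> ZoopsResult:
    """Fit a zero-or-one-occurrence-per-sequence (ZOOPS) motif model by EM.

    Initialization follows the MEME heuristic: every distinct width-w word in
    the data is turned into a seed matrix (0.7 on its letters, 0.1 elsewhere),
    seeds are ranked by their one-shot ZOOPS log-likelihood at gamma=0.5, and
    EM is run from the ``n_starts`` best. Columns carry a Dirichlet prior of
    strength ``prior_strength`` times the background, so the maximized
    objective is the MAP objective, which is non-decreasing per iteration
    (asserted).
    """
    if width < 4:
        raise ValueError("motif width must be >= 4")
    if not sequences:
        raise ValueError("no sequences")
    enc_list = [encode_sequence(s) for s in sequences]
    if any(e.size < width for e in enc_list):
        raise ValueError("motif width exceeds the shortest sequence")
    if any((e > 3).any() for e in enc_list):
        raise ValueError("sequences must contain only A, C, G, T")
    windows_list = [_window_matrix(e, width) for e in enc_list]
    n_seq = len(enc_list)
    n_strands = 2 if both_strands else 1
    rng = np.random.default_rng(seed)

    # 0-order background from the aggregate composition of the input
    allbases = np.concatenate(enc_list)
    bg = np.bincount(allbases, minlength=4) / allbases.size
    bg = np.clip(bg, 1e-6, None)
    bg = bg / bg.sum()
    logbg = np.log(bg)

    # --- seed ranking
    seen: dict[tuple, None] = {}
    for win in windows_list:
        for row in win:
            seen.setdefault(tuple(int(v) for v in row), None)
    seeds = sorted(seen)  # deterministic order
    if len(seeds) > max_seed_words:
        pick = rng.choice(len(seeds), size=max_seed_words, replace=False)
        seeds = [seeds[i] for i in sorted(pick)]

    def seed_ppm(word):
        p = np.full((width, 4), 0.1)
        p[np.arange(width), list(word)] = 0.7
        return p

    scored = []
    for word in seeds:
        lr = np.log(seed_ppm(word)) - logbg[None, :]
        _, ll = _zoops_estep(windows_list, lr, 0.5, n_strands)
        scored.append((ll, word))
    scored.sort(key=lambda t: (-t[0], t[1]))
    starts = [seed_ppm(word) for _, word in scored[: max(1, n_starts)]]

    pseudo = prior_strength * bg  # Dirichlet kernel exponents

    best = None
    for p0 in starts:
        p = p0.copy()
        gamma = 0.5
        trace = []
        prev = -np.inf
        converged = False
        for _ in range(max_iter):
            logratio = np.log(p) - logbg[None, :]
            z_list, rel_ll = _zoops_estep(windows_list, logratio, gamma, n_strands)
            obj = rel_ll + float((pseudo[None, :] * np.log(p)).sum())
            # MAP-EM objective must not decrease
            assert obj >= prev - 1e-6 * (1.0 + abs(prev)), (
                f"EM objective decreased: {prev} -> {obj}"
            )
            trace.append(obj)
            if obj - prev < tol * (1.0 + abs(obj)):
                prev = obj
                converged = True
                break
            prev = obj
            # M-step
            counts = np.zeros((width, 4))
            gsum = 0.0
            for win, z in zip(windows_list, z_list):
                m = win.shape[0]
                z_fwd = z[1 : 1 + m]
                gsum += z[1:].sum()
                for s in range(4):
                    counts[:, s] += ((win == s) * z_fwd[:, None]).sum(axis=0)
                if n_strands == 2:
                    z_rev = z[1 + m :]
                    raw = np.zeros((width, 4))
                    for s in range(4):
                        raw[:, s] = ((win == s) * z_rev[:, None]).sum(axis=0)
                    counts += raw[::-1, ::-1]
            counts += pseudo[None, :]
            p = counts / counts.sum(axis=1, keepdims=True)
            gamma = float(np.clip(gsum / n_seq, 1e-4, 1.0 - 1e-4))
        if not converged:
            warnings.warn("ZOOPS-EM did not converge; returning best-so-far")
        if best is None or prev > best[0]:
            best = (prev, p, gamma, np.array(trace), converged)

    obj, p, gamma, trace, converged = best
    logratio = np.log(p) - logbg[None, :]
    z_list, rel_ll = _zoops_estep(windows_list, logratio, gamma, n_strands)

    calls = []
    for win, z in zip(windows_list, z_list):
        m = win.shape[0]
        site_prob = float(z[1:].sum())
        j = int(np.argmax(z[1:]))
        strand = "+" if j < m else "-"
        calls.append((j % m, strand, site_prob))

    model = MotifModel(
        probabilities=p,
        background=bg,
        n_sites=int(round(gamma * n_seq)),
    )
    return ZoopsResult(
        model=model,
        gamma=gamma,
        site_posteriors=z_list,
        site_calls=calls,
        objective_trace=trace,
        log_likelihood=rel_ll,
        converged=converged,
    )


def background_only_log_likelihood_ratio(sequences: list[str]) -> float:
    """Reference point for likelihood-ratio checks: the ZOOPS relative
    log-likelihood of the no-motif model is exactly 0 by construction."""
    return 0.0


# ---------------------------------------------------------------------------
# minimal MEME motif format

def write_meme_motif(model: MotifModel, name: str = "MOTIF1") -> str:
    bg = model.background
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{c} {bg[i]:.6f}" for i, c in enumerate(ALPHABET)),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {model.width} nsites= {max(model.n_sites, 1)}",
    ]
    for row in model.probabilities:
        lines.append(" " + " ".join(f"{v:.6f}" for v in row))
    lines.append("")
    return "\n".join(lines)


def read_meme_motif(text: str) -> MotifModel:
    """Parse the first motif of a minimal MEME motif file."""
    lines = [ln.rstrip() for ln in text.splitlines()]
    bg = UNIFORM.copy()
    i = 0
    width = None
    nsites = 1
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            if len(toks) >= 8:
                freq = {toks[j]: float(toks[j + 1]) for j in range(0, 8, 2)}
                bg = np.array([freq.get(c, 0.25) for c in ALPHABET])
            i += 2
            continue
        if ln.startswith("letter-probability matrix"):
            toks = ln.replace(":", " ").split()
            kv = {toks[j]: toks[j + 1] for j in range(len(toks) - 1) if toks[j] in ("alength=", "w=", "nsites=")}
            # tokens look like "alength= 4"; re-scan pairwise
            kv = {}
            for j, t in enumerate(toks):
                if t.endswith("=") and j + 1 < len(toks):
                    kv[t[:-1]] = toks[j + 1]
            if int(kv.get("alength", 4)) != 4:
                raise ValueError("only alength=4 (DNA) is supported")
            width = int(kv["w"])
            nsites = int(float(kv.get("nsites", 1)))
            rows = []
            for j in range(i + 1, i + 1 + width):
                if j >= len(lines):
                    raise ValueError("matrix shorter than declared width")
                vals = [float(v) for v in lines[j].split()]
                if len(vals) != 4:
                    raise ValueError("matrix row must have 4 probabilities")
                rows.append(vals)
            p = np.array(rows)
            sums = p.sum(axis=1, keepdims=True)
            # renormalize only rows that are off by more than 6-decimal
            # rounding, so clean round trips stay bit-faithful
            bad = np.abs(sums - 1.0) > 2e-6
            p = np.where(bad, p / sums, p)
            return MotifModel(probabilities=p, background=bg, n_sites=nsites)
        i += 1
    raise ValueError("no letter-probability matrix found")
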