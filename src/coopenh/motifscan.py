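"""Two-step upstream-TF inference for regulatory element sets.

Step 1 — regulon over-representation: for each transcription factor with a
known target set (regulon), a hypergeometric tail test asks whether the
element-associated genes are enriched for that regulon; q < 0.1 after
Benjamini-Hochberg selects candidates.

Step 2 — motif validation: each candidate's position weight matrix is
scanned over the regulatory-element sequence and over length- and
chromosome-matched background regions drawn by constrained shuffling.
Window p-values come from the exact score distribution of the PWM under an
i.i.d. background (dynamic programming over integerised per-position
log-odds, FIMO-style), hits are filtered at q < 0.1 per PWM, and per-TF
enrichment is a Pearson chi-squared test on the 2x2 bound/unbound x
RE/background table.  TFs are ranked by *binding difference* — the
percentage of REs bound minus the percentage of background regions bound —
and selected when q < 0.1 with a positive difference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from coopenh.intervals import GenomicInterval

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# PWM construction and I/O


@dataclass(frozen=True)
class PWM:
    """Position weight model: probabilities and log2-odds vs background."""

    name: str
    probs: np.ndarray  # (width, 4), rows sum to 1
    log_odds: np.ndarray  # (width, 4), log2(probs / background)
    background: np.ndarray  # (4,)

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def __post_init__(self) -> None:
        if self.probs.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM probabilities must sum to 1 at each position")


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    tf: str
    score: float
    p_value: float
    q_value: float


def pwm_from_counts(
    name: str,
    counts: np.ndarray,
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
) -> PWM:
    """Build a PWM from a (width, 4) count matrix.

    probs = (count + pseudocount) / (column_total + 4 * pseudocount);
    log-odds are log2(probs / background), flat background by default.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must have shape (width, 4)")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every position needs at least one positive count")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 frequencies summing to 1")
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)[:, None]
    log_odds = np.log2(probs / bg)
    return PWM(name=name, probs=probs, log_odds=log_odds, background=bg)


def with_background(pwm: PWM, background: Sequence[float]) -> PWM:
    """Re-derive log-odds of an existing PWM against new base frequencies."""
    bg = np.asarray(background, float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 frequencies summing to 1")
    return PWM(name=pwm.name, probs=pwm.probs,
               log_odds=np.log2(pwm.probs / bg), background=bg)


def read_jaspar(path: str | Path, pseudocount: float = 0.5,
                background: Sequence[float] | None = None) -> list[PWM]:
    """Read JASPAR-style 4-row count matrices (``A [ 1 2 ... ]`` rows)."""
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}
    for line in Path(path).read_text().splitlines() + [">"]:
        line = line.strip()
        if line.startswith(">"):
            if name is not None and rows:
                counts = np.array([rows[b] for b in BASES]).T
                pwms.append(pwm_from_counts(name, counts, pseudocount, background))
            name = line[1:].strip().split()[-1] if len(line) > 1 else None
            rows = {}
        elif line:
            m = re.match(r"([ACGT])\s*\[?\s*([\d.\s]+)\]?", line)
            if not m:
                raise ValueError(f"{path}: unparseable matrix line {line!r}")
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    return pwms


def write_jaspar(pwm_counts: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write integer count matrices in JASPAR text format."""
    with open(path, "w") as fh:
        for i, (name, counts) in enumerate(pwm_counts.items(), 1):
            fh.write(f">SYN{i:04d} {name}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(str(int(v)) for v in np.asarray(counts)[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Exact score distribution (dynamic programming)


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of window log-odds scores under an i.i.d. background.

    Scores are integerised at ``granularity`` bits; ``pmf[k]`` is the
    probability of integer score ``min_score + k`` and ``sf[k]`` the tail
    P(score >= min_score + k).  The same integerised matrix is used when
    scanning, so scan p-values are achievable tail values of this
    distribution with no interpolation.
    """

    int_log_odds: np.ndarray  # (width, 4) integers
    granularity: float
    min_score: int
    pmf: np.ndarray
    sf: np.ndarray

    def p_value(self, int_scores: np.ndarray) -> np.ndarray:
        idx = np.clip(np.asarray(int_scores) - self.min_score, 0, self.sf.size - 1)
        return self.sf[idx]


def score_distribution(pwm: PWM, granularity: float = 1e-4) -> ScoreDistribution:
    """DP over integerised per-position scores; total mass 1 within 1e-9.

    With the default granularity, rounding error is below 1e-3 per position
    (at most granularity/2 each), preserving the ordering of window scores
    for any realistic matrix.
    """
    int_lo = np.rint(pwm.log_odds / granularity).astype(np.int64)
    bg = pwm.background
    # Convolve position by position over the integer score lattice.
    cur = np.zeros(1)
    cur[0] = 1.0
    cur_min = 0
    for j in range(pwm.width):
        lo = int_lo[j]
        new_min = cur_min + int(lo.min())
        new_size = cur.size + int(lo.max() - lo.min())
        new = np.zeros(new_size)
        for b in range(4):
            shift = int(lo[b] - lo.min())
            new[shift : shift + cur.size] += cur * bg[b]
        cur = new
        cur_min = new_min
    pmf = cur
    total = pmf.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"score distribution mass {total} != 1")
    sf = pmf[::-1].cumsum()[::-1]
    return ScoreDistribution(
        int_log_odds=int_lo,
        granularity=granularity,
        min_score=cur_min,
        pmf=pmf,
        sf=np.minimum(sf, 1.0),
    )


# ---------------------------------------------------------------------------
# Scanning


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4 (treated as N)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[arr]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _window_int_scores(
    encoded: np.ndarray, dist: ScoreDistribution
) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of all windows plus a validity mask (no N)."""
    w = dist.int_log_odds.shape[0]
    n_win = encoded.size - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    scores = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    # Row 4 (N) scores zero; such windows are masked out via `valid` anyway.
    padded = np.vstack(
        [dist.int_log_odds.T, np.zeros((1, w), dtype=np.int64)]
    ).astype(np.int64)
    for j in range(w):
        col = encoded[j : j + n_win]
        scores += padded[col, j]
        valid &= col < 4
    return scores, valid


def scan(
    sequences: Mapping[str, str],
    pwm: PWM,
    q_threshold: float = 0.1,
    granularity: float = 1e-4,
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan named sequences with one PWM on both strands.

    Windows containing N are skipped.  Each window's p-value is the exact
    tail probability of its score; Benjamini-Hochberg is applied across all
    scanned windows of this PWM (both strands, all sequences) and hits with
    q < ``q_threshold`` are returned.  Minus-strand hits are reported in
    plus-strand coordinates of the scanned sequence.
    """
    if dist is None:
        dist = score_distribution(pwm, granularity)
    w = pwm.width
    names: list[str] = []
    starts: list[np.ndarray] = []
    strands: list[str] = []
    scores: list[np.ndarray] = []
    for name, seq in sequences.items():
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            enc = encode_sequence(s)
            sc, valid = _window_int_scores(enc, dist)
            idx = np.flatnonzero(valid)
            if idx.size == 0:
                continue
            if strand == "+":
                st = idx
            else:
                st = len(seq) - w - idx  # mirror back to + coordinates
            names.extend([name] * idx.size)
            starts.append(st)
            strands.extend([strand] * idx.size)
            scores.append(sc[idx])
    if not scores:
        return []
    start_arr = np.concatenate(starts)
    score_arr = np.concatenate(scores)
    p = dist.p_value(score_arr)
    q = benjamini_hochberg(p)
    keep = np.flatnonzero(q < q_threshold)
    hits = [
        MotifHit(
            interval=GenomicInterval(names[i], int(start_arr[i]), int(start_arr[i]) + w),
            strand=strands[i],
            tf=pwm.name,
            score=float(score_arr[i] * dist.granularity),
            p_value=float(p[i]),
            q_value=float(q[i]),
        )
        for i in keep
    ]
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
    return hits


def genome_background(sequences: Mapping[str, str]) -> np.ndarray:
    """Zero-order base frequencies estimated from supplied sequence."""
    counts = np.zeros(4)
    for seq in sequences.values():
        enc = encode_sequence(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases to estimate background from")
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Shuffled background


def shuffle_background(
    regions: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    seed: int,
    excluded: Sequence[GenomicInterval] | None = None,
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """Length- and chromosome-matched random regions avoiding exclusions.

    One background region per input region, placed uniformly among valid
    start positions on the same chromosome; backgrounds overlap neither each
    other, the input regions (excluded by default), nor any extra
    ``excluded`` interval.  Rejection sampling; after ``max_tries`` failures
    a ``RuntimeError`` names the chromosome.
    """
    rng = np.random.default_rng(seed)
    forbidden: dict[str, list[tuple[int, int]]] = {}
    base_excl = list(regions) + list(excluded or ())
    for iv in base_excl:
        forbidden.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in regions:
        L = chrom_sizes[iv.chrom]
        length = len(iv)
        if length > L:
            raise RuntimeError(f"region longer than chromosome {iv.chrom}")
        placed = None
        blocks = forbidden.setdefault(iv.chrom, [])
        for _ in range(max_tries):
            start = int(rng.integers(0, L - length + 1))
            end = start + length
            if not any(bs < end and start < be for bs, be in blocks):
                placed = GenomicInterval(iv.chrom, start, end)
                break
        if placed is None:
            raise RuntimeError(
                f"could not place a {length} bp background region on {iv.chrom} "
                f"after {max_tries} tries"
            )
        blocks.append((placed.start, placed.end))
        out.append(placed)
    return out


# ---------------------------------------------------------------------------
# Enrichment statistics


@dataclass(frozen=True)
class TFEnrichmentRecord:
    tf: str
    pct_re_bound: float
    pct_bg_bound: float
    binding_difference: float
    chi2_stat: float
    p_value: float
    q_value: float
    selected: bool


def _pearson_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on [[a,b],[c,d]]."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(sps.chi2.sf(stat, 1))


def tf_enrichment(
    re_bound: Mapping[str, Sequence[bool]],
    bg_bound: Mapping[str, Sequence[bool]],
    q_threshold: float = 0.1,
) -> list[TFEnrichmentRecord]:
    """Chi-squared binding-difference ranking of TFs.

    ``re_bound[tf]`` / ``bg_bound[tf]`` flag, per region of each arm, whether
    the region carries >= 1 significant hit of that TF.  Selected TFs have
    BH q < ``q_threshold`` *and* a positive binding difference (enriched in
    the analysed REs, not the background); output is ranked by descending
    binding difference.
    """
    tfs = sorted(re_bound)
    if set(tfs) != set(bg_bound):
        raise ValueError("re_bound and bg_bound must cover the same TFs")
    rows = []
    for tf in tfs:
        re_flags = np.asarray(re_bound[tf], dtype=bool)
        bg_flags = np.asarray(bg_bound[tf], dtype=bool)
        if re_flags.size == 0 or bg_flags.size == 0:
            raise ValueError("both arms need at least one region")
        a, b = int(re_flags.sum()), int((~re_flags).sum())
        c, d = int(bg_flags.sum()), int((~bg_flags).sum())
        chi2, p = _pearson_chi2(a, b, c, d)
        pct_re = 100.0 * a / re_flags.size
        pct_bg = 100.0 * c / bg_flags.size
        rows.append((tf, pct_re, pct_bg, pct_re - pct_bg, chi2, p))
    q = benjamini_hochberg([r[5] for r in rows])
    records = [
        TFEnrichmentRecord(
            tf=r[0],
            pct_re_bound=r[1],
            pct_bg_bound=r[2],
            binding_difference=r[3],
            chi2_stat=r[4],
            p_value=r[5],
            q_value=float(qi),
            selected=bool(qi < q_threshold and r[3] > 0),
        )
        for r, qi in zip(rows, q)
    ]
    records.sort(key=lambda r: (-r.binding_difference, r.tf))
    return records


def enrichment_table(records: Sequence[TFEnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tf": [r.tf for r in records],
            "pct_re_bound": [r.pct_re_bound for r in records],
            "pct_bg_bound": [r.pct_bg_bound for r in records],
            "binding_difference": [r.binding_difference for r in records],
            "chi2": [r.chi2_stat for r in records],
            "p_value": [r.p_value for r in records],
            "q_value": [r.q_value for r in records],
            "selected": [r.selected for r in records],
        }
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment: q_i = min_{j>=rank(i)} m * p_(j) / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def regulon_overrepresentation(
    target_genes: set[str],
    regulon_library: Mapping[str, set[str]],
    universe: set[str],
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each TF's regulon in a gene list.

    For a universe of N genes, a regulon of K genes, n target genes and an
    overlap of k, the p-value is P(X >= k) for X ~ Hypergeom(N, K, n).
    BH across TFs; selected iff q < ``q_threshold``.
    """
    if not universe:
        raise ValueError("empty gene universe")
    targets = target_genes & universe
    n = len(targets)
    N = len(universe)
    rows = []
    for tf in sorted(regulon_library):
        regulon = regulon_library[tf] & universe
        K = len(regulon)
        k = len(regulon & targets)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"tf": tf, "overlap": k, "regulon_size": K,
                     "n_targets": n, "universe": N, "p_value": min(1.0, max(p, 1e-300))})
    df = pd.DataFrame(rows)
    df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["selected"] = df["q_value"] < q_threshold
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def read_regulons(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (tf, target) -> regulon dictionary."""
    regulons: dict[str, set[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {i}: expected 'tf<TAB>target'")
        regulons.setdefault(parts[0], set()).add(parts[1])
    return regulons


def bound_flags(
    regions: Sequence[GenomicInterval], hits: Sequence[MotifHit]
) -> list[bool]:
    """Per-region flag: does any hit fall inside the region (either strand)?

    Hit coordinates must be genomic (same space as ``regions``).
    """
    flags = []
    for r in regions:
        flags.append(
            any(
                h.interval.chrom == r.chrom
                and h.interval.start < r.end
                and r.start < h.interval.end
                for h in hits
            )
        )
    return flags
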