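"""Promoter extraction, PWM scanning, and motif-presence enrichment.

A position frequency matrix (raw base counts per motif column) is converted
to a position weight matrix of log2 likelihood ratios against a background
base composition, with pseudocounts spread by that composition.  Every
length-L window of a promoter, on both strands, is scored as the sum of PWM
entries; windows overlapping an N score as non-matching (-inf).  A promoter
"contains" a motif when at least one window reaches the score threshold
(8.0 log2 units by default), and per-motif enrichment compares the fraction
of motif-containing promoters in a target set against a background promoter
set with a one-tailed Fisher exact test, Bonferroni-corrected over the
motifs tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import bonferroni_threshold, log10_fisher_one_tailed
from .io import PFM, PromoterSet

__all__ = [
    "MotifModel",
    "PromoterWindowSpec",
    "extract_promoter",
    "build_motif_model",
    "scan",
    "motif_presence",
    "motif_enrich",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NEG_INF = -np.inf


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterWindowSpec:
    """Promoter window around the TSS, 0-based half-open, strand-aware.

    ``upstream`` bases precede the TSS and ``downstream`` bases follow it in
    transcript orientation; the default (1000, 500) yields 1500-base windows.
    """

    upstream: int = 1000
    downstream: int = 500

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window lengths must be nonnegative")
        if self.upstream + self.downstream < 4:
            raise ValueError("window must be at least as long as a motif")

    @property
    def length(self) -> int:
        return self.upstream + self.downstream


@dataclass
class MotifModel:
    """PWM of log2(p_motif / p_background) with its score threshold."""

    name: str
    pwm: np.ndarray  # 4 x L
    probabilities: np.ndarray  # 4 x L, pseudocounted
    background: np.ndarray  # length-4, sums to 1
    threshold: float = 8.0

    @property
    def length(self) -> int:
        return int(self.pwm.shape[1])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.pwm, axis=0))

    def max_score(self) -> float:
        return float(self.pwm.max(axis=0).sum())


def extract_promoter(
    genome_seq: str,
    tss: int,
    strand: str,
    window: PromoterWindowSpec = PromoterWindowSpec(),
) -> str:
    """Extract the promoter window around a TSS from a contig sequence.

    Plus strand returns ``[tss - upstream, tss + downstream)``; minus strand
    returns the reverse complement of ``[tss - downstream, tss + upstream)``.
    Windows running off the contig are clipped with a logged warning.
    """
    n = len(genome_seq)
    if not 0 <= tss < n:
        raise ValueError(f"TSS {tss} outside sequence of length {n}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "+":
        lo, hi = tss - window.upstream, tss + window.downstream
    else:
        lo, hi = tss - window.downstream, tss + window.upstream
    clipped_lo, clipped_hi = max(lo, 0), min(hi, n)
    if (clipped_lo, clipped_hi) != (lo, hi):
        logger.warning(
            "promoter window [%d, %d) clipped to [%d, %d) at contig ends",
            lo, hi, clipped_lo, clipped_hi,
        )
    seq = genome_seq[clipped_lo:clipped_hi].upper()
    return seq if strand == "+" else reverse_complement(seq)


def build_motif_model(
    pfm: PFM,
    background: np.ndarray | None = None,
    pseudocount: float = 4.0,
    threshold: float = 8.0,
) -> MotifModel:
    """Build a log2-ratio PWM from raw counts.

    ``pseudocount`` is the total added per column, spread across bases by
    the background composition (the default of 4 adds one count per base
    under a uniform background).
    """
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies")
    bg = bg / bg.sum()
    counts = pfm.counts
    col_tot = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (col_tot + pseudocount)
    pwm = np.log2(probs / bg[:, None])
    return MotifModel(
        name=pfm.name, pwm=pwm, probabilities=probs, background=bg, threshold=threshold
    )


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGTN base {exc.args[0]!r} in sequence") from exc


def _window_scores(enc: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Scores of all plus-strand windows of one encoded sequence.

    The PWM is extended with a fifth, -inf row so any window containing an
    N scores -inf.  Accumulates position by position to keep memory flat.
    """
    L = pwm.shape[1]
    n_win = enc.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    lut = np.vstack([pwm, np.full((1, L), _NEG_INF)])  # 5 x L
    scores = np.zeros(n_win)
    with np.errstate(invalid="ignore"):
        for pos in range(L):
            scores += lut[enc[pos : pos + n_win], pos]
    return scores


def scan(model: MotifModel, sequence: str, gene_id: str = "") -> pd.DataFrame:
    """Score every window on both strands; return hits at/above threshold.

    Offsets index the window start on the *given* (plus) sequence whatever
    the hit strand, so ``sequence[offset : offset + L]`` is always the
    plus-strand context of the hit.
    """
    seq = sequence.upper()
    L = model.length
    cols = ["gene_id", "motif", "offset", "strand", "score"]
    if len(seq) < L:
        return pd.DataFrame(columns=cols)
    enc = _encode(seq)
    rows = []
    plus = _window_scores(enc, model.pwm)
    for off in np.nonzero(plus >= model.threshold)[0]:
        rows.append((gene_id, model.name, int(off), "+", float(plus[off])))
    rc = _encode(reverse_complement(seq))
    minus = _window_scores(rc, model.pwm)
    n_win = len(minus)
    for off in np.nonzero(minus >= model.threshold)[0]:
        # window at rc offset o starts at len - L - o on the plus sequence
        rows.append((gene_id, model.name, int(n_win - 1 - off), "-", float(minus[off])))
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["offset", "strand"], kind="stable"
    ).reset_index(drop=True)


def _presence_matrix(promoters: PromoterSet, models: list[MotifModel]) -> pd.DataFrame:
    """Boolean gene x motif presence table, scanning both strands."""
    gene_ids = list(promoters.sequences)
    lengths = {len(s) for s in promoters.sequences.values()}
    out = pd.DataFrame(False, index=gene_ids, columns=[m.name for m in models])
    if len(lengths) == 1 and gene_ids:
        # uniform-length fast path: batch all promoters into one matrix
        enc = np.vstack([_encode(promoters.sequences[g]) for g in gene_ids])
        rc = np.vstack(
            [_encode(reverse_complement(promoters.sequences[g])) for g in gene_ids]
        )
        for model in models:
            L = model.length
            n_win = enc.shape[1] - L + 1
            if n_win <= 0:
                continue
            lut = np.vstack([model.pwm, np.full((1, L), _NEG_INF)])
            best = np.full(len(gene_ids), _NEG_INF)
            for strand_enc in (enc, rc):
                scores = np.zeros((len(gene_ids), n_win))
                with np.errstate(invalid="ignore"):
                    for pos in range(L):
                        scores += lut[strand_enc[:, pos : pos + n_win], pos]
                best = np.maximum(best, scores.max(axis=1))
            out[model.name] = best >= model.threshold
        return out
    for gid in gene_ids:
        for model in models:
            out.loc[gid, model.name] = not scan(model, promoters.sequences[gid], gid).empty
    return out


def motif_presence(promoters: PromoterSet, model: MotifModel) -> pd.Series:
    """Per-gene flag: does the promoter contain at least one site."""
    return _presence_matrix(promoters, [model])[model.name]


def motif_enrich(
    target: PromoterSet,
    background: PromoterSet,
    models: list[MotifModel],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-motif Fisher enrichment of presence in target vs background.

    When the target promoters are a subset of the background set (the usual
    "all promoters on the array" background), the target is tested against
    background-minus-target so the 2x2 cells stay disjoint.  The Bonferroni
    threshold is alpha / number of motifs tested.
    """
    if len(target) == 0 or len(background) == 0:
        raise ValueError("target and background promoter sets must be non-empty")
    if not models:
        raise ValueError("no motif models supplied")
    bg_ids = [g for g in background.sequences if g not in target.sequences]
    if not bg_ids:
        raise ValueError("background contains no promoters outside the target")
    bg_only = background.subset(bg_ids)
    presence_t = _presence_matrix(target, models)
    presence_b = _presence_matrix(bg_only, models)
    m = len(models)
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    for model in models:
        a = int(presence_t[model.name].sum())
        b = len(target) - a
        c = int(presence_b[model.name].sum())
        d = len(bg_only) - c
        log10p = log10_fisher_one_tailed(a, b, c, d)
        rows.append(
            {
                "motif": model.name,
                "consensus": model.consensus(),
                "target_with": a,
                "target_without": b,
                "background_with": c,
                "background_without": d,
                "target_fraction": a / len(target),
                "background_fraction": c / len(bg_only),
                "p": float(10.0**log10p),
                "log10_p": log10p,
                "threshold": threshold,
                "significant": 10.0**log10p < threshold,
            }
        )
    return pd.DataFrame(rows).sort_values("log10_p", kind="stable").reset_index(drop=True)
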