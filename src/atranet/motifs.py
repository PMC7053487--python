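"""PWM log-odds scanning of a promoter window and binding-site clusters.

A position frequency matrix is turned into a log-odds score with a
pseudocount spread by the background:

    score(seq) = sum_i  ln( (c[b_i, i] + pc * bg[b_i]) / (tot_i + pc) )
                       - ln( bg[b_i] )

The relative score rescales into [0, 1] between the per-matrix minimum
and maximum achievable over all words (computed column-wise).  Both
strands are scanned; the minus strand scores the reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import BASES, GenomicInterval, PWM

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BG = {b: 0.25 for b in BASES}


@dataclass(frozen=True)
class MotifHit:
    matrix_id: str
    start: int          # 0-based offset of the matched word in the window
    strand: str
    score: float        # log-odds, nats
    rel_score: float
    length: int = 0

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class MotifCluster:
    hits: list[MotifHit]
    span: GenomicInterval

    def __len__(self) -> int:
        return len(self.hits)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def log_odds_matrix(
    pwm: PWM,
    background: Mapping[str, float] | None = None,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """4 x L per-column log-odds (nats)."""
    bg = UNIFORM_BG if background is None else dict(background)
    bg_vec = np.array([bg[b] for b in BASES])[:, None]
    totals = pwm.counts.sum(axis=0, keepdims=True)
    return np.log((pwm.counts + pseudocount * bg_vec) / (totals + pseudocount)) - np.log(
        bg_vec
    )


def score_pwm_window(
    pwm: PWM,
    seq: str,
    background: Mapping[str, float] | None = None,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Score one L-mer against a PWM; returns (score, rel_score).

    Any base outside A/C/G/T scores -inf and suppresses the hit.
    """
    seq = seq.upper()
    if len(seq) != pwm.length:
        raise ValueError(
            f"sequence length {len(seq)} != matrix length {pwm.length}"
        )
    lo = log_odds_matrix(pwm, background, pseudocount)
    base_index = {b: i for i, b in enumerate(BASES)}
    score = 0.0
    for pos, base in enumerate(seq):
        if base not in base_index:
            return float("-inf"), 0.0
        score += lo[base_index[base], pos]
    lo_min = lo.min(axis=0).sum()
    lo_max = lo.max(axis=0).sum()
    rel = (score - lo_min) / (lo_max - lo_min) if lo_max > lo_min else 1.0
    return float(score), float(rel)


def scan_sequence(
    pwms: Sequence[PWM],
    window: str,
    rel_min: float = 0.8,
    background: Mapping[str, float] | None = None,
    pseudocount: float = 1.0,
) -> list[MotifHit]:
    """Scan both strands of a window; keep hits with rel_score >= rel_min.

    A minus-strand hit at ``start`` means the reverse complement of
    ``window[start:start+L]`` matches the matrix.  Hits are sorted by
    start, then strand, then matrix id.
    """
    window = window.upper()
    hits: list[MotifHit] = []
    for pwm in pwms:
        L = pwm.length
        if len(window) < L:
            raise ValueError("window shorter than matrix length")
        for start in range(len(window) - L + 1):
            word = window[start : start + L]
            for strand, oriented in (("+", word), ("-", reverse_complement(word))):
                score, rel = score_pwm_window(pwm, oriented, background, pseudocount)
                if np.isfinite(score) and rel >= rel_min:
                    hits.append(
                        MotifHit(
                            matrix_id=pwm.matrix_id,
                            start=start,
                            strand=strand,
                            score=score,
                            rel_score=rel,
                            length=L,
                        )
                    )
    return sorted(hits, key=lambda h: (h.start, h.strand, h.matrix_id))


def call_clusters(
    hits: Sequence[MotifHit],
    merge_gap: int = 50,
    chrom: str = "window",
) -> list[MotifCluster]:
    """Single-linkage merge of hits whose start-to-start gap <= merge_gap."""
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: h.start)
    clusters: list[list[MotifHit]] = [[hits[0]]]
    for hit in hits[1:]:
        if hit.start - clusters[-1][-1].start <= merge_gap:
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    return [
        MotifCluster(
            hits=members,
            span=GenomicInterval(
                chrom=chrom,
                start=members[0].start,
                end=max(h.end for h in members) or members[-1].start + 1,
                name=f"cluster_{i + 1}",
            ),
        )
        for i, members in enumerate(clusters)
    ]
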