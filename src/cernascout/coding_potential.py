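"""ORF statistics and the Fickett TESTCODE coding-potential score.

Used to triage candidate lncRNAs: a genuine lncRNA should harbor only
short ORFs and a TESTCODE score in the noncoding band.  Only the
composition/position statistic and ORF enumeration are implemented —
no trained classifier.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import yaml

from .io import check_unambiguous, normalize_rna

__all__ = ["Orf", "OrfReport", "find_orfs", "fickett_score", "orf_report"]

_STOPS = {"UAA", "UAG", "UGA"}


@dataclass(frozen=True)
class Orf:
    """One open reading frame: AUG .. in-frame stop (stop included)."""

    frame: int          # 0, 1, 2
    start: int          # 0-based
    end: int            # half-open; end - start is a multiple of 3
    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OrfReport:
    transcript_id: str
    orfs: list[Orf]
    longest_orf_len: int
    fickett: float
    call: str  # coding-like / noncoding-like / borderline


def find_orfs(seq: str, min_orf_len: int = 75) -> list[Orf]:
    """All forward-strand ORFs in all three frames, longest first.

    An ORF runs from an AUG to the first in-frame stop codon
    (inclusive); overlapping ORFs are all reported.  ORFs shorter than
    ``min_orf_len`` nucleotides are dropped.
    """
    seq = normalize_rna(seq)
    check_unambiguous(seq, "sequence")
    orfs: list[Orf] = []
    for frame in range(3):
        # positions of stops per frame, scanned once
        open_starts: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "AUG":
                open_starts.append(pos)
            elif codon in _STOPS:
                for start in open_starts:
                    if pos + 3 - start >= min_orf_len:
                        orfs.append(Orf(frame=frame, start=start, end=pos + 3))
                open_starts = []
    orfs.sort(key=lambda o: (-o.length, o.start, o.frame))
    return orfs


@functools.lru_cache(maxsize=1)
def _load_tables() -> dict:
    text = resources.files("cernascout.data").joinpath("fickett_tables.yaml").read_text()
    return yaml.safe_load(text)


def _lookup(value: float, para: list[float], probs: list[float]) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Position parameters capture the codon-position asymmetry of each
    base (max over the three frames divided by min + 1); content
    parameters are plain base fractions.  Both are mapped through the
    published lookup tables and combined with the published weights.
    U and T are equivalent.  Sequences shorter than ~200 nt give noisy
    scores but are accepted.
    """
    seq = normalize_rna(seq)
    if len(seq) == 0:
        raise ValueError("empty sequence")
    check_unambiguous(seq, "sequence")
    tables = _load_tables()
    score = 0.0
    for base in "ACGU":
        counts = [seq[frame::3].count(base) for frame in range(3)]
        position_value = max(counts) / (min(counts) + 1.0)
        content_value = sum(counts) / len(seq)
        score += (
            _lookup(position_value, tables["position_para"], tables["position_prob"][base])
            * tables["position_weight"][base]
        )
        score += (
            _lookup(content_value, tables["content_para"], tables["content_prob"][base])
            * tables["content_weight"][base]
        )
    return score


def orf_report(
    transcript_id: str,
    seq: str,
    min_orf_len: int = 75,
    noncoding_below: float | None = None,
    coding_above: float | None = None,
) -> OrfReport:
    """Combine ORF enumeration and TESTCODE score into one triage call."""
    tables = _load_tables()
    lo = tables["noncoding_below"] if noncoding_below is None else noncoding_below
    hi = tables["coding_above"] if coding_above is None else coding_above
    orfs = find_orfs(seq, min_orf_len=min_orf_len)
    score = fickett_score(seq)
    if score < lo:
        call = "noncoding-like"
    elif score > hi:
        call = "coding-like"
    else:
        call = "borderline"
    return OrfReport(
        transcript_id=transcript_id,
        orfs=orfs,
        longest_orf_len=max((o.length for o in orfs), default=0),
        fickett=score,
        call=call,
    )
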