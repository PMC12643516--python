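"""miRNA seed-site scanning and RNA:RNA duplex free-energy scoring.

Seed sites follow the canonical site classes: with the miRNA written
5'->3' and positions numbered from 1, the seed is nucleotides 2-7.

* 6mer      — target matches the reverse complement of positions 2-7;
* 7mer-A1   — 6mer plus an adenosine opposite position 1;
* 7mer-m8   — reverse complement of positions 2-8;
* 8mer      — 7mer-m8 plus the A1 anchor.

Seed matching is strictly Watson-Crick (no G:U), and each target window
is reported once under its most specific class.

Duplex energies come from a dynamic program over intermolecular
hybridization only — neither strand may pair with itself, mirroring
the model of hybridization tools used for sponge-site evaluation.
Admissible pairs are Watson-Crick and G:U; consecutive pairs score the
nearest-neighbor stacking energy, and interruptions are charged affine
bulge / internal-loop penalties.  The duplex must start and end with a
pair.  Parameters ship in ``data/nn_params.yaml``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import yaml

from .io import check_unambiguous, normalize_rna

__all__ = [
    "SeedSite",
    "DuplexResult",
    "reverse_complement",
    "scan_seed_sites",
    "duplex_mfe",
    "load_nn_params",
    "SITE_CLASS_RANK",
]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

# canonical Watson-Crick plus wobble, as (target base, mirna base)
_ALLOWED_PAIRS = {
    ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"),
}

SITE_CLASS_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}

MAX_WINDOW = 60


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement on the RNA alphabet."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SeedSite:
    """One seed-match site on a transcript (0-based half-open interval)."""

    transcript_id: str
    start: int
    end: int
    site_class: str
    mirna_id: str

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class DuplexResult:
    """Minimum-free-energy intermolecular duplex for one target window.

    ``mfe`` is in kcal/mol; 0.0 means no stabilizing duplex exists.
    ``pairing`` is a dot-bracket string ``target&mirna`` with ``(`` /
    ``)`` at paired positions; empty when ``mfe == 0``.
    """

    mfe: float
    pairing: str
    target_window: tuple[int, int]


def scan_seed_sites(
    transcript: str,
    mirna: str,
    transcript_id: str = "transcript",
    mirna_id: str = "mirna",
) -> list[SeedSite]:
    """Find all canonical seed-match sites of ``mirna`` on ``transcript``.

    Both sequences are normalized to the RNA alphabet first; ambiguous
    bases raise a format error.  Sites are returned sorted by start
    coordinate, each target window once under its best class.
    """
    transcript = normalize_rna(transcript)
    mirna = normalize_rna(mirna)
    check_unambiguous(transcript, transcript_id)
    check_unambiguous(mirna, mirna_id)
    if len(mirna) < 8:
        raise ValueError(f"{mirna_id}: miRNA must be at least 8 nt, got {len(mirna)}")

    core6 = reverse_complement(mirna[1:7])   # pairs miRNA positions 2-7
    m8_base = _COMPLEMENT[mirna[7]]          # target base pairing position 8
    sites: list[SeedSite] = []
    pos = transcript.find(core6)
    while pos != -1:
        has_m8 = pos >= 1 and transcript[pos - 1] == m8_base
        has_a1 = pos + 6 < len(transcript) and transcript[pos + 6] == "A"
        if has_m8 and has_a1:
            start, end, cls = pos - 1, pos + 7, "8mer"
        elif has_m8:
            start, end, cls = pos - 1, pos + 6, "7mer-m8"
        elif has_a1:
            start, end, cls = pos, pos + 7, "7mer-A1"
        else:
            start, end, cls = pos, pos + 6, "6mer"
        sites.append(SeedSite(transcript_id, start, end, cls, mirna_id))
        pos = transcript.find(core6, pos + 1)
    return sites


@functools.lru_cache(maxsize=1)
def load_nn_params(version: int = 1) -> dict:
    """Load the versioned nearest-neighbor parameter table."""
    text = resources.files("cernascout.data").joinpath("nn_params.yaml").read_text()
    params = yaml.safe_load(text)
    if params.get("version") != version:
        raise ValueError(
            f"nn_params version mismatch: wanted {version}, found {params.get('version')}"
        )
    return params


def _stack_energy(params: dict, prev_pair: tuple[str, str], cur_pair: tuple[str, str]) -> float | None:
    """Energy of stacking ``cur_pair`` 3' of ``prev_pair`` (target strand).

    Helix fragment 5'-a b-3' / 3'-c d-5' with prev = (a, c), cur = (b, d)
    is looked up as stack["ac"]["db"] per the table's convention.
    """
    table = params["stack"]
    row = table.get(prev_pair[0] + prev_pair[1])
    if row is None:
        return None
    return row.get(cur_pair[1] + cur_pair[0])


def loop_energy(params: dict, a_unpaired: int, b_unpaired: int) -> float:
    """Affine penalty for a bulge or internal loop between two pairs."""
    loops = params["loops"]
    total = a_unpaired + b_unpaired
    if total == 0:
        raise ValueError("loop must contain at least one unpaired base")
    if a_unpaired == 0 or b_unpaired == 0:
        return loops["bulge_open"] + loops["bulge_ext"] * (total - 1)
    return loops["internal_open"] + loops["internal_ext"] * (total - 2)


def duplex_mfe(
    target_window: str,
    mirna: str,
    params: dict | None = None,
    window_interval: tuple[int, int] | None = None,
) -> DuplexResult:
    """Minimum free energy of the intermolecular target:miRNA duplex.

    The DP state is the last (3'-most on the target) pair (i, j); pairs
    advance i upward and j downward (antiparallel strands).  Gap states
    track an open bulge on either strand or an internal loop, giving
    exactly the affine loop costs of :func:`loop_energy`.  The returned
    structure is loop-free at both ends (terminal pairs).
    """
    if params is None:
        params = load_nn_params()
    s = normalize_rna(target_window)
    t = normalize_rna(mirna)
    check_unambiguous(s, "target window")
    check_unambiguous(t, "miRNA")
    if len(s) > MAX_WINDOW:
        raise ValueError(
            f"target window of {len(s)} nt exceeds limit {MAX_WINDOW}; tile windows instead"
        )
    interval = window_interval or (0, len(s))
    n, m = len(s), len(t)
    INF = float("inf")
    loops = params["loops"]

    # state tables: P = last cell is a pair; BT/BM = open bulge on
    # target / mirna strand; IL = open internal loop
    P = [[INF] * m for _ in range(n)]
    BT = [[INF] * m for _ in range(n)]
    BM = [[INF] * m for _ in range(n)]
    IL = [[INF] * m for _ in range(n)]
    # parent pointers for traceback: (state, i, j) or None for duplex start
    parent: dict[tuple[str, int, int], tuple[str, int, int] | None] = {}

    for i in range(n):
        for j in range(m - 1, -1, -1):
            # bulge on target: unpaired s[i], last pair at (k, j), k < i
            best, arg = INF, None
            if i >= 1:
                if P[i - 1][j] + loops["bulge_open"] < best:
                    best, arg = P[i - 1][j] + loops["bulge_open"], ("P", i - 1, j)
                if BT[i - 1][j] + loops["bulge_ext"] < best:
                    best, arg = BT[i - 1][j] + loops["bulge_ext"], ("BT", i - 1, j)
            BT[i][j], parent[("BT", i, j)] = best, arg

            # bulge on miRNA: unpaired t[j], last pair at (i, l), l > j
            best, arg = INF, None
            if j + 1 < m:
                if P[i][j + 1] + loops["bulge_open"] < best:
                    best, arg = P[i][j + 1] + loops["bulge_open"], ("P", i, j + 1)
                if BM[i][j + 1] + loops["bulge_ext"] < best:
                    best, arg = BM[i][j + 1] + loops["bulge_ext"], ("BM", i, j + 1)
            BM[i][j], parent[("BM", i, j)] = best, arg

            # internal loop: >=1 unpaired on both strands
            best, arg = INF, None
            if i >= 1 and j + 1 < m:
                if P[i - 1][j + 1] + loops["internal_open"] < best:
                    best, arg = P[i - 1][j + 1] + loops["internal_open"], ("P", i - 1, j + 1)
                if IL[i - 1][j] + loops["internal_ext"] < best:
                    best, arg = IL[i - 1][j] + loops["internal_ext"], ("IL", i - 1, j)
                if IL[i][j + 1] + loops["internal_ext"] < best:
                    best, arg = IL[i][j + 1] + loops["internal_ext"], ("IL", i, j + 1)
            IL[i][j], parent[("IL", i, j)] = best, arg

            # pair (i, j)
            if (s[i], t[j]) not in _ALLOWED_PAIRS:
                continue
            best, arg = 0.0, None  # opening pair of the duplex
            if i >= 1 and j + 1 < m:
                stack = _stack_energy(params, (s[i - 1], t[j + 1]), (s[i], t[j]))
                if stack is not None and P[i - 1][j + 1] + stack < best:
                    best, arg = P[i - 1][j + 1] + stack, ("P", i - 1, j + 1)
                if BT[i - 1][j + 1] < best:
                    best, arg = BT[i - 1][j + 1], ("BT", i - 1, j + 1)
                if BM[i - 1][j + 1] < best:
                    best, arg = BM[i - 1][j + 1], ("BM", i - 1, j + 1)
                if IL[i - 1][j + 1] < best:
                    best, arg = IL[i - 1][j + 1], ("IL", i - 1, j + 1)
            P[i][j], parent[("P", i, j)] = best, arg

    init = params.get("init", 0.0)
    mfe, end = 0.0, None
    for i in range(n):
        for j in range(m):
            if P[i][j] + init < mfe - 1e-12:
                mfe, end = P[i][j] + init, (i, j)
    if end is None:
        return DuplexResult(mfe=0.0, pairing="", target_window=interval)

    pairs: list[tuple[int, int]] = []
    node: tuple[str, int, int] | None = ("P", end[0], end[1])
    while node is not None:
        state, i, j = node
        if state == "P":
            pairs.append((i, j))
        node = parent[node]
    target_struct = ["."] * n
    mirna_struct = ["."] * m
    for i, j in pairs:
        target_struct[i] = "("
        mirna_struct[j] = ")"
    pairing = "".join(target_struct) + "&" + "".join(mirna_struct)
    return DuplexResult(mfe=round(mfe, 6), pairing=pairing, target_window=interval)


def best_site_mfe(
    transcript: str,
    site: SeedSite,
    mirna: str,
    params: dict | None = None,
    flank: int = 15,
) -> DuplexResult:
    """Score the duplex on the seed site extended by ``flank`` nt each side."""
    lo = max(0, site.start - flank)
    hi = min(len(transcript), site.end + flank)
    return duplex_mfe(transcript[lo:hi], mirna, params=params, window_interval=(lo, hi))
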