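"""Error-tolerant semi-global adapter matching.

Finds the best alignment of an adapter inside a read under unit-cost edit
distance (substitutions, insertions, deletions all cost 1), with the read's
ends free in the mode-appropriate way:

* ``BACK`` (3' adapter, cutadapt ``-a`` style): the full adapter anywhere in
  the read, or an adapter *prefix* whose alignment reaches the read's 3' end
  (adapter read-through off the end of the read).
* ``FRONT`` (5' adapter/primer, ``-g`` style): the full adapter anywhere, or
  an adapter *suffix* whose alignment starts at the read's 5' end.
* ``ANYWHERE`` (``-b`` style, Ion Torrent): the union of both candidate sets.

A candidate alignment is admissible iff
``errors <= floor(error_rate * adapter_bases_aligned)`` and
``adapter_bases_aligned >= min_overlap``.  Among admissible candidates the
best is chosen by: fewest errors, then most adapter bases aligned, then
smallest ``read_start``, then smallest ``read_end`` — a total order, so the
result is deterministic.  ``N`` never matches anything (always a mismatch).

The implementation is a row-vectorized dynamic program over batches of
equal-length reads; per-cell it carries the lexicographically minimal
``(cost, start)`` pair encoded in a single integer, so exact start
coordinates (with the tie-break above) come out of the DP directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    from .fastq_io import ReadRecord

__all__ = [
    "AdapterMode",
    "AdapterSpec",
    "AdapterMatch",
    "find_adapter",
    "insert_length",
    "match_batch",
    "ADAPTER_PRESETS",
]

_BIG = np.int64(2**62)
_N_CODE = 4

_CODE = np.full(256, _N_CODE, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


class AdapterMode(str, Enum):
    BACK = "back"
    FRONT = "front"
    ANYWHERE = "anywhere"


@dataclass(frozen=True)
class AdapterSpec:
    """An adapter sequence plus the matching dialect applied to it.

    ``error_rate`` is the per-aligned-base error budget: an alignment of
    ``k`` adapter bases may carry at most ``floor(error_rate * k)`` edits.
    ``min_overlap`` is the minimum number of adapter bases that must take
    part in the alignment (3, the conventional trimming default).
    """

    name: str
    sequence: str
    mode: AdapterMode = AdapterMode.BACK
    error_rate: float = 0.1
    min_overlap: int = 3

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValueError(f"adapter {self.name!r}: sequence shorter than 8 nt")
        if set(seq) - set("ACGTN"):
            raise ValueError(f"adapter {self.name!r}: non-ACGTN characters")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        object.__setattr__(self, "mode", AdapterMode(self.mode))


@dataclass(frozen=True)
class AdapterMatch:
    """Best admissible adapter alignment; 0-based, half-open coordinates."""

    read_start: int
    read_end: int
    adapter_bases_aligned: int
    errors: int
    matched: bool

    @staticmethod
    def no_match() -> "AdapterMatch":
        return AdapterMatch(0, 0, 0, 0, False)


#: Adapter presets for the two small-RNA sequencing chemistries handled here.
ADAPTER_PRESETS: dict[str, dict[str, AdapterSpec]] = {
    "illumina-truseq-smallrna": {
        "adapter3": AdapterSpec(
            "truseq-smallrna-3p",
            "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC",
            AdapterMode.BACK,
            0.1,
        ),
        "adapter5": AdapterSpec(
            "truseq-smallrna-5p-primer",
            "CGACAGGTTCAGAGTTCTACAGTCCGACGATC",
            AdapterMode.FRONT,
            0.1,
        ),
    },
    "iontorrent-smallrna": {
        "adapter3": AdapterSpec(
            "iontorrent-smallrna-3p",
            "ATCACCGACTGCCCATAGAGAGGAAAGCGG",
            AdapterMode.ANYWHERE,
            0.2,
        ),
    },
}


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A,C,G,T -> 0..3; anything else -> N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _semiglobal_dp(
    codes: np.ndarray, acodes: np.ndarray, carry_max_start: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Semi-global DP of adapter vs. a batch of equal-length reads.

    ``D[i][j]`` = min edit cost of aligning ``adapter[:i]`` against
    ``read[s:j]`` with the start ``s`` free; each cell carries the start of
    the optimal path (min start on cost ties, or max start when
    ``carry_max_start``, which the caller uses for reversed-read runs).

    Returns ``(cost, start)`` for the final adapter row (all ``j``) and for
    the final read column (all ``i``), as ``(B, n+1)`` / ``(B, m+1)`` arrays.
    """
    B, n = codes.shape
    m = len(acodes)
    C = np.int64(n + 1)
    j_idx = np.arange(n + 1, dtype=np.int64)
    t0 = (n - j_idx) if carry_max_start else j_idx
    prev = np.broadcast_to(t0, (B, n + 1)).copy()  # row 0: cost 0, start j
    col_cost = np.empty((B, m + 1), dtype=np.int64)
    col_t = np.empty((B, m + 1), dtype=np.int64)
    col_cost[:, 0] = 0
    col_t[:, 0] = t0[n]
    Cj = C * j_idx
    codes16 = codes.astype(np.int64)
    for i in range(m):
        a = int(acodes[i])
        sub = (codes16 != a) | (codes16 == _N_CODE)
        if a == _N_CODE:
            sub = np.ones_like(sub)
        # vertical/diagonal candidates, then horizontal closure via a
        # running minimum of (combined - C*j)
        H = np.empty((B, n + 1), dtype=np.int64)
        H[:, 0] = prev[:, 0] + C
        np.minimum(prev[:, :-1] + C * sub, prev[:, 1:] + C, out=H[:, 1:])
        H -= Cj
        np.minimum.accumulate(H, axis=1, out=H)
        H += Cj
        prev = H
        col_cost[:, i + 1] = prev[:, n] // C
        col_t[:, i + 1] = prev[:, n] % C
    lr_cost = prev // C
    lr_t = prev % C
    if carry_max_start:
        lr_start = n - lr_t
        col_start = n - col_t
    else:
        lr_start = lr_t
        col_start = col_t
    return lr_cost, lr_start, col_cost, col_start


def _budgets(m: int, error_rate: float) -> np.ndarray:
    # floor with a tiny epsilon so e.g. 0.1*30 == 3.0 is not floored to 2
    return np.floor(error_rate * np.arange(m + 1) + 1e-9).astype(np.int64)


def match_batch(codes: np.ndarray, spec: AdapterSpec) -> dict[str, np.ndarray]:
    """Vectorized :func:`find_adapter` over a batch of equal-length reads.

    ``codes`` is a ``(B, n)`` uint8 matrix from :func:`encode_bases`.
    Returns arrays ``matched, errors, aligned, read_start, read_end``.
    """
    if codes.ndim != 2 or codes.shape[1] == 0:
        raise ValueError("codes must be a (B, n) matrix with n >= 1")
    B, n = codes.shape
    acodes = encode_bases(spec.sequence)
    m = len(acodes)
    budgets = _budgets(m, spec.error_rate)
    lo = min(spec.min_overlap, m)
    j_idx = np.arange(n + 1, dtype=np.int64)
    i_idx = np.arange(lo, m, dtype=np.int64)

    err_parts: list[np.ndarray] = []
    ali_parts: list[np.ndarray] = []
    sta_parts: list[np.ndarray] = []
    end_parts: list[np.ndarray] = []
    adm_parts: list[np.ndarray] = []

    def add(err, ali, sta, end, adm):
        err_parts.append(err)
        ali_parts.append(np.broadcast_to(ali, err.shape))
        sta_parts.append(np.broadcast_to(sta, err.shape))
        end_parts.append(np.broadcast_to(end, err.shape))
        adm_parts.append(np.broadcast_to(adm, err.shape))

    if spec.mode in (AdapterMode.BACK, AdapterMode.ANYWHERE):
        lr_cost, lr_start, col_cost, col_start = _semiglobal_dp(codes, acodes, False)
        # full adapter ending at any j
        add(lr_cost, np.int64(m), lr_start, j_idx, lr_cost <= budgets[m])
        # adapter prefix of length i reaching the read's 3' end
        if len(i_idx):
            add(
                col_cost[:, lo:m],
                i_idx,
                col_start[:, lo:m],
                np.int64(n),
                col_cost[:, lo:m] <= budgets[lo:m],
            )
    if spec.mode in (AdapterMode.FRONT, AdapterMode.ANYWHERE):
        lr_cost, lr_start, col_cost, col_start = _semiglobal_dp(
            codes[:, ::-1], acodes[::-1], True
        )
        # reversed coordinates: orig_start = n - j', orig_end = n - s'
        add(lr_cost, np.int64(m), n - j_idx, n - lr_start, lr_cost <= budgets[m])
        # adapter suffix of length i starting at the read's 5' end
        if len(i_idx):
            add(
                col_cost[:, lo:m],
                i_idx,
                np.int64(0),
                n - col_start[:, lo:m],
                col_cost[:, lo:m] <= budgets[lo:m],
            )

    errors = np.concatenate(err_parts, axis=1)
    aligned = np.concatenate(ali_parts, axis=1)
    start = np.concatenate(sta_parts, axis=1)
    end = np.concatenate(end_parts, axis=1)
    admissible = np.concatenate(adm_parts, axis=1)

    key = ((errors * (m + 1) + (m - aligned)) * (n + 1) + start) * np.int64(
        n + 2
    ) + end
    key = np.where(admissible, key, _BIG)
    best = np.argmin(key, axis=1)
    rows = np.arange(B)
    matched = key[rows, best] < _BIG
    return {
        "matched": matched,
        "errors": np.where(matched, errors[rows, best], 0),
        "aligned": np.where(matched, aligned[rows, best], 0),
        "read_start": np.where(matched, start[rows, best], 0),
        "read_end": np.where(matched, end[rows, best], 0),
    }


def find_adapter(read: "ReadRecord | str", spec: AdapterSpec) -> AdapterMatch:
    """Best admissible semi-global alignment of ``spec`` inside ``read``.

    Total on non-empty reads; returns ``AdapterMatch.no_match()`` when no
    candidate satisfies the error budget and minimum overlap.
    """
    bases = read if isinstance(read, str) else read.bases
    if not bases:
        raise ValueError("read must be non-empty")
    res = match_batch(encode_bases(bases)[None, :], spec)
    if not res["matched"][0]:
        return AdapterMatch.no_match()
    return AdapterMatch(
        int(res["read_start"][0]),
        int(res["read_end"][0]),
        int(res["aligned"][0]),
        int(res["errors"][0]),
        True,
    )


def insert_length(
    read: "ReadRecord | str", match: AdapterMatch, mode: AdapterMode
) -> int:
    """Length of the biological insert implied by an adapter match.

    For a 3'-portion hit the insert precedes the adapter
    (``read_start`` bases); for a 5'-portion hit it follows
    (``len(read) - read_end`` bases).  The adapter sits in the 5' portion
    when ``read_start < len(read) - read_end``.
    """
    if not match.matched:
        raise ValueError("insert_length requires a matched AdapterMatch")
    n = len(read if isinstance(read, str) else read.bases)
    mode = AdapterMode(mode)
    if mode == AdapterMode.BACK:
        return match.read_start
    if mode == AdapterMode.FRONT:
        return n - match.read_end
    if match.read_start < n - match.read_end:  # 5' portion
        return n - match.read_end
    return match.read_start
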