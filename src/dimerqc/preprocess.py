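"""Per-read trimming and classification; per-sample QC aggregation.

Every raw read ends up in exactly one of four classes:

* ``DIMER`` — the 3' adapter is found with at most ``dimer_max_insert``
  bases of insert in front of it: the read is an adapter-dimer artefact
  (zero-length biological insert, possibly with a base or two of junk at
  the ligation junction).
* ``SHORT`` — after adapter removal (and quality trimming) the insert is
  below the minimum informative length, and the shortfall is attributable
  to the insert itself (an adapter was found, or the read was already
  sub-minimum before quality trimming).
* ``LOW_QUALITY`` — the read only fell below the minimum length because
  quality trimming removed a low-quality 3' tail.
* ``CLEAN`` — everything else; the trimmed read is the usable insert.

``pct_read_loss = 100 * (n_raw - n_clean) / n_raw`` and the four counts
partition ``n_raw`` exactly.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Iterator

import numpy as np

from .adapters import (
    ADAPTER_PRESETS,
    AdapterMatch,
    AdapterMode,
    AdapterSpec,
    encode_bases,
    find_adapter,
    insert_length,
    match_batch,
)
from .fastq_io import ReadRecord

__all__ = [
    "PlatformProfile",
    "ReadClass",
    "SampleQC",
    "PROFILE_PRESETS",
    "get_preset",
    "quality_trim_end",
    "classify_read",
    "classify_reads",
    "process_sample",
    "adapter_content_curve",
    "overrepresented_sequences",
]

_CHUNK = 4096


class ReadClass(str, Enum):
    DIMER = "DIMER"
    SHORT = "SHORT"
    LOW_QUALITY = "LOW_QUALITY"
    CLEAN = "CLEAN"


@dataclass(frozen=True)
class PlatformProfile:
    """Adapter set plus trimming parameters defining a pre-processing dialect."""

    name: str
    adapter3: AdapterSpec
    adapter5: AdapterSpec | None = None
    quality_threshold: int = 20
    min_length: int = 15
    dimer_max_insert: int = 2
    fixed_read_length: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.quality_threshold <= 41:
            raise ValueError("quality_threshold must be in [0, 41]")
        if not 0 <= self.dimer_max_insert < self.min_length:
            raise ValueError("need min_length > dimer_max_insert >= 0")


PROFILE_PRESETS: dict[str, PlatformProfile] = {
    "illumina-truseq-smallrna": PlatformProfile(
        name="illumina-truseq-smallrna",
        adapter3=ADAPTER_PRESETS["illumina-truseq-smallrna"]["adapter3"],
        adapter5=ADAPTER_PRESETS["illumina-truseq-smallrna"]["adapter5"],
        quality_threshold=20,
        min_length=15,
        dimer_max_insert=2,
        fixed_read_length=75,
    ),
    "iontorrent-smallrna": PlatformProfile(
        name="iontorrent-smallrna",
        adapter3=ADAPTER_PRESETS["iontorrent-smallrna"]["adapter3"],
        adapter5=None,
        quality_threshold=20,
        min_length=15,
        dimer_max_insert=2,
        fixed_read_length=None,
    ),
}


def get_preset(name: str) -> PlatformProfile:
    try:
        return PROFILE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PROFILE_PRESETS)}"
        ) from None


@dataclass
class SampleQC:
    """Per-sample read-class counts, derived percentages and diagnostics."""

    sample_id: str
    n_raw: int = 0
    n_dimer: int = 0
    n_short: int = 0
    n_lowq: int = 0
    n_clean: int = 0
    pct_dimer: float = math.nan
    pct_short: float = math.nan
    pct_lowq: float = math.nan
    pct_clean: float = math.nan
    pct_read_loss: float = math.nan
    adapter_content_curve: list[float] = field(default_factory=list)
    overrepresented: list[tuple[str, int, float]] = field(default_factory=list)
    mean_quality_per_position: list[float] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        """True when the sample had no reads; percentage fields are NaN."""
        return self.n_raw == 0

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "n_raw": self.n_raw,
            "n_dimer": self.n_dimer,
            "n_short": self.n_short,
            "n_lowq": self.n_lowq,
            "n_clean": self.n_clean,
            "pct_dimer": self.pct_dimer,
            "pct_short": self.pct_short,
            "pct_lowq": self.pct_lowq,
            "pct_clean": self.pct_clean,
            "pct_read_loss": self.pct_read_loss,
            "adapter_content_curve": list(self.adapter_content_curve),
            "overrepresented": [list(t) for t in self.overrepresented],
            "mean_quality_per_position": list(self.mean_quality_per_position),
        }
        return d

    @staticmethod
    def from_dict(d: dict) -> "SampleQC":
        qc = SampleQC(sample_id=d["sample_id"])
        for k, v in d.items():
            if k == "overrepresented":
                v = [tuple(t) for t in v]
            setattr(qc, k, v)
        return qc


def quality_trim_end(read: ReadRecord, threshold: int) -> ReadRecord:
    """Trim the 3' tail by the partial-sum rule (BWA/cutadapt ``-q``).

    Cuts at the position minimizing the running sum of ``qual - threshold``
    accumulated from the 3' end; ties keep the most bases.  May return an
    empty read.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    cut = _trim_points(
        np.array([read.quals], dtype=np.int64), threshold
    )[0]
    if cut == len(read):
        return read
    return ReadRecord(read.read_id, read.bases[:cut], read.quals[:cut])


def _trim_points(quals: np.ndarray, threshold: int) -> np.ndarray:
    """Vectorized partial-sum 3' cut points for a (B, n) quality matrix."""
    B, n = quals.shape
    P = np.zeros((B, n + 1), dtype=np.int64)
    P[:, :n] = np.cumsum((quals - threshold)[:, ::-1], axis=1)[:, ::-1]
    # argmin on the reversed array -> largest index on ties (trim least)
    return n - np.argmin(P[:, ::-1], axis=1)


def _trim_after_match(
    bases: str, quals: tuple[int, ...], match: AdapterMatch, mode: AdapterMode
) -> tuple[str, tuple[int, ...]]:
    """Remove the adapter and everything beyond it on its far side."""
    if not match.matched:
        return bases, quals
    n = len(bases)
    if mode == AdapterMode.FRONT or (
        mode == AdapterMode.ANYWHERE and match.read_start < n - match.read_end
    ):
        return bases[match.read_end :], quals[match.read_end :]
    return bases[: match.read_start], quals[: match.read_start]


def classify_read(
    read: ReadRecord, profile: PlatformProfile
) -> tuple[ReadClass, ReadRecord]:
    """Classify one read and return its trimmed form.

    Pipeline: (1) locate the 3' adapter; an insert of at most
    ``dimer_max_insert`` nt means DIMER.  (2) remove the adapter (and the
    5' adapter/primer where configured).  (3) quality-trim the 3' tail.
    (4) apply the minimum-length filter, attributing sub-minimum reads to
    SHORT or LOW_QUALITY.  (5) otherwise CLEAN.
    """
    m3 = find_adapter(read, profile.adapter3)
    if m3.matched:
        ins = insert_length(read, m3, profile.adapter3.mode)
        if ins <= profile.dimer_max_insert:
            b, q = _trim_after_match(
                read.bases, read.quals, m3, profile.adapter3.mode
            )
            return ReadClass.DIMER, ReadRecord(read.read_id, b, q)
    bases, quals = _trim_after_match(
        read.bases, read.quals, m3, profile.adapter3.mode
    )
    if profile.adapter5 is not None and bases:
        m5 = find_adapter(bases, profile.adapter5)
        if m5.matched:
            bases, quals = _trim_after_match(
                bases, quals, m5, profile.adapter5.mode
            )
    pre_q_len = len(bases)
    trimmed = quality_trim_end(
        ReadRecord(read.read_id, bases, quals), profile.quality_threshold
    ) if bases else ReadRecord(read.read_id, "", ())
    if len(trimmed) < profile.min_length:
        if m3.matched or pre_q_len < profile.min_length:
            return ReadClass.SHORT, trimmed
        return ReadClass.LOW_QUALITY, trimmed
    return ReadClass.CLEAN, trimmed


def _classify_chunk(
    chunk: list[ReadRecord], profile: PlatformProfile
) -> tuple[list[ReadClass], list[ReadRecord], list[int]]:
    """Batched classify_read over a chunk; also returns 3'-match starts (-1
    when the 3' adapter was not found), for the adapter-content curve."""
    n_reads = len(chunk)
    classes: list[ReadClass | None] = [None] * n_reads
    trimmed: list[ReadRecord | None] = [None] * n_reads
    starts = [-1] * n_reads
    mode3 = profile.adapter3.mode

    by_len: dict[int, list[int]] = {}
    for idx, rec in enumerate(chunk):
        by_len.setdefault(len(rec), []).append(idx)

    remaining: list[tuple[int, str, tuple[int, ...], bool]] = []
    for n, idxs in by_len.items():
        codes = np.vstack([encode_bases(chunk[i].bases) for i in idxs])
        res = match_batch(codes, profile.adapter3)
        for row, i in enumerate(idxs):
            rec = chunk[i]
            if res["matched"][row]:
                m3 = AdapterMatch(
                    int(res["read_start"][row]),
                    int(res["read_end"][row]),
                    int(res["aligned"][row]),
                    int(res["errors"][row]),
                    True,
                )
                starts[i] = m3.read_start
                ins = insert_length(rec, m3, mode3)
                b, q = _trim_after_match(rec.bases, rec.quals, m3, mode3)
                if ins <= profile.dimer_max_insert:
                    classes[i] = ReadClass.DIMER
                    trimmed[i] = ReadRecord(rec.read_id, b, q)
                else:
                    remaining.append((i, b, q, True))
            else:
                remaining.append((i, rec.bases, rec.quals, False))

    if profile.adapter5 is not None:
        by_len5: dict[int, list[int]] = {}
        for pos, (_, b, _, _) in enumerate(remaining):
            if b:
                by_len5.setdefault(len(b), []).append(pos)
        mode5 = profile.adapter5.mode
        for n, positions in by_len5.items():
            codes = np.vstack(
                [encode_bases(remaining[p][1]) for p in positions]
            )
            res = match_batch(codes, profile.adapter5)
            for row, p in enumerate(positions):
                if res["matched"][row]:
                    i, b, q, had3 = remaining[p]
                    m5 = AdapterMatch(
                        int(res["read_start"][row]),
                        int(res["read_end"][row]),
                        int(res["aligned"][row]),
                        int(res["errors"][row]),
                        True,
                    )
                    b, q = _trim_after_match(b, q, m5, mode5)
                    remaining[p] = (i, b, q, had3)

    # quality trimming, batched by remaining length
    by_len_q: dict[int, list[int]] = {}
    for pos, (_, b, _, _) in enumerate(remaining):
        by_len_q.setdefault(len(b), []).append(pos)
    for n, positions in by_len_q.items():
        if n == 0:
            cuts = [0] * len(positions)
        else:
            quals = np.array(
                [remaining[p][2] for p in positions], dtype=np.int64
            )
            cuts = _trim_points(quals, profile.quality_threshold)
        for cut, p in zip(cuts, positions):
            i, b, q, had3 = remaining[p]
            cut = int(cut)
            rec = chunk[i]
            tr = ReadRecord(rec.read_id, b[:cut], q[:cut])
            if len(tr) < profile.min_length:
                if had3 or len(b) < profile.min_length:
                    classes[i] = ReadClass.SHORT
                else:
                    classes[i] = ReadClass.LOW_QUALITY
            else:
                classes[i] = ReadClass.CLEAN
            trimmed[i] = tr

    return classes, trimmed, starts  # type: ignore[return-value]


def classify_reads(
    reads: Iterable[ReadRecord], profile: PlatformProfile
) -> list[tuple[ReadClass, ReadRecord]]:
    """Batched :func:`classify_read` over a read collection (same results,
    vectorized adapter matching)."""
    out: list[tuple[ReadClass, ReadRecord]] = []
    chunk: list[ReadRecord] = []

    def flush() -> None:
        classes, trimmed, _ = _classify_chunk(chunk, profile)
        out.extend(zip(classes, trimmed))

    for rec in reads:
        chunk.append(rec)
        if len(chunk) >= _CHUNK:
            flush()
            chunk = []
    if chunk:
        flush()
    return out


def process_sample(
    reads: Iterable[ReadRecord],
    profile: PlatformProfile,
    sample_id: str,
    clean_writer: Callable[[ReadRecord], None] | None = None,
    overrepresented_threshold_pct: float = 0.1,
) -> SampleQC:
    """Aggregate per-read classification over a stream into a SampleQC.

    Streams in fixed-size chunks; counts partition exactly
    (``n_raw == n_dimer + n_short + n_lowq + n_clean``).  ``clean_writer``,
    when given, receives each trimmed CLEAN read as it is produced.
    """
    qc = SampleQC(sample_id=sample_id)
    counts = Counter()
    seq_counter: Counter[str] = Counter()
    qual_sums = np.zeros(0, dtype=np.float64)
    qual_counts = np.zeros(0, dtype=np.int64)
    start_counter: Counter[int] = Counter()
    max_len = 0

    def flush(chunk: list[ReadRecord]) -> None:
        nonlocal qual_sums, qual_counts, max_len
        classes, trimmed, starts = _classify_chunk(chunk, profile)
        for rec, cls, tr, st in zip(chunk, classes, trimmed, starts):
            counts[cls] += 1
            seq_counter[rec.bases] += 1
            if st >= 0:
                start_counter[st] += 1
            if len(rec) > max_len:
                max_len = len(rec)
                qual_sums = np.pad(qual_sums, (0, max_len - len(qual_sums)))
                qual_counts = np.pad(
                    qual_counts, (0, max_len - len(qual_counts))
                )
            q = np.asarray(rec.quals)
            qual_sums[: len(q)] += q
            qual_counts[: len(q)] += 1
            if cls is ReadClass.CLEAN and clean_writer is not None:
                clean_writer(tr)

    chunk: list[ReadRecord] = []
    for rec in reads:
        chunk.append(rec)
        if len(chunk) >= _CHUNK:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)

    qc.n_dimer = counts[ReadClass.DIMER]
    qc.n_short = counts[ReadClass.SHORT]
    qc.n_lowq = counts[ReadClass.LOW_QUALITY]
    qc.n_clean = counts[ReadClass.CLEAN]
    qc.n_raw = qc.n_dimer + qc.n_short + qc.n_lowq + qc.n_clean
    if qc.n_raw > 0:
        qc.pct_dimer = 100.0 * qc.n_dimer / qc.n_raw
        qc.pct_short = 100.0 * qc.n_short / qc.n_raw
        qc.pct_lowq = 100.0 * qc.n_lowq / qc.n_raw
        qc.pct_clean = 100.0 * qc.n_clean / qc.n_raw
        qc.pct_read_loss = 100.0 * (qc.n_raw - qc.n_clean) / qc.n_raw
        cum = np.cumsum(
            np.bincount(
                list(start_counter.keys()) or [0],
                list(start_counter.values()) or [0],
                minlength=max_len,
            )
        )
        qc.adapter_content_curve = [
            float(v) for v in 100.0 * cum[:max_len] / qc.n_raw
        ]
        qc.overrepresented = _overrepresented_from_counter(
            seq_counter, qc.n_raw, overrepresented_threshold_pct
        )
        qc.mean_quality_per_position = [
            float(v) for v in qual_sums / np.maximum(qual_counts, 1)
        ]
    return qc


def adapter_content_curve(
    reads: Iterable[ReadRecord], adapter3: AdapterSpec
) -> list[float]:
    """Cumulative 3'-adapter content per read position.

    ``curve[p]`` is the percentage of reads whose adapter match starts at a
    position <= ``p``; non-decreasing and bounded by 100.  A value well
    above 0 already at position 0 is the adapter-dimer signature.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("adapter_content_curve requires at least one read")
    max_len = max(len(r) for r in reads)
    hits = np.zeros(max_len, dtype=np.int64)
    by_len: dict[int, list[ReadRecord]] = {}
    for r in reads:
        by_len.setdefault(len(r), []).append(r)
    for n, group in by_len.items():
        codes = np.vstack([encode_bases(r.bases) for r in group])
        res = match_batch(codes, adapter3)
        for matched, start in zip(res["matched"], res["read_start"]):
            if matched:
                hits[int(start)] += 1
    return [float(v) for v in 100.0 * np.cumsum(hits) / len(reads)]


def _overrepresented_from_counter(
    counter: Counter, total: int, threshold_pct: float
) -> list[tuple[str, int, float]]:
    out = [
        (seq, cnt, 100.0 * cnt / total)
        for seq, cnt in counter.items()
        if 100.0 * cnt / total > threshold_pct
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def overrepresented_sequences(
    reads: Iterable[ReadRecord], threshold_pct: float = 0.1
) -> list[tuple[str, int, float]]:
    """Exact-sequence counts; sequences above ``threshold_pct`` percent
    (strictly greater) of all reads, sorted by count then lexicographically."""
    counter: Counter[str] = Counter()
    total = 0
    for r in reads:
        counter[r.bases] += 1
        total += 1
    if total == 0:
        raise ValueError("overrepresented_sequences requires at least one read")
    return _overrepresented_from_counter(counter, total, threshold_pct)
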