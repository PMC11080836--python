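"""FASTQ, JSON-report and TSV input/output.

Reads are represented as :class:`ReadRecord` objects with integer Phred
scores (offset-33 on disk).  FASTQ files may be plain or gzip-compressed;
compression is detected from the gzip magic bytes, never from the file
extension.  Offset-64 encoded input decodes to scores above 60 and is
rejected rather than guessed.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

__all__ = [
    "ReadRecord",
    "FastqFormatError",
    "read_fastq",
    "write_fastq",
    "write_qc_report",
    "read_qc_report",
    "write_tsv",
    "read_tsv",
]

_PHRED_OFFSET = 33
_MAX_QUAL = 60

QC_REPORT_SCHEMA_VERSION = "1"


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ input; names the 1-based record index."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, bases over {A,C,G,T,N}, integer Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


def _open_maybe_gzip(path: str | Path) -> IO[bytes]:
    handle = open(path, "rb")
    magic = handle.read(2)
    handle.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(handle, "rb")  # type: ignore[return-value]
    return handle


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a 4-line FASTQ file (plain or gzip, Phred+33).

    Yields records in file order with O(1) memory.  Malformed records
    (truncation, length mismatch, bad quality characters) raise
    :class:`FastqFormatError` naming the 1-based record index.
    """
    with _open_maybe_gzip(path) as raw:
        text = io.TextIOWrapper(raw, encoding="ascii")
        index = 0
        while True:
            header = text.readline()
            if not header:
                return
            index += 1
            seq = text.readline()
            plus = text.readline()
            qual = text.readline()
            if not qual:
                raise FastqFormatError(f"record {index}: truncated FASTQ record")
            header = header.rstrip("\n")
            seq = seq.rstrip("\n")
            plus = plus.rstrip("\n")
            qual = qual.rstrip("\n")
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"record {index}: header does not start with '@': {header!r}"
                )
            if not plus.startswith("+"):
                raise FastqFormatError(
                    f"record {index}: separator line does not start with '+'"
                )
            if not seq:
                raise FastqFormatError(f"record {index}: empty sequence")
            if len(qual) != len(seq):
                raise FastqFormatError(
                    f"record {index}: {len(seq)} bases but {len(qual)} "
                    "quality characters"
                )
            quals = tuple(ord(c) - _PHRED_OFFSET for c in qual)
            for q in quals:
                if q < 0:
                    raise FastqFormatError(
                        f"record {index}: quality character below '!' "
                        "(not Phred+33)"
                    )
                if q > _MAX_QUAL:
                    raise FastqFormatError(
                        f"record {index}: Phred score {q} > {_MAX_QUAL}; "
                        "input looks Phred+64 encoded, which is not supported"
                    )
            yield ReadRecord(header[1:], seq, quals)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write records as 4-line Phred+33 FASTQ; gzip when path ends in .gz.

    Round-trip contract: ``list(read_fastq(p))`` after ``write_fastq(x, p)``
    equals ``list(x)``.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="ascii") as out:  # type: ignore[operator]
        for rec in records:
            qual = "".join(chr(q + _PHRED_OFFSET) for q in rec.quals)
            out.write(f"@{rec.read_id}\n{rec.bases}\n+\n{qual}\n")


def write_qc_report(path: str | Path, samples: list[dict], parameters: dict) -> None:
    """Write a versioned JSON QC report (per-sample counts/fractions + params)."""
    from . import __version__

    payload = {
        "schema_version": QC_REPORT_SCHEMA_VERSION,
        "tool": "dimerqc",
        "version": __version__,
        "parameters": parameters,
        "samples": samples,
    }
    with open(path, "w", encoding="utf-8") as out:
        json.dump(payload, out, indent=2, sort_keys=True)
        out.write("\n")


def read_qc_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    version = payload.get("schema_version")
    if version != QC_REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported QC report schema version: {version!r}")
    return payload


def write_tsv(frame, path: str | Path) -> None:
    """Write a pandas DataFrame as TSV with a header row."""
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
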