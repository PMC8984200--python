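"""FASTQ read filtering: the three whole-read removal rules.

A read is removed if, in this order, (1) it contains the adapter as an
exact substring, else (2) strictly more than 10% of its bases are N,
else (3) strictly more than 50% of its bases have Phred quality < 10
(offset 33).  Each read is counted in exactly one removal category, so
the tallies are additive.  Reads are removed whole, never trimmed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass
class QcReport:
    n_input: int = 0
    n_removed_adapter: int = 0
    n_removed_nfrac: int = 0
    n_removed_lowq: int = 0
    n_kept: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def classify_read(
    seq: str,
    qual: str,
    adapter_seq: str,
    n_frac_max: float = 0.10,
    lowq_frac_max: float = 0.50,
    q_min: int = 10,
) -> str | None:
    """Removal reason for one read, or None if it is kept.

    Boundary behaviour is strict: a read at exactly the N-fraction or
    low-quality-fraction limit is kept.
    """
    if adapter_seq in seq:
        return "adapter"
    n = len(seq)
    if seq.count("N") + seq.count("n") > n_frac_max * n:
        return "nfrac"
    n_lowq = sum(1 for q in qual if ord(q) - 33 < q_min)
    if n_lowq > lowq_frac_max * n:
        return "lowq"
    return None


def filter_records(
    records: Iterable[tuple[str, str, str]],
    adapter_seq: str,
    n_frac_max: float = 0.10,
    lowq_frac_max: float = 0.50,
    q_min: int = 10,
    report: QcReport | None = None,
) -> Iterator[tuple[str, str, str]]:
    """Yield kept ``(title, seq, qual)`` records, tallying into *report*.

    Sequence and quality strings pass through unmodified; this filter
    removes reads, it never trims them.
    """
    if not adapter_seq:
        raise ValueError("adapter_seq must be non-empty")
    if report is None:
        report = QcReport()
    for idx, (title, seq, qual) in enumerate(records):
        if len(seq) != len(qual):
            raise ValueError(
                f"malformed FASTQ record {idx} ({title!r}): sequence length "
                f"{len(seq)} != quality length {len(qual)}"
            )
        report.n_input += 1
        reason = classify_read(seq, qual, adapter_seq, n_frac_max, lowq_frac_max, q_min)
        if reason == "adapter":
            report.n_removed_adapter += 1
        elif reason == "nfrac":
            report.n_removed_nfrac += 1
        elif reason == "lowq":
            report.n_removed_lowq += 1
        else:
            report.n_kept += 1
            yield title, seq, qual


def filter_reads(
    fastq_in,
    adapter_seq: str,
    fastq_out=None,
    n_frac_max: float = 0.10,
    lowq_frac_max: float = 0.50,
    q_min: int = 10,
) -> tuple[list[tuple[str, str, str]], QcReport]:
    """Filter a FASTQ file or handle; return kept records and the tally.

    ``fastq_in`` may be a path (``.gz`` transparent) or an open text
    handle.  If ``fastq_out`` is given the kept records are also written
    there as 4-line FASTQ.
    """
    from . import io as ks_io

    report = QcReport()
    with ks_io.open_text(fastq_in) as handle:
        kept = list(
            filter_records(
                FastqGeneralIterator(handle),
                adapter_seq,
                n_frac_max,
                lowq_frac_max,
                q_min,
                report=report,
            )
        )
    if fastq_out is not None:
        ks_io.write_fastq(kept, fastq_out)
    return kept, report
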