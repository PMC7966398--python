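"""CArG-box scanning: the SRF binding consensus CC(A/T)6GG.

Serum response factor (SRF) binds a 10-bp element — two C's, six A/T's,
two G's — in the promoters of its target genes. The scanner reports every
matching 10-mer window (overlaps included) in BED-convention coordinates
(0-based, half-open). The consensus family is closed under reverse
complement, so plus- and minus-strand hits occupy identical intervals;
both are still reported when both_strands is set, with the strand-oriented
matched string. Only the strict consensus matches; N never matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from coexmod.errors import DataError

CARG_LENGTH = 10
# lookahead so overlapping windows are all reported
_CARG_RE = re.compile(r"(?=(CC[AT]{6}GG))")
_VALID = set("ACGTN")


@dataclass(frozen=True)
class CargHit:
    seq_id: str
    start: int          # 0-based
    end: int            # exclusive; end - start == 10
    strand: str         # "+" or "-"
    match: str          # strand-oriented matched 10-mer


def _validate_sequence(seq: str, seq_id: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in _VALID:
            raise DataError(
                f"sequence {seq_id!r} has non-IUPAC character {ch!r} at position {pos}"
            )
    return seq


def scan_sequence(seq: str, seq_id: str = "seq", both_strands: bool = True) -> list[CargHit]:
    """All CArG consensus occurrences in one sequence.

    Scanning is exhaustive over all L-9 windows; minus-strand matches are
    reported in plus-strand coordinates with strand '-'.
    """
    seq = _validate_sequence(str(seq), seq_id)
    L = len(seq)
    hits = [
        CargHit(seq_id, m.start(), m.start() + CARG_LENGTH, "+", m.group(1))
        for m in _CARG_RE.finditer(seq)
    ]
    if both_strands:
        rc = str(Seq(seq).reverse_complement())
        for m in _CARG_RE.finditer(rc):
            start = L - m.start() - CARG_LENGTH
            hits.append(CargHit(seq_id, start, start + CARG_LENGTH, "-", m.group(1)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_fasta(
    fasta,
    windows: dict[str, tuple[int, int]] | None = None,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan FASTA records and return a BED-style hit table.

    ``fasta`` is a path or an iterable of Biopython SeqRecords. ``windows``
    optionally restricts each record to a (start, end) interval; hits must
    lie fully inside the window. Output columns follow 6-column BED:
    seq_id, start, end, name, score, strand, sorted by seq_id then start.
    """
    if isinstance(fasta, (str, Path)):
        records = list(SeqIO.parse(str(fasta), "fasta"))
    else:
        records = list(fasta)
    rows = []
    for idx, rec in enumerate(records):
        if not rec.id or len(rec.seq) == 0:
            raise DataError(f"malformed FASTA record at index {idx}")
        lo, hi = 0, len(rec.seq)
        if windows is not None and rec.id in windows:
            lo, hi = windows[rec.id]
            if not 0 <= lo <= hi <= len(rec.seq):
                raise DataError(
                    f"window ({lo}, {hi}) out of bounds for record {rec.id!r} "
                    f"of length {len(rec.seq)}"
                )
        for h in scan_sequence(str(rec.seq), rec.id, both_strands=both_strands):
            if h.start >= lo and h.end <= hi:
                rows.append((h.seq_id, h.start, h.end, "CArG", 0, h.strand))
    df = pd.DataFrame(rows, columns=["seq_id", "start", "end", "name", "score", "strand"])
    return df.sort_values(["seq_id", "start", "strand"], kind="stable").reset_index(drop=True)


def write_bed(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False)
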