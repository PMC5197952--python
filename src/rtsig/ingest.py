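"""Turn mapped reads (SAM/BAM) or samtools pileup text into per-position tallies.

The central container is the *pileup table*: one row per reference position
(1-based, every position from 1 to the reference length), with columns

    pos, ref_base, depth, n_A, n_C, n_G, n_T, n_del, n_start, n_end

``depth`` counts reads whose alignment covers the position, deletions
included (samtools convention).  ``n_start`` counts reads whose leftmost
aligned base is the position — the "circumflexes" of the pileup text format
— and ``n_end`` reads whose rightmost aligned base is the position.  Each
primary mapped read contributes exactly one start and one end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

PILEUP_COLUMNS = [
    "pos", "ref_base", "depth",
    "n_A", "n_C", "n_G", "n_T",
    "n_del", "n_start", "n_end",
]

# CIGAR op codes (pysam numeric encoding)
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N, _CIGAR_S, _CIGAR_H, _CIGAR_P = range(7)
_CIGAR_EQ, _CIGAR_X = 7, 8
_QUERY_OPS = {_CIGAR_M, _CIGAR_I, _CIGAR_S, _CIGAR_EQ, _CIGAR_X}
_REF_OPS = {_CIGAR_M, _CIGAR_D, _CIGAR_N, _CIGAR_EQ, _CIGAR_X}


class MalformedReadError(ValueError):
    """A read whose CIGAR/sequence cannot be walked."""


@dataclass
class PileupColumn:
    """Single-position tally, mirroring one row of the pileup table."""

    reference_id: str
    pos: int  # 1-based
    ref_base: str
    depth: int
    n_A: int
    n_C: int
    n_G: int
    n_T: int
    n_del: int
    n_start: int
    n_end: int


def pileup_from_sam(
    sam_path,
    reference_id: str,
    reference_seq: str,
    min_base_quality: int = 0,
    start_mode: str = "leftmost",
) -> pd.DataFrame:
    """Build the per-position pileup table for one reference from a SAM/BAM file.

    Parameters
    ----------
    sam_path
        Path to a SAM (or BAM, where a reader is available) file with a header.
    reference_id
        Name of the reference to tally; reads mapped elsewhere are ignored.
    reference_seq
        The reference sequence (sets table length and ``ref_base``).
    min_base_quality
        Base calls below this quality are excluded from the base tallies
        (they still count toward depth).  Default 0 — no filtering.
    start_mode
        ``"leftmost"`` (default): ``n_start`` counts the leftmost aligned
        base of every read, matching the pileup circumflex.  ``"forward"``:
        only forward-strand reads contribute starts.  ``"read_end"``: the
        biological 5' end is taken from the ``$`` side instead — starts are
        counted at the rightmost aligned base — for library protocols with
        the opposite orientation.

    Returns
    -------
    pandas.DataFrame with `PILEUP_COLUMNS`, one row per position 1..len(reference_seq).
    """
    n = len(reference_seq)
    depth = np.zeros(n, dtype=np.int64)
    counts = {b: np.zeros(n, dtype=np.int64) for b in "ACGT"}
    n_del = np.zeros(n, dtype=np.int64)
    n_start = np.zeros(n, dtype=np.int64)
    n_end = np.zeros(n, dtype=np.int64)

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != reference_id:
                continue
            if read.cigartuples is None:
                raise MalformedReadError(
                    f"read {read.query_name!r} has no CIGAR but is flagged mapped"
                )
            if read.reference_end is not None and read.reference_end > n:
                logger.warning(
                    "read %r extends past the end of reference %s (%d > %d); skipped",
                    read.query_name, reference_id, read.reference_end, n,
                )
                continue
            _tally_read(read, depth, counts, n_del, n_start, n_end,
                        min_base_quality, start_mode)

    return pd.DataFrame({
        "pos": np.arange(1, n + 1),
        "ref_base": list(reference_seq.upper()),
        "depth": depth,
        "n_A": counts["A"],
        "n_C": counts["C"],
        "n_G": counts["G"],
        "n_T": counts["T"],
        "n_del": n_del,
        "n_start": n_start,
        "n_end": n_end,
    })


def _tally_read(read, depth, counts, n_del, n_start, n_end,
                min_base_quality, start_mode):
    seq = read.query_sequence
    if seq is None:
        raise MalformedReadError(f"read {read.query_name!r} has no sequence")
    quals = read.query_qualities if min_base_quality > 0 else None
    rp = read.reference_start  # 0-based
    qp = 0
    for op, length in read.cigartuples:
        if op in (_CIGAR_M, _CIGAR_EQ, _CIGAR_X):
            depth[rp:rp + length] += 1
            block = np.frombuffer(seq[qp:qp + length].encode("ascii"), dtype="S1")
            if quals is not None:
                ok = np.asarray(quals[qp:qp + length]) >= min_base_quality
            else:
                ok = None
            for base, arr in counts.items():
                hit = block == base.encode()
                if ok is not None:
                    hit &= ok
                arr[rp:rp + length] += hit
            rp += length
            qp += length
        elif op == _CIGAR_I:
            qp += length
        elif op == _CIGAR_S:
            qp += length
        elif op == _CIGAR_D:
            depth[rp:rp + length] += 1
            n_del[rp:rp + length] += 1
            rp += length
        elif op == _CIGAR_N:
            rp += length
        elif op in (_CIGAR_H, _CIGAR_P):
            pass
        else:
            raise MalformedReadError(
                f"read {read.query_name!r}: unsupported CIGAR op {op}"
            )
    left = read.reference_start       # 0-based leftmost
    right = read.reference_end - 1    # 0-based rightmost
    if start_mode == "leftmost":
        n_start[left] += 1
    elif start_mode == "forward":
        if not read.is_reverse:
            n_start[left] += 1
    elif start_mode == "read_end":
        n_start[right] += 1
    else:
        raise ValueError(f"unknown start_mode {start_mode!r}")
    n_end[right] += 1


def count_mapped_reads(sam_path, reference_id: str | None = None) -> int:
    """Number of primary mapped alignments (optionally to one reference)."""
    k = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if reference_id is not None and read.reference_name != reference_id:
                continue
            k += 1
    return k


class PileupParseError(ValueError):
    pass


def parse_pileup_line(line: str, line_number: int | None = None) -> PileupColumn:
    """Parse one line of samtools 6-column pileup text into a `PileupColumn`.

    Handles the full base-string dialect: ``.``/``,`` matches, upper/lower
    case mismatches, ``^X`` read starts (the following mapping-quality
    character is consumed and not counted), ``$`` read ends, ``+n``/``-n``
    indel blobs (skipped entirely), ``*`` deletion placeholders, and
    ``>``/``<`` reference skips (depth only).
    """
    where = f" (line {line_number})" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise PileupParseError(f"expected >= 6 tab-separated fields{where}: {line!r}")
    ref_id, pos_s, ref_base, depth_s, bases = fields[:5]
    pos, declared_depth = int(pos_s), int(depth_s)
    ref_base = ref_base.upper()

    tallies = {b: 0 for b in "ACGT"}
    n_del = n_start = n_end = n_other = 0
    parsed_depth = 0
    i = 0
    while i < len(bases):
        ch = bases[i]
        if ch == "^":
            n_start += 1
            i += 2  # skip the mapping-quality character
            continue
        if ch == "$":
            n_end += 1
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            while j < len(bases) and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"bare {ch!r} without indel length{where}")
            i = j + int(bases[i + 1:j])
            continue
        if ch in ".,":
            if ref_base in tallies:
                tallies[ref_base] += 1
            parsed_depth += 1
        elif ch.upper() in "ACGT":
            tallies[ch.upper()] += 1
            parsed_depth += 1
        elif ch == "*":
            n_del += 1
            parsed_depth += 1
        elif ch.upper() == "N":
            n_other += 1
            parsed_depth += 1
        elif ch in "><":
            n_other += 1
            parsed_depth += 1
        else:
            raise PileupParseError(f"unknown pileup character {ch!r}{where}")
        i += 1

    if parsed_depth != declared_depth:
        raise PileupParseError(
            f"declared depth {declared_depth} != parsed base count {parsed_depth}{where}"
        )
    return PileupColumn(
        reference_id=ref_id, pos=pos, ref_base=ref_base, depth=parsed_depth,
        n_A=tallies["A"], n_C=tallies["C"], n_G=tallies["G"], n_T=tallies["T"],
        n_del=n_del, n_start=n_start, n_end=n_end,
    )


def pileup_from_text(lines, reference_id: str, reference_seq: str) -> pd.DataFrame:
    """Assemble a full pileup table from samtools pileup text lines.

    Positions absent from the text (zero depth) are filled with empty rows.
    """
    n = len(reference_seq)
    df = pd.DataFrame({
        "pos": np.arange(1, n + 1),
        "ref_base": list(reference_seq.upper()),
        **{c: np.zeros(n, dtype=np.int64) for c in PILEUP_COLUMNS[2:]},
    })
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        col = parse_pileup_line(line, line_number=ln)
        if col.reference_id != reference_id:
            continue
        if not 1 <= col.pos <= n:
            raise PileupParseError(f"position {col.pos} outside reference (line {ln})")
        idx = col.pos - 1
        for field in PILEUP_COLUMNS[2:]:
            df.iloc[idx, df.columns.get_loc(field)] = getattr(col, field)
    return df


def columns_to_frame(columns) -> pd.DataFrame:
    """List of `PileupColumn` -> pileup table (positions must be contiguous)."""
    rows = [{f: getattr(c, f) for f in PILEUP_COLUMNS} for c in columns]
    df = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    return df
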