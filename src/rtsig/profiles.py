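"""The tabular per-position profile and its 1-kb block file layout.

A *profile* lists reference positions line-wise with columns: position,
reference base, coverage, mismatch rate M, counts of A/G/T/C calls, and
arrest rate A.  On disk it is split into block files named ``x_y.txt``
where ``x`` is the 1-based reference number (FASTA order) and ``y`` the
y-th 1-kb block: block y spans positions (y-1)*1000+1 .. min(y*1000, n).
The naming doubles as a hash — a query region maps straight to the block
files that hold it, so the tail of a long reference is readable without
scanning leading positions.

Dialect: tab-separated; one '#'-prefixed header line naming the columns;
undefined rates serialized as ``NA``.  The arrest rate of the final
position (which has no downstream neighbor) is stored as 0; see the module
documentation for the convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PROFILE_COLUMNS = [
    "pos", "ref_base", "coverage", "mismatch_rate",
    "n_A", "n_G", "n_T", "n_C", "arrest_rate",
]
_HEADER = "#" + "\t".join(PROFILE_COLUMNS)
NA_TOKEN = "NA"

DEFAULT_BLOCK_SIZE = 1000

# file-open hook, replaceable in tests to assert which blocks are touched
_open_block = open


def profile_from_columns(pileup: pd.DataFrame) -> pd.DataFrame:
    """Pileup table -> profile table (one row per position 1..n).

    Row i carries the base counts of position i; its arrest rate comes from
    position i+1 (read starts at i+1 over coverage at i+1, NA when i+1 is
    uncovered).  The final row's arrest rate is stored as 0.
    """
    pos = pileup["pos"].to_numpy()
    if len(pos) == 0:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
        raise ValueError("pileup positions must be contiguous from 1")

    depth = pileup["depth"].to_numpy(dtype=np.int64)
    starts = pileup["n_start"].to_numpy(dtype=np.int64)
    ref = pileup["ref_base"].astype(str).str.upper().to_numpy()
    counts = {b: pileup[f"n_{b}"].to_numpy(dtype=np.int64) for b in "ACGT"}

    order = np.array(list("ACGT"))
    cmat = np.stack([counts[b] for b in "ACGT"], axis=1).astype(float)
    is_ref = ref[:, None] == order[None, :]
    mm = np.where(is_ref, 0.0, cmat).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mrate = np.where((depth > 0) & np.isin(ref, order), mm / depth, np.nan)

    cov_next = np.append(depth[1:], 0)
    start_next = np.append(starts[1:], 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        arate = np.where(cov_next > 0, start_next / np.where(cov_next > 0, cov_next, 1),
                         np.nan)
    arate[-1] = 0.0  # final position: no downstream neighbor

    return pd.DataFrame({
        "pos": pos,
        "ref_base": ref,
        "coverage": depth,
        "mismatch_rate": mrate,
        "n_A": counts["A"],
        "n_G": counts["G"],
        "n_T": counts["T"],
        "n_C": counts["C"],
        "arrest_rate": arate,
    })


@dataclass(frozen=True)
class BlockAddress:
    ref_index: int   # x, 1-based
    block_index: int  # y, 1-based
    block_size: int = DEFAULT_BLOCK_SIZE

    @property
    def filename(self) -> str:
        return f"{self.ref_index}_{self.block_index}.txt"

    def span(self, reference_length: int) -> tuple[int, int]:
        start = (self.block_index - 1) * self.block_size + 1
        return start, min(self.block_index * self.block_size, reference_length)


def block_for_position(pos: int, reference_length: int, ref_index: int = 1,
                       block_size: int = DEFAULT_BLOCK_SIZE) -> tuple[BlockAddress, int]:
    """Block address and 1-based within-block offset for a position."""
    if not 1 <= pos <= reference_length:
        raise ValueError(f"position {pos} outside 1..{reference_length}")
    y = math.ceil(pos / block_size)
    offset = pos - (y - 1) * block_size
    return BlockAddress(ref_index, y, block_size), offset


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return NA_TOKEN
        return repr(float(v))
    return str(v)


def write_profile_blocks(rows: pd.DataFrame, ref_index: int, out_dir,
                         block_size: int = DEFAULT_BLOCK_SIZE) -> list[Path]:
    """Write a profile as x_y.txt block files; returns the paths in y-order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos = rows["pos"].to_numpy()
    if len(pos) == 0:
        raise ValueError("empty profile")
    if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
        raise ValueError("profile rows must cover positions 1..n contiguously")
    n = len(pos)
    paths = []
    for y in range(1, math.ceil(n / block_size) + 1):
        addr = BlockAddress(ref_index, y, block_size)
        start, end = addr.span(n)
        path = out_dir / addr.filename
        chunk = rows.iloc[start - 1:end]
        with open(path, "w") as fh:
            fh.write(_HEADER + "\n")
            for rec in chunk.itertuples(index=False):
                fh.write("\t".join(_format_value(v) for v in rec) + "\n")
        paths.append(path)
    return paths


def _read_block(path) -> pd.DataFrame:
    rows = []
    with _open_block(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((
                int(f[0]), f[1], int(f[2]),
                float("nan") if f[3] == NA_TOKEN else float(f[3]),
                int(f[4]), int(f[5]), int(f[6]), int(f[7]),
                float("nan") if f[8] == NA_TOKEN else float(f[8]),
            ))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def read_region(ref_index: int, start: int, end: int, profile_dir,
                block_size: int = DEFAULT_BLOCK_SIZE) -> pd.DataFrame:
    """Rows for positions [start, end], opening only the overlapping blocks."""
    if start < 1 or end < start:
        raise ValueError(f"bad region {start}-{end}")
    profile_dir = Path(profile_dir)
    y_lo = math.ceil(start / block_size)
    y_hi = math.ceil(end / block_size)
    parts = []
    for y in range(y_lo, y_hi + 1):
        path = profile_dir / BlockAddress(ref_index, y, block_size).filename
        if not path.exists():
            raise FileNotFoundError(f"missing profile block file: {path}")
        parts.append(_read_block(path))
    df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=PROFILE_COLUMNS)
    df = df[(df["pos"] >= start) & (df["pos"] <= end)].reset_index(drop=True)
    return df


def read_profile(ref_index: int, profile_dir,
                 block_size: int = DEFAULT_BLOCK_SIZE) -> pd.DataFrame:
    """Concatenate all blocks of one reference in y-order."""
    profile_dir = Path(profile_dir)
    parts = []
    y = 1
    while True:
        path = profile_dir / BlockAddress(ref_index, y, block_size).filename
        if not path.exists():
            break
        parts.append(_read_block(path))
        y += 1
    if not parts:
        raise FileNotFoundError(
            f"no profile blocks for reference {ref_index} in {profile_dir}")
    return pd.concat(parts, ignore_index=True)


INDEX_FILE = "references.tsv"


def write_reference_index(entries, out_dir) -> Path:
    """Per-reference index: ref_index -> FASTA ID, length, mapped reads.

    ``entries`` is an iterable of dicts with keys ref_index, id, length,
    mapped_reads (extra keys are preserved as extra columns).
    """
    path = Path(out_dir) / INDEX_FILE
    pd.DataFrame(list(entries)).to_csv(path, sep="\t", index=False)
    return path


def read_reference_index(profile_dir) -> pd.DataFrame:
    path = Path(profile_dir) / INDEX_FILE
    if not path.exists():
        raise FileNotFoundError(f"missing reference index: {path}")
    return pd.read_csv(path, sep="\t")
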