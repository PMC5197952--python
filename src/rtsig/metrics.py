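"""Per-position RT-signature metrics and per-reference statistics.

Metrics
-------
arrest rate A(i)
    Fraction of reads covering position i+1 that start exactly at i+1 —
    truncated cDNAs from RT arrest at i pile their 5' ends one position
    downstream of the blocking site.  Undefined (NaN) when coverage at i+1
    is zero.
mismatch rate M(i)
    Non-reference base calls over coverage at i.  Undefined when coverage
    is zero or the reference base is N.
CSA (context-sensitive arrest rate)
    Fold change of A(i) over the median arrest rate of its +-r neighborhood
    (i excluded, default r = 5).  A pseudocount added to numerator and
    denominator keeps the ratio defined in arrest-free regions while
    preserving CSA = 1 on flat profiles.

Reference statistics
--------------------
S_A / S_M count high-arrest / high-mismatch sites via a one-sided exact
binomial tail against a background rate — a coverage-normalized threshold:
a given rate is insignificant at low coverage but captured at high
coverage.  S_H counts heterogeneous-mismatch sites: coverage >= 20 and the
median of the three non-reference base frequencies >= 0.1, i.e. at least
two mismatch types at >= 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CsaConfig:
    """Window radius and pseudocount for the context-sensitive arrest rate."""

    r: int = 5
    pseudocount: float = 0.001

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("window radius r must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def arrest_rate(n_start_next: int, coverage_next: int) -> float:
    """A(i) = read starts at i+1 over coverage at i+1; NaN when uncovered."""
    if n_start_next < 0 or coverage_next < 0:
        raise ValueError("counts must be non-negative")
    if n_start_next > coverage_next:
        raise ValueError("start count exceeds coverage")
    if coverage_next == 0:
        return float("nan")
    return n_start_next / coverage_next


def mismatch_rate(n_A: int, n_C: int, n_G: int, n_T: int,
                  ref_base: str, coverage: int) -> float:
    """Non-reference base calls over coverage; NaN if uncovered or ref N.

    Deletion calls do not count as mismatches: only the four base types do.
    """
    if coverage == 0 or ref_base not in "ACGT":
        return float("nan")
    counts = {"A": n_A, "C": n_C, "G": n_G, "T": n_T}
    return sum(v for b, v in counts.items() if b != ref_base) / coverage


def _median(values: np.ndarray) -> float:
    # midpoint-average convention for even-sized sets
    return float(np.median(values))


def csa(arrest: np.ndarray, i: int, cfg: CsaConfig | None = None) -> float:
    """Context-sensitive arrest rate at 1-based position ``i``.

    ``arrest`` is the per-position arrest-rate array; NaN entries are
    treated as 0.  The window holds up to ``r`` neighbors on each side,
    excluding ``i`` itself, truncated at the sequence ends.  Returns NaN for
    a length-1 profile (empty window).
    """
    cfg = cfg or CsaConfig()
    a = np.nan_to_num(np.asarray(arrest, dtype=float), nan=0.0)
    n = len(a)
    if not 1 <= i <= n:
        raise IndexError(f"position {i} outside profile of length {n}")
    idx = i - 1
    lo = max(0, idx - cfg.r)
    hi = min(n, idx + cfg.r + 1)
    window = np.concatenate([a[lo:idx], a[idx + 1:hi]])
    if window.size == 0:
        return float("nan")
    p = cfg.pseudocount
    denom = _median(window) + p
    if denom == 0:
        return float("nan")
    return (a[idx] + p) / denom


def csa_profile(arrest: np.ndarray, cfg: CsaConfig | None = None) -> np.ndarray:
    """CSA at every position of an arrest-rate array."""
    cfg = cfg or CsaConfig()
    n = len(arrest)
    return np.array([csa(arrest, i, cfg) for i in range(1, n + 1)], dtype=float)


# ---------------------------------------------------------------------------
# per-reference site statistics, computed on a profile table
# (see profiles.PROFILE_COLUMNS for the expected columns)

def _base_count_matrix(rows: pd.DataFrame) -> np.ndarray:
    return rows[["n_A", "n_C", "n_G", "n_T"]].to_numpy(dtype=float)


def heterogeneous_sites(rows: pd.DataFrame, min_coverage: int = 20,
                        min_median_mf: float = 0.1) -> int:
    """S_H: positions where >= 2 mismatch types each reach 10% frequency.

    A position contributes when coverage >= ``min_coverage`` and the median
    of the three non-reference base frequencies F_b = n_b / coverage
    (b != reference base) is >= ``min_median_mf``.  Rows with reference
    base N never contribute.
    """
    cov = rows["coverage"].to_numpy(dtype=float)
    ref = rows["ref_base"].to_numpy()
    counts = _base_count_matrix(rows)
    order = np.array(list("ACGT"))
    valid = (cov >= min_coverage) & np.isin(ref, order)
    if not valid.any():
        return 0
    freqs = counts[valid] / cov[valid, None]
    # mask the reference base, take the median of the remaining three
    is_ref = ref[valid, None] == order[None, :]
    med = np.nanmedian(np.where(is_ref, np.nan, freqs), axis=1)
    return int(np.sum(med >= min_median_mf))


def _event_counts(rows: pd.DataFrame, which: str) -> tuple[np.ndarray, np.ndarray]:
    """(event count k, relevant coverage c) per row for 'mismatch' or 'arrest'.

    Mismatch events use the row's own counts.  Arrest information for row i
    lives at position i+1: the rate stored on row i is starts(i+1) over
    coverage(i+1), so the relevant coverage is the next row's and the count
    is recovered exactly by rounding rate * coverage.
    """
    cov = rows["coverage"].to_numpy(dtype=float)
    if which == "mismatch":
        counts = _base_count_matrix(rows)
        ref = rows["ref_base"].to_numpy()
        order = np.array(list("ACGT"))
        is_ref = ref[:, None] == order[None, :]
        k = np.where(is_ref, 0.0, counts).sum(axis=1)
        # mismatch undefined for non-ACGT reference bases: never an event
        k = np.where(np.isin(ref, order), k, 0.0)
        return k, cov
    if which == "arrest":
        a = rows["arrest_rate"].to_numpy(dtype=float)
        c_next = np.append(cov[1:], 0.0)
        k = np.where(np.isnan(a), 0.0, a) * c_next
        return np.rint(k), c_next
    raise ValueError(f"unknown metric {which!r}")


def high_rate_sites(rows: pd.DataFrame, which: str, p0: float = 0.05,
                    alpha: float = 0.001, mode: str = "binomial",
                    rate_threshold: float = 0.1) -> int:
    """S_A (``which='arrest'``) or S_M (``which='mismatch'``).

    ``mode='binomial'`` (default): count positions whose one-sided exact
    binomial tail P(X >= k | c, p0) is <= alpha — low rates are
    insignificant at low coverage but captured when coverage is high.
    ``mode='rate'``: a flat rate threshold instead (k/c >= rate_threshold).
    """
    if mode == "binomial" and not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    k, c = _event_counts(rows, which)
    ok = (c > 0) & (k > 0)
    if mode == "rate":
        with np.errstate(invalid="ignore", divide="ignore"):
            return int(np.sum(ok & (k / np.where(c > 0, c, 1) >= rate_threshold)))
    tails = stats.binom.sf(k[ok] - 1, c[ok], p0)
    return int(np.sum(tails <= alpha))


@dataclass
class ReferenceStats:
    """Per-reference summary row for the statistics table."""

    id: str
    path: str
    length: int
    sequence_head: str  # first 100 nt
    coverage_peak: int
    S_A: int
    S_M: int
    S_H: int
    mapped_reads: int

    FIELDS = ("id", "path", "length", "sequence_head", "coverage_peak",
              "S_A", "S_M", "S_H", "mapped_reads")


def reference_summary(rows: pd.DataFrame, ref_id: str, sequence: str,
                      mapped_reads: int, path: str = "",
                      p0: float = 0.05, alpha: float = 0.001) -> ReferenceStats:
    """Gather the summary statistics for one reference sequence."""
    cov = rows["coverage"].to_numpy()
    return ReferenceStats(
        id=ref_id,
        path=str(path),
        length=len(sequence),
        sequence_head=sequence[:100],
        coverage_peak=int(cov.max()) if len(cov) else 0,
        S_A=high_rate_sites(rows, "arrest", p0=p0, alpha=alpha),
        S_M=high_rate_sites(rows, "mismatch", p0=p0, alpha=alpha),
        S_H=heterogeneous_sites(rows),
        mapped_reads=int(mapped_reads),
    )


def summary_table(stats_list) -> pd.DataFrame:
    """Stack `ReferenceStats` into the sortable/filterable summary table."""
    return pd.DataFrame(
        [{f: getattr(s, f) for f in ReferenceStats.FIELDS} for s in stats_list],
        columns=list(ReferenceStats.FIELDS),
    )
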