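"""Screen profile positions with threshold formulas and attach significance.

Every position passing a minimum-coverage gate is tested: the observed
event count (non-reference base calls, or read starts for the arrest
metric) is compared against a background rate with a one-sided exact
binomial tail, and the raw p-values are corrected for the number of tested
positions (Bonferroni or Benjamini-Hochberg).  The user formula is then
evaluated on each gated row; ``p`` and ``p_adj`` are formula variables, so
``p_adj <= 0.05 AND mism >= 0.1`` works as expected.

The original screening concept is threshold-only; the significance test is
this package's addition and can be bypassed with ``correction='none'`` and
a formula that ignores ``p``/``p_adj``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import formula as fm
from . import metrics
from .metrics import CsaConfig

CANDIDATE_COLUMNS = [
    "ref_index", "pos", "ref", "cov", "mism", "A", "CSA",
    "fA", "fC", "fG", "fT", "nA", "nC", "nG", "nT",
    "p", "p_adj", "passed",
]


def site_pvalue(k: int, c: int, p0: float) -> float:
    """One-sided exact binomial tail P(X >= k | c, p0)."""
    if not 0 <= k <= c:
        raise ValueError(f"need 0 <= k <= c, got k={k}, c={c}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binom.sf(k - 1, c, p0))


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment, returned in input order.

    ``bonferroni``: min(1, p*m).  ``bh``: Benjamini-Hochberg step-up
    adjusted values.  ``none``: unchanged.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if method == "none":
        return p.copy()
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=key)[1]


@dataclass
class ScanConfig:
    """Significance settings for a candidate scan.

    metric
        Which event count the binomial test uses: ``mismatch`` or ``arrest``.
    p0
        Background event rate.  ``None`` (default) estimates it as the
        pooled genome-wide rate, total event count / total coverage over
        the gated positions — the binomial MLE of the background, slightly
        conservative when the data contain true sites.
    method
        ``bh`` | ``bonferroni`` | ``none``.
    min_coverage
        Positions below this coverage are never tested; the correction uses
        m = number of gated positions.
    """

    metric: str = "mismatch"
    p0: float | None = None
    method: str = "bh"
    min_coverage: int = 20
    csa: CsaConfig = field(default_factory=CsaConfig)


def _pooled_rate(k: np.ndarray, c: np.ndarray) -> float:
    total_c = float(c.sum())
    if total_c <= 0:
        return 0.5  # degenerate: nothing covered, p-values all 1 anyway
    total_k = float(k.sum())
    # keep the estimate strictly inside (0, 1)
    return min(max(total_k / total_c, 0.5 / total_c), 1 - 0.5 / total_c)


def snapshot_frame(rows: pd.DataFrame, ref_index: int = 1,
                   csa_cfg: CsaConfig | None = None) -> pd.DataFrame:
    """Profile rows -> per-position formula-variable snapshots.

    Adds the derived CSA column and the base fractions fA..fT.
    """
    cov = rows["coverage"].to_numpy(dtype=float)
    safe = np.where(cov > 0, cov, 1.0)
    snap = pd.DataFrame({
        "ref_index": ref_index,
        "pos": rows["pos"].to_numpy(),
        "ref": rows["ref_base"].to_numpy(),
        "cov": rows["coverage"].to_numpy(),
        "mism": rows["mismatch_rate"].to_numpy(dtype=float),
        "A": rows["arrest_rate"].to_numpy(dtype=float),
        "CSA": metrics.csa_profile(rows["arrest_rate"].to_numpy(dtype=float),
                                   csa_cfg or CsaConfig()),
    })
    for b in "ACGT":
        n_b = rows[f"n_{b}"].to_numpy(dtype=float)
        snap[f"n{b}"] = rows[f"n_{b}"].to_numpy()
        snap[f"f{b}"] = np.where(cov > 0, n_b / safe, np.nan)
    return snap


def call_candidates(rows: pd.DataFrame, ast, config: ScanConfig | None = None,
                    ref_index: int = 1) -> pd.DataFrame:
    """Evaluate a threshold formula over a profile; one record per hit.

    Returns a candidates table (`CANDIDATE_COLUMNS`): gated positions where
    the formula holds, with their metric snapshot and raw/adjusted p-values.
    """
    config = config or ScanConfig()
    if isinstance(ast, str):
        ast = fm.parse_formula(ast)
    used = fm.variables(ast)
    diff_used = used & fm.DIFFERENTIAL_VARIABLES
    if diff_used:
        raise fm.FormulaError(
            "differential variables "
            + ", ".join(sorted(diff_used))
            + " require two profiles; use the differential comparison")

    snap = snapshot_frame(rows, ref_index=ref_index, csa_cfg=config.csa)
    mask = (snap["cov"] >= config.min_coverage).to_numpy()
    gated = snap[mask].reset_index(drop=True)
    if gated.empty:
        out = pd.DataFrame(columns=CANDIDATE_COLUMNS)
        return out

    # event counts are position-linked (arrest looks one row downstream),
    # so compute them on the full profile and subset afterwards
    k_full, c_full = metrics._event_counts(rows.reset_index(drop=True), config.metric)
    k, c = k_full[mask], c_full[mask]
    p0 = config.p0 if config.p0 is not None else _pooled_rate(k, c)
    with np.errstate(invalid="ignore"):
        p_raw = np.where(c > 0, stats.binom.sf(np.maximum(k, 0) - 1,
                                               np.maximum(c, 1), p0), 1.0)
    gated["p"] = p_raw
    gated["p_adj"] = adjust_pvalues(p_raw, config.method)

    hits = [fm.evaluate_formula(ast, row) for row in gated.to_dict("records")]
    out = gated[np.asarray(hits, dtype=bool)].reset_index(drop=True)
    out["passed"] = True
    return out[CANDIDATE_COLUMNS]


def write_candidates(records: pd.DataFrame, path) -> None:
    """Candidates TSV: stable documented column order, one record per line."""
    records.to_csv(path, sep="\t", index=False, na_rep="NA",
                   columns=[c for c in CANDIDATE_COLUMNS if c in records.columns])


def read_candidates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
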