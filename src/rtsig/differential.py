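"""Positionwise comparison of two profiles of the same reference.

Typical pairings: untreated vs. chemically treated (e.g. alkaline Dimroth
rearrangement erasing an m1A mismatch signature) or wild-type vs.
methyltransferase knockout.  Sample 2 is the "treated"/second sample and
every delta is sample 2 minus sample 1.

A per-position two-sided Fisher exact test on the (mismatch, match) x
(sample 1, sample 2) table is available as an optional significance layer;
plain threshold criteria on the deltas remain the default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import candidates as cand
from . import formula as fm
from .candidates import ScanConfig
from .metrics import CsaConfig

DIFF_CANDIDATE_COLUMNS = [
    "ref_index", "pos", "ref",
    "cov1", "mism1", "A1", "CSA1",
    "cov2", "mism2", "A2", "CSA2",
    "d_mism", "d_A", "d_CSA",
    "p", "p_adj", "passed",
]


def pair_profiles(rows1: pd.DataFrame, rows2: pd.DataFrame,
                  csa_cfg: CsaConfig | None = None,
                  ref_index: int = 1) -> pd.DataFrame:
    """Positionwise join of two profiles with sample2-minus-sample1 deltas.

    Deltas are NA wherever either sample's metric is undefined.
    """
    if len(rows1) != len(rows2):
        raise ValueError(
            f"profiles cover different lengths: {len(rows1)} vs {len(rows2)}")
    if not np.array_equal(rows1["pos"].to_numpy(), rows2["pos"].to_numpy()):
        raise ValueError("profiles cover different positions")

    s1 = cand.snapshot_frame(rows1, ref_index=ref_index, csa_cfg=csa_cfg)
    s2 = cand.snapshot_frame(rows2, ref_index=ref_index, csa_cfg=csa_cfg)
    out = pd.DataFrame({
        "ref_index": ref_index,
        "pos": s1["pos"],
        "ref": s1["ref"],
    })
    for name in ("cov", "mism", "A", "CSA"):
        out[f"{name}1"] = s1[name]
        out[f"{name}2"] = s2[name]
    for b in "ACGT":
        out[f"f{b}1"] = s1[f"f{b}"]
        out[f"f{b}2"] = s2[f"f{b}"]
    for name, col in (("d_mism", "mism"), ("d_A", "A"), ("d_CSA", "CSA")):
        out[name] = s2[col] - s1[col]
    # carry the raw counts needed by the Fisher test
    out["_mm1"] = _mismatch_counts(rows1)
    out["_mm2"] = _mismatch_counts(rows2)
    return out


def _mismatch_counts(rows: pd.DataFrame) -> np.ndarray:
    counts = rows[["n_A", "n_C", "n_G", "n_T"]].to_numpy(dtype=float)
    ref = rows["ref_base"].to_numpy()
    order = np.array(list("ACGT"))
    return np.where(ref[:, None] == order[None, :], 0.0, counts).sum(axis=1)


def differential_test(mm1: int, cov1: int, mm2: int, cov2: int) -> float:
    """Two-sided Fisher exact p for (mismatch, match) x (sample 1, sample 2).

    NaN when either sample has zero coverage.  The same machinery applies
    to arrest counts (pass start counts and downstream coverages).
    """
    if cov1 == 0 or cov2 == 0:
        return float("nan")
    table = [[int(mm1), int(cov1 - mm1)], [int(mm2), int(cov2 - mm2)]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def flag_differential_sites(diff: pd.DataFrame, ast,
                            config: ScanConfig | None = None) -> pd.DataFrame:
    """Evaluate a delta-aware formula over a paired-profile table.

    The coverage gate requires BOTH samples at ``min_coverage``; ``p`` is
    the per-position Fisher exact p on mismatch counts, corrected over the
    gated positions.
    """
    config = config or ScanConfig()
    if isinstance(ast, str):
        ast = fm.parse_formula(ast)
    unknown = fm.variables(ast) - set(diff.columns) - {"p", "p_adj"}
    if unknown:
        raise fm.FormulaError(
            "variables not available in a differential comparison: "
            + ", ".join(sorted(unknown)))

    mask = ((diff["cov1"] >= config.min_coverage)
            & (diff["cov2"] >= config.min_coverage)).to_numpy()
    gated = diff[mask].reset_index(drop=True)
    if gated.empty:
        return pd.DataFrame(columns=DIFF_CANDIDATE_COLUMNS)

    p_raw = np.array([
        differential_test(mm1, c1, mm2, c2)
        for mm1, c1, mm2, c2 in zip(gated["_mm1"], gated["cov1"],
                                    gated["_mm2"], gated["cov2"])
    ])
    gated["p"] = p_raw
    gated["p_adj"] = cand.adjust_pvalues(np.nan_to_num(p_raw, nan=1.0),
                                         config.method)

    hits = [fm.evaluate_formula(ast, row) for row in gated.to_dict("records")]
    out = gated[np.asarray(hits, dtype=bool)].reset_index(drop=True)
    out["passed"] = True
    return out[DIFF_CANDIDATE_COLUMNS]


def write_differential(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, na_rep="NA",
                   columns=[c for c in DIFF_CANDIDATE_COLUMNS
                            if c in records.columns])
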