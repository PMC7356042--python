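"""Replicate-level quantification of fully tryptic peptides (t-LiP-MRM).

For each monitored precursor the peak areas of treated and control runs are
compared per ligand concentration: the fold change is the ratio of means,
the p-value a two-sided two-sample t-test (Student by default; Welch and
log-transformed variants are available).  A peptide is called *protected*
when its fold change exceeds 1 and its p-value falls below alpha at every
tested concentration -- the dual-concentration rule guards against
single-condition flukes at triplicate sample sizes.

No multiple-testing correction is applied by default (the protection call
operates on raw p-values); a Benjamini-Hochberg option is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTROL = "control"


def treated_label(concentration: float) -> str:
    c = int(concentration) if float(concentration).is_integer() else concentration
    return f"treated@{c}"


def fold_change(treated_areas, control_areas) -> float:
    """Ratio of mean treated area to mean control area."""
    t = np.asarray(treated_areas, dtype=float)
    c = np.asarray(control_areas, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("replicate vectors must be non-empty")
    if (t <= 0).any() or (c <= 0).any():
        raise ValueError("peak areas must be positive")
    return float(t.mean() / c.mean())


def test_difference(treated_areas, control_areas, method: str = "student",
                    log_areas: bool = False) -> float:
    """Two-sided two-sample t-test p-value on replicate peak areas.

    ``method`` is ``"student"`` (equal variance, the default) or ``"welch"``;
    ``log_areas`` tests log-transformed areas instead.  Degenerate inputs
    follow fixed conventions: zero variance in both groups gives p = 1.0 for
    equal means and p = 0.0 for unequal means.
    """
    t = np.asarray(treated_areas, dtype=float)
    c = np.asarray(control_areas, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if (t <= 0).any() or (c <= 0).any():
        raise ValueError("peak areas must be positive")
    if log_areas:
        t, c = np.log(t), np.log(c)
    if t.std(ddof=1) == 0.0 and c.std(ddof=1) == 0.0:
        return 1.0 if t.mean() == c.mean() else 0.0
    if method == "student":
        res = stats.ttest_ind(t, c, equal_var=True)
    elif method == "welch":
        res = stats.ttest_ind(t, c, equal_var=False)
    else:
        raise ValueError(f"unknown test method {method!r}")
    return float(res.pvalue)


@dataclass(frozen=True)
class PeptideStat:
    """Per-precursor fold changes and p-values across concentrations."""

    precursor_id: str
    #: concentration -> (fold_change, p_value)
    per_concentration: tuple[tuple[float, float, float], ...]
    protected: bool = False

    def fold_at(self, concentration: float) -> float:
        for c, fc, _ in self.per_concentration:
            if c == concentration:
                return fc
        raise KeyError(concentration)

    def p_at(self, concentration: float) -> float:
        for c, _, p in self.per_concentration:
            if c == concentration:
                return p
        raise KeyError(concentration)


class AreaMatrix:
    """Replicate MRM peak areas in long format.

    Columns: ``precursor_id``, ``condition`` (``control`` or
    ``treated@<c>``), ``replicate``, ``area``; descriptive columns such as
    ``peptide``, ``start``, ``end``, ``charge``, ``q1_mz`` are carried
    through when present.
    """

    REQUIRED = ["precursor_id", "condition", "replicate", "area"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"area matrix missing columns {missing}")
        if (frame["area"] <= 0).any():
            raise ValueError("peak areas must be positive")
        counts = frame.groupby(["precursor_id", "condition"])["replicate"].count()
        if (counts < 2).any():
            bad = counts[counts < 2].index[0]
            raise ValueError(f"fewer than 2 replicates for {bad}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path) -> "AreaMatrix":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")

    def areas(self, precursor_id: str, condition: str) -> np.ndarray:
        sub = self.frame[
            (self.frame["precursor_id"] == precursor_id)
            & (self.frame["condition"] == condition)
        ]
        return sub["area"].to_numpy(dtype=float)

    @property
    def precursor_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["precursor_id"]))


def compute_stats(matrix: AreaMatrix, concentrations: list[float],
                  method: str = "student", log_areas: bool = False,
                  alpha: float = 0.05,
                  bh_correct: bool = False) -> list[PeptideStat]:
    """Fold change and p-value per precursor per concentration.

    With ``bh_correct`` the p-values are Benjamini-Hochberg adjusted within
    each concentration before the protection call.
    """
    ids = matrix.precursor_ids
    per_conc: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for c in concentrations:
        label = treated_label(c)
        fcs, ps = [], []
        for pid in ids:
            treated = matrix.areas(pid, label)
            control = matrix.areas(pid, CONTROL)
            if treated.size == 0:
                raise ValueError(f"{pid}: missing condition {label!r}")
            fcs.append(fold_change(treated, control))
            ps.append(test_difference(treated, control, method=method,
                                      log_areas=log_areas))
        ps_arr = np.asarray(ps)
        if bh_correct:
            ps_arr = multipletests(ps_arr, method="fdr_bh")[1]
        per_conc[c] = (np.asarray(fcs), ps_arr)
    stats_out = []
    for i, pid in enumerate(ids):
        per = tuple(
            (c, float(per_conc[c][0][i]), float(per_conc[c][1][i]))
            for c in concentrations
        )
        protected = all(fc > 1.0 and p < alpha for _, fc, p in per)
        stats_out.append(PeptideStat(pid, per, protected))
    return stats_out


def select_protected(stats_list: list[PeptideStat], alpha: float = 0.05,
                     concentrations: list[float] | None = None) -> list[PeptideStat]:
    """Precursors with fold change > 1 and p < alpha at every concentration."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    selected = []
    for stat in stats_list:
        concs = concentrations or [c for c, _, _ in stat.per_concentration]
        have = {c for c, _, _ in stat.per_concentration}
        missing = [c for c in concs if c not in have]
        if missing:
            raise ValueError(
                f"{stat.precursor_id}: missing concentration(s) {missing}"
            )
        ok = all(stat.fold_at(c) > 1.0 and stat.p_at(c) < alpha for c in concs)
        if ok:
            selected.append(
                PeptideStat(stat.precursor_id, stat.per_concentration, True)
            )
    return selected


def stats_to_frame(stats_list: list[PeptideStat],
                   concentrations: list[float],
                   extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wide stats table: one row per precursor, fc/p per concentration."""
    rows = []
    for stat in stats_list:
        row: dict = {"precursor_id": stat.precursor_id}
        for c in concentrations:
            tag = treated_label(c).split("@")[1]
            row[f"fc_{tag}uM"] = round(stat.fold_at(c), 4)
            row[f"p_{tag}uM"] = stat.p_at(c)
        row["protected"] = stat.protected
        rows.append(row)
    frame = pd.DataFrame(rows)
    if extra is not None:
        frame = frame.merge(extra, on="precursor_id", how="left")
    return frame
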