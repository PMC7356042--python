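"""DARTS protection scoring from spectral-match counts and lane profiles.

In a DARTS experiment, ligand binding shields the target from limited
proteolysis, so the intact-protein signal in a treated lane sits between the
vehicle control (fully exposed) and the undigested lysate (fully shielded).
The protection percentage normalises the treated signal onto that range::

    protection = 100 * (treated - control) / (undigested - control)

0% means no protection (treated equals control), 100% means complete
protection (treated equals the undigested level).  With noisy counts the
ratio can leave [0, 100]; such values are reported but flagged rather than
silently clamped, and are excluded from ranking by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

UNDIGESTED = "undigested"
CONTROL = "control"


def treated_label(concentration: float) -> str:
    c = int(concentration) if float(concentration).is_integer() else concentration
    return f"treated@{c}"


@dataclass(frozen=True)
class ProtectionValue:
    percent: float | None
    denominator_invalid: bool = False
    out_of_range: bool = False


@dataclass(frozen=True)
class ProtectionResult:
    protein_id: str
    #: concentration -> protection value
    per_concentration: tuple[tuple[float, ProtectionValue], ...]
    dose_consistent: bool = False

    def at(self, concentration: float) -> ProtectionValue:
        for c, v in self.per_concentration:
            if c == concentration:
                return v
        raise KeyError(concentration)


def protection_percentage(treated: float, control: float,
                          undigested: float) -> ProtectionValue:
    """The DARTS protection score for one protein at one concentration.

    Counts must be non-negative.  A non-positive denominator (undigested not
    above control) yields no value and the ``denominator_invalid`` flag.
    """
    for name, v in (("treated", treated), ("control", control),
                    ("undigested", undigested)):
        if v < 0:
            raise ValueError(f"{name} count must be non-negative, got {v}")
    denom = undigested - control
    if denom <= 0:
        return ProtectionValue(None, denominator_invalid=True)
    pct = 100.0 * (treated - control) / denom
    return ProtectionValue(pct, out_of_range=not (0.0 <= pct <= 100.0))


class MatchCountTable:
    """Spectral-match counts per protein and condition (long format).

    Columns: ``protein_id``, optional ``band_mw_kda``, ``condition``,
    ``count``.  Conditions are ``undigested``, ``control`` and
    ``treated@<c>`` for each ligand concentration ``c``.
    """

    REQUIRED = ["protein_id", "condition", "count"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"match-count table missing columns {missing}")
        if (frame["count"] < 0).any():
            raise ValueError("negative spectral-match count")
        conditions = set(frame["condition"])
        if UNDIGESTED not in conditions or CONTROL not in conditions:
            raise ValueError(
                f"conditions must include {UNDIGESTED!r} and {CONTROL!r}"
            )
        if not any(c.startswith("treated@") for c in conditions):
            raise ValueError("at least one treated@<conc> condition required")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path) -> "MatchCountTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")

    def counts_for(self, protein_id: str) -> dict[str, float]:
        sub = self.frame[self.frame["protein_id"] == protein_id]
        # multiple bands for one protein are summed at its molecular weight
        return sub.groupby("condition")["count"].sum().to_dict()

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self.frame["protein_id"].unique())


class LaneProfile:
    """Densitometric lane intensities over a shared molecular-weight axis.

    One row per MW bin (column ``mw_bin_kda``), one column per lane.
    """

    def __init__(self, frame: pd.DataFrame):
        if "mw_bin_kda" not in frame.columns:
            raise ValueError("lane profile needs a mw_bin_kda column")
        lanes = [c for c in frame.columns if c != "mw_bin_kda"]
        if not lanes:
            raise ValueError("lane profile needs at least one lane column")
        if (frame[lanes] < 0).any().any():
            raise ValueError("negative lane intensity")
        self.frame = frame.reset_index(drop=True)
        self.lanes = lanes

    @classmethod
    def read_tsv(cls, path) -> "LaneProfile":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def nominate_bands(profile: LaneProfile, lane_order: list[str],
                   min_total_increase: float = 0.20) -> list:
    """MW bins whose intensity rises with ligand concentration.

    ``lane_order`` lists lane columns from control to the highest
    concentration.  A bin is nominated when intensity is non-decreasing along
    that order and the total relative increase over the control lane is at
    least ``min_total_increase`` (default 20%).
    """
    missing = [lane for lane in lane_order if lane not in profile.lanes]
    if missing:
        raise ValueError(f"lanes {missing} absent from profile")
    nominated = []
    for _, row in profile.frame.iterrows():
        values = [row[lane] for lane in lane_order]
        monotone = all(b >= a for a, b in zip(values, values[1:]))
        if not monotone:
            continue
        base = values[0]
        if base <= 0:
            # a silent control lane with any treated signal counts as a rise
            if values[-1] > 0:
                nominated.append(row["mw_bin_kda"])
            continue
        if (values[-1] - base) / base >= min_total_increase:
            nominated.append(row["mw_bin_kda"])
    return nominated


def score_table(table: MatchCountTable,
                concentrations: list[float]) -> list[ProtectionResult]:
    """Protection per protein and concentration, with dose-consistency flag."""
    results = []
    for pid in table.protein_ids:
        counts = table.counts_for(pid)
        if UNDIGESTED not in counts or CONTROL not in counts:
            raise ValueError(f"{pid}: missing undigested or control counts")
        per = []
        for c in concentrations:
            label = treated_label(c)
            if label not in counts:
                raise ValueError(f"{pid}: missing condition {label!r}")
            per.append((c, protection_percentage(counts[label], counts[CONTROL],
                                                 counts[UNDIGESTED])))
        vals = [v.percent for _, v in per]
        dose_consistent = (
            all(v is not None for v in vals)
            and all(b >= a for a, b in zip(vals, vals[1:]))
        )
        results.append(ProtectionResult(pid, tuple(per), dose_consistent))
    return results


def rank_targets(table: MatchCountTable, concentrations: list[float],
                 include_flagged: bool = False) -> list[ProtectionResult]:
    """Proteins sorted by protection at the highest concentration, descending.

    Proteins with an invalid denominator sort last; out-of-range protection
    values are excluded from the ranked block by default (they join the
    trailing block).  Ties are broken by protein id for a stable order.
    """
    results = score_table(table, concentrations)
    top = max(concentrations)

    def sort_key(res: ProtectionResult):
        val = res.at(top)
        unrankable = val.denominator_invalid or (
            val.out_of_range and not include_flagged
        )
        if unrankable:
            return (1, 0.0, res.protein_id)
        return (0, -val.percent, res.protein_id)

    return sorted(results, key=sort_key)


def results_to_frame(results: list[ProtectionResult],
                     concentrations: list[float]) -> pd.DataFrame:
    rows = []
    for rank, res in enumerate(results, start=1):
        row: dict = {"protein_id": res.protein_id, "rank": rank}
        flags = []
        for c in concentrations:
            v = res.at(c)
            row[f"protection_pct@{treated_label(c).split('@')[1]}uM"] = (
                round(v.percent, 3) if v.percent is not None else math.nan
            )
            if v.denominator_invalid:
                flags.append(f"denominator_invalid@{c}")
            if v.out_of_range:
                flags.append(f"out_of_range@{c}")
        row["dose_consistent"] = res.dose_consistent
        row["flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)
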