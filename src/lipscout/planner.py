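"""Deterministic MRM method construction.

Targeted limited-proteolysis experiments monitor the fully tryptic peptides
of a candidate target on a triple quadrupole.  Public spectral-library
resources rank candidate transitions by observed intensity; intensities are
not reproducible offline, so this planner substitutes a deterministic score
encoding the standard heuristics used when picking transitions by hand:

* y ions are preferred over b ions (more stable under CID for tryptic
  peptides with a C-terminal K/R),
* fragments above the precursor m/z are preferred (cleaner of low-mass
  chemical noise and of precursor-related interference),
* mid-sequence ordinals are mildly preferred over terminal fragments.

Identical input always yields a byte-identical transition list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .digest import Enzyme, Peptide, TRYPSIN, TrypticStatus, digest
from .fragments import FragmentIon, enumerate_fragments
from .mass import PrecursorIon, precursor_mz
from .proteins import ProteinRecord


@dataclass(frozen=True)
class PlannerConfig:
    """Filters applied when selecting quantifiable precursors."""

    min_length: int = 7
    max_length: int = 25
    min_mz: float = 300.0
    max_mz: float = 1250.0
    max_missed: int = 0
    charge: int = 2
    transitions_per_precursor: int = 3
    enzyme: Enzyme = TRYPSIN
    #: exclude peptides containing Cys or Met, whose modification status can
    #: perturb quantification; off by default.
    exclude_cys_met: bool = False
    fixed_mods: dict[str, float] | None = None


@dataclass(frozen=True)
class MRMEntry:
    precursor: PrecursorIon
    transitions: tuple[FragmentIon, ...]
    #: set when fewer eligible fragments existed than requested
    short: bool = False


@dataclass(frozen=True)
class MRMMethod:
    entries: tuple[MRMEntry, ...]
    config: PlannerConfig
    diagnostics: tuple[str, ...] = ()

    @property
    def n_precursors(self) -> int:
        return len(self.entries)


def transition_score(fragment: FragmentIon, precursor: PrecursorIon) -> float:
    """Deterministic stand-in for observed fragment intensity."""
    n = precursor.peptide.length
    score = 0.0
    if fragment.series == "y":
        score += 2.0
    if fragment.mz > precursor.mz:
        score += 1.0
    if 3 <= fragment.ordinal <= n - 2:
        score += 0.5
    return score


def rank_transitions(fragments: list[FragmentIon], precursor: PrecursorIon,
                     k: int = 3) -> tuple[list[FragmentIon], bool]:
    """The ``k`` best transitions in a deterministic total order.

    Ties are broken by series (y before b), then higher ordinal, then lower
    m/z.  When fewer than ``k`` fragments are eligible all of them are
    returned and the second element of the result is True (warning flag).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not fragments:
        raise ValueError("no fragments to rank")
    ordered = sorted(
        fragments,
        key=lambda f: (
            -transition_score(f, precursor),
            0 if f.series == "y" else 1,
            -f.ordinal,
            f.mz,
        ),
    )
    short = len(ordered) < k
    return ordered[:k], short


def build_method(proteins: list[ProteinRecord],
                 config: PlannerConfig | None = None) -> MRMMethod:
    """Select quantifiable precursors from a digest and attach transitions.

    Default filters: fully tryptic, unmodified (no variable modifications),
    zero missed cleavages, length 7-25, precursor m/z 300-1250, three
    transitions per precursor.
    """
    cfg = config or PlannerConfig()
    entries: list[MRMEntry] = []
    diagnostics: list[str] = []
    for protein in proteins:
        peptides = digest(protein, enzyme=cfg.enzyme, max_missed=cfg.max_missed)
        kept = 0
        for pep in peptides:
            if pep.tryptic_status is not TrypticStatus.FULLY_TRYPTIC:
                continue
            if not cfg.min_length <= pep.length <= cfg.max_length:
                continue
            if cfg.exclude_cys_met and (set(pep.sequence) & {"C", "M"}):
                continue
            prec = precursor_mz(pep, charge=cfg.charge, mods=cfg.fixed_mods)
            if not cfg.min_mz <= prec.mz <= cfg.max_mz:
                continue
            frags = enumerate_fragments(prec)
            if not frags:
                continue
            best, short = rank_transitions(frags, prec, cfg.transitions_per_precursor)
            entries.append(MRMEntry(prec, tuple(best), short=short))
            kept += 1
        if kept == 0:
            diagnostics.append(
                f"{protein.id}: no peptide passed the planner filters"
            )
    return MRMMethod(entries=tuple(entries), config=cfg,
                     diagnostics=tuple(diagnostics))


#: Fixed column order of the transition-list export, for interoperability
#: with downstream vendor tools.
TRANSITION_COLUMNS = [
    "protein_id", "peptide_sequence", "start", "end", "precursor_charge",
    "precursor_mz", "fragment_series", "fragment_ordinal", "fragment_charge",
    "product_mz", "rank",
]


def method_to_frame(method: MRMMethod) -> pd.DataFrame:
    rows = []
    for entry in method.entries:
        pep = entry.precursor.peptide
        for rank, frag in enumerate(entry.transitions, start=1):
            rows.append({
                "protein_id": pep.protein_id,
                "peptide_sequence": pep.sequence,
                "start": pep.start,
                "end": pep.end,
                "precursor_charge": entry.precursor.charge,
                "precursor_mz": round(entry.precursor.mz, 6),
                "fragment_series": frag.series,
                "fragment_ordinal": frag.ordinal,
                "fragment_charge": frag.charge,
                "product_mz": round(frag.mz, 6),
                "rank": rank,
            })
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


def write_transition_list(method: MRMMethod, path) -> None:
    method_to_frame(method).to_csv(path, sep="\t", index=False,
                                   float_format="%.6f", lineterminator="\n")
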