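"""Mapping protected peptides onto protein regions and active-site residues.

A protected peptide localises the ligand effect on the protein sequence.
Overlap with annotated domains or loops gives a region-level (possibly
allosteric-proximal) localisation; containment of catalytic residues makes
the protection *orthosteric* -- the ligand plausibly occupies or remodels
the active site itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .proteins import ProteinRecord


@dataclass(frozen=True)
class RegionAnnotation:
    """A named region of a protein, 1-based inclusive coordinates.

    Regions may abut or overlap; no disjointness is required.
    """

    name: str
    start: int
    end: int
    category: str = "domain"  # "domain" or "loop"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start > end")
        if self.category not in ("domain", "loop"):
            raise ValueError(f"region {self.name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class ActiveSiteSet:
    """Catalytic residues given as (letter, 1-based index) pairs.

    When a reference sequence is supplied every listed letter is checked
    against the sequence at its index; a mismatch is a hard error, guarding
    against numbering drift between annotation sources.
    """

    name: str
    residues: tuple[tuple[str, int], ...]

    def validate_against(self, protein: ProteinRecord) -> None:
        for letter, index in self.residues:
            actual = protein.residue(index)
            if actual != letter:
                raise ValueError(
                    f"active-site residue {letter}{index} ({self.name}): "
                    f"reference sequence has {actual} at position {index}"
                )

    @property
    def indices(self) -> frozenset[int]:
        return frozenset(i for _, i in self.residues)

    def labels(self) -> list[str]:
        return [f"{aa}{i}" for aa, i in sorted(self.residues, key=lambda r: r[1])]


def span_overlap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Number of residues shared by two 1-based inclusive spans."""
    return max(0, min(end_a, end_b) - max(start_a, start_b) + 1)


def map_peptide_to_regions(start: int, end: int,
                           annotations: list[RegionAnnotation]
                           ) -> list[tuple[RegionAnnotation, int]]:
    """Regions overlapping a peptide span by at least one residue,
    with the overlap length (in residues) for each."""
    if start > end or start < 1:
        raise ValueError(f"invalid span [{start},{end}]")
    hits = []
    for region in annotations:
        ov = span_overlap(start, end, region.start, region.end)
        if ov >= 1:
            hits.append((region, ov))
    return hits


def classify_orthosteric(start: int, end: int, sites: ActiveSiteSet,
                         protein: ProteinRecord | None = None
                         ) -> tuple[bool, list[str]]:
    """Whether a peptide span contains any active-site residue.

    Returns the flag and the labels of the residues hit (e.g. ``["T502"]``).
    When a reference protein is given the site letters are validated first.
    """
    if start > end or start < 1:
        raise ValueError(f"invalid span [{start},{end}]")
    if protein is not None:
        sites.validate_against(protein)
    hit = [(aa, i) for aa, i in sites.residues if start <= i <= end]
    hit.sort(key=lambda r: r[1])
    return bool(hit), [f"{aa}{i}" for aa, i in hit]


@dataclass(frozen=True)
class PeptideMapping:
    start: int
    end: int
    label: str
    regions: tuple[tuple[str, int], ...]  # (region name, overlap length)
    active_site_hits: tuple[str, ...]
    orthosteric: bool


def protection_map_report(spans: list[tuple[int, int]],
                          annotations: list[RegionAnnotation],
                          sites: ActiveSiteSet,
                          protein: ProteinRecord | None = None
                          ) -> list[PeptideMapping]:
    """One mapping row per protected peptide span."""
    if protein is not None:
        sites.validate_against(protein)
    report = []
    for start, end in spans:
        overlaps = map_peptide_to_regions(start, end, annotations)
        ortho, hits = classify_orthosteric(start, end, sites, protein=None)
        label = f"[{start}-{end}]"
        if protein is not None:
            label = (f"{protein.residue(start)}-[{start}-{end}]-"
                     f"{protein.residue(end)}")
        report.append(PeptideMapping(
            start=start, end=end, label=label,
            regions=tuple((r.name, ov) for r, ov in overlaps),
            active_site_hits=tuple(hits),
            orthosteric=ortho,
        ))
    return report


def protected_regions(report: list[PeptideMapping]) -> dict[str, int]:
    """Region name -> number of protected peptides overlapping it."""
    counts: dict[str, int] = {}
    for row in report:
        for name, _ in row.regions:
            counts[name] = counts.get(name, 0) + 1
    return counts


def report_to_frame(report: list[PeptideMapping]) -> pd.DataFrame:
    rows = []
    for row in report:
        rows.append({
            "peptide": row.label,
            "start": row.start,
            "end": row.end,
            "regions": ";".join(f"{n}({ov})" for n, ov in row.regions),
            "active_site_hits": ";".join(row.active_site_hits),
            "orthosteric": row.orthosteric,
        })
    return pd.DataFrame(
        rows, columns=["peptide", "start", "end", "regions",
                       "active_site_hits", "orthosteric"])


def read_region_tsv(path) -> dict[str, list[RegionAnnotation]]:
    """Annotation TSV (protein_id, name, start, end, category) -> per-protein lists."""
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, list[RegionAnnotation]] = {}
    for _, row in frame.iterrows():
        out.setdefault(row["protein_id"], []).append(
            RegionAnnotation(row["name"], int(row["start"]), int(row["end"]),
                             row.get("category", "domain")))
    return out


def read_active_site_tsv(path) -> dict[str, ActiveSiteSet]:
    """Active-site TSV (protein_id, set_name, residue_letter, residue_index)."""
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, ActiveSiteSet] = {}
    for pid, sub in frame.groupby("protein_id"):
        residues = tuple(
            (row["residue_letter"], int(row["residue_index"]))
            for _, row in sub.iterrows()
        )
        name = sub["set_name"].iloc[0]
        out[pid] = ActiveSiteSet(name=name, residues=residues)
    return out
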