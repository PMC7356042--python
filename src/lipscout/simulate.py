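"""Synthetic DARTS and t-LiP data with planted, parameterised protection.

The generator emulates the study design the pipeline consumes: three
replicates per condition, two ligand concentrations for the targeted
quantification step (1 and 10 uM) plus a third (100 uM) for the gel-based
step, multiplicative protection of a planted peptide subset, log-normal
multiplicative noise on peak areas, and Poisson spectral-match counts
bounded by the undigested and control levels.

Ligand occupancy follows a single-site hyperbola, ``occ(c) = c / (c + KD)``.
The default KD of 0.1 uM sits well below the assay concentrations so the
planted effect is near-saturating where it is measured; the planted fold
factor phi is then essentially the realised fold change.  All randomness
flows from one integer seed through a PCG64 generator, so identical
parameters give byte-identical outputs on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import darts as _darts
from . import lipquant as _lip
from .digest import Peptide, TRYPSIN, TrypticStatus, digest
from .mapping import RegionAnnotation
from .proteins import ProteinRecord

#: Residue alphabet and draw probabilities for simulated proteins.  K and R
#: together get ~11% so tryptic peptides come out at realistic lengths
#: (mean zero-missed length ~9 residues).
_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_FREQS = np.array([
    0.074, 0.020, 0.053, 0.063, 0.040, 0.071, 0.022, 0.053, 0.058, 0.090,
    0.022, 0.044, 0.051, 0.040, 0.052, 0.072, 0.056, 0.065, 0.012, 0.032,
])
_FREQS = _FREQS / _FREQS.sum()


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one synthetic experiment."""

    seed: int
    concentrations: tuple[float, ...] = (1.0, 10.0)
    replicates: int = 3
    sigma_log: float = 0.15
    occupancy_kd: float = 0.1  # uM
    #: protein id -> planted DARTS protection pi in [0, 1]
    planted_protection: tuple[tuple[str, float], ...] = ()
    #: planted peptide fold factor phi (> 0) for the protected subset
    fold_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.fold_factor <= 0:
            raise ValueError("fold factor must be > 0")
        if self.occupancy_kd < 0:
            raise ValueError("occupancy KD must be >= 0")
        for pid, pi in self.planted_protection:
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"planted protection for {pid} outside [0,1]")

    def occupancy(self, concentration: float) -> float:
        """Single-site binding occupancy; KD = 0 models exact saturation."""
        if concentration <= 0:
            return 0.0
        return concentration / (concentration + self.occupancy_kd)

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.Generator(np.random.PCG64([self.seed, stream]))


def simulate_protein(seed: int, length: int = 500,
                     region_plan: list[tuple[str, int]] | None = None,
                     protein_id: str | None = None
                     ) -> tuple[ProteinRecord, list[RegionAnnotation]]:
    """A random protein with realistic K/R density plus tiled region annotations.

    ``region_plan`` lists (name, length) pairs; regions tile the sequence in
    order and the last region is truncated or extended to the protein end.
    """
    if length < 50:
        raise ValueError("length must be >= 50")
    rng = np.random.Generator(np.random.PCG64([seed, 7]))
    seq = "".join(rng.choice(_RESIDUES, size=length, p=_FREQS))
    pid = protein_id or f"SYN{seed:04d}"
    record = ProteinRecord(id=pid, sequence=seq,
                           description=f"synthetic protein (seed {seed})")
    regions: list[RegionAnnotation] = []
    if region_plan:
        pos = 1
        for i, (name, rlen) in enumerate(region_plan):
            if pos > length:
                break
            end = length if i == len(region_plan) - 1 else min(pos + rlen - 1, length)
            regions.append(RegionAnnotation(name, pos, end, "domain"))
            pos = end + 1
    return record, regions


def select_planted_peptides(protein: ProteinRecord, rng: np.random.Generator,
                            fraction: float = 0.3,
                            min_length: int = 7, max_length: int = 25
                            ) -> tuple[list[Peptide], list[Peptide]]:
    """Split the quantifiable digest into planted (protected) and null sets."""
    peptides = [
        p for p in digest(protein, TRYPSIN, max_missed=0)
        if min_length <= p.length <= max_length
    ]
    n_planted = int(round(fraction * len(peptides)))
    idx = rng.permutation(len(peptides))
    planted = sorted(idx[:n_planted].tolist())
    planted_set = set(planted)
    return ([p for i, p in enumerate(peptides) if i in planted_set],
            [p for i, p in enumerate(peptides) if i not in planted_set])


def simulate_lip_areas(truth: SyntheticTruth, peptides: list[Peptide],
                       planted: set[str] | None = None,
                       base_area_range: tuple[float, float] = (1e4, 1e7)
                       ) -> _lip.AreaMatrix:
    """Replicate peak areas for a set of precursors.

    Control expected areas are log-uniform over ``base_area_range``; planted
    precursors get ``A * (1 + (phi - 1) * occ(c))`` under treatment; every
    observed area is the expected area times ``exp(eps)`` with
    ``eps ~ Normal(0, sigma_log)``.
    """
    planted = planted or set()
    rng = truth.rng(stream=11)
    lo, hi = base_area_range
    if not (0 < lo < hi):
        raise ValueError("invalid base area range")
    rows = []
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(peptides)))
    for i, pep in enumerate(peptides):
        pid = f"{pep.protein_id}:{pep.span_label()}/2"
        conditions = [(_lip.CONTROL, base[i])]
        for c in truth.concentrations:
            expected = base[i]
            if pid in planted or pep.span_label() in planted:
                expected = base[i] * (1.0 + (truth.fold_factor - 1.0)
                                      * truth.occupancy(c))
            conditions.append((_lip.treated_label(c), expected))
        for condition, expected in conditions:
            eps = rng.normal(0.0, truth.sigma_log, size=truth.replicates)
            for r, noise in enumerate(eps, start=1):
                rows.append({
                    "precursor_id": pid,
                    "peptide": pep.sequence,
                    "start": pep.start,
                    "end": pep.end,
                    "charge": 2,
                    "condition": condition,
                    "replicate": r,
                    "area": float(expected * np.exp(noise)),
                })
    return _lip.AreaMatrix(pd.DataFrame(rows))


def simulate_darts_counts(truth: SyntheticTruth,
                          lambda_undigested: dict[str, float] | None = None,
                          survival_ratio: float = 0.3,
                          concentrations: tuple[float, ...] | None = None
                          ) -> _darts.MatchCountTable:
    """Poisson spectral-match counts for the DARTS stage.

    Per protein: undigested counts are Poisson with mean ``lambda_u`` (drawn
    log-uniformly from [50, 1000] unless supplied), control counts Poisson
    with mean ``r * lambda_u`` (``r`` = ``survival_ratio``), and treated
    counts Poisson with mean ``lambda_c + pi * occ(c) * (lambda_u -
    lambda_c)`` -- protection moves the expectation from the control level
    toward, never past, the undigested level.
    """
    if not 0 < survival_ratio < 1:
        raise ValueError("survival ratio must lie in (0, 1)")
    concs = concentrations or truth.concentrations
    rng = truth.rng(stream=23)
    planted = dict(truth.planted_protection)
    if lambda_undigested is None:
        if not planted:
            raise ValueError("no proteins to simulate")
        lambda_undigested = {
            pid: float(np.exp(rng.uniform(np.log(50), np.log(1000))))
            for pid in planted
        }
    rows = []
    for pid, lam_u in lambda_undigested.items():
        if not 0 < lam_u:
            raise ValueError(f"{pid}: lambda_u must be positive")
        pi = planted.get(pid, 0.0)
        lam_c = survival_ratio * lam_u
        rows.append({"protein_id": pid, "condition": _darts.UNDIGESTED,
                     "count": int(rng.poisson(lam_u))})
        rows.append({"protein_id": pid, "condition": _darts.CONTROL,
                     "count": int(rng.poisson(lam_c))})
        for c in concs:
            lam_t = lam_c + pi * truth.occupancy(c) * (lam_u - lam_c)
            rows.append({"protein_id": pid,
                         "condition": _darts.treated_label(c),
                         "count": int(rng.poisson(lam_t))})
    return _darts.MatchCountTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class SyntheticBundle:
    """A complete synthetic experiment ready for the end-to-end pipeline."""

    truth: SyntheticTruth
    proteins: list[ProteinRecord]
    regions: dict[str, list[RegionAnnotation]]
    target_id: str
    planted_peptides: list[Peptide]
    null_peptides: list[Peptide]
    darts_table: _darts.MatchCountTable
    area_matrix: _lip.AreaMatrix

    def truth_dict(self) -> dict:
        return {
            "seed": self.truth.seed,
            "concentrations": list(self.truth.concentrations),
            "replicates": self.truth.replicates,
            "sigma_log": self.truth.sigma_log,
            "occupancy_kd": self.truth.occupancy_kd,
            "fold_factor": self.truth.fold_factor,
            "planted_protection": dict(self.truth.planted_protection),
            "target": self.target_id,
            "planted_peptides": [p.span_label() for p in self.planted_peptides],
        }


def simulate_bundle(seed: int, n_proteins: int = 6, target_protection: float = 0.8,
                    background_protection: float = 0.05,
                    truth: SyntheticTruth | None = None,
                    darts_concentrations: tuple[float, ...] = (1.0, 10.0, 100.0),
                    ) -> SyntheticBundle:
    """One planted target among decoys, with matching DARTS and t-LiP data.

    The first simulated protein is the target: it receives
    ``target_protection`` in the DARTS stage and a planted protected peptide
    subset in the quantification stage; decoys get a small background
    protection.
    """
    base = truth or SyntheticTruth(seed=seed)
    proteins: list[ProteinRecord] = []
    regions: dict[str, list[RegionAnnotation]] = {}
    plan = [("N-dom", 150), ("core", 200), ("C-dom", 150)]
    planted_prot = []
    for i in range(n_proteins):
        rec, regs = simulate_protein(seed * 1000 + i, length=500, region_plan=plan)
        proteins.append(rec)
        regions[rec.id] = regs
        planted_prot.append(
            (rec.id, target_protection if i == 0 else background_protection))
    truth_full = replace(base, planted_protection=tuple(planted_prot))
    target = proteins[0]
    rng = truth_full.rng(stream=5)
    planted_peps, null_peps = select_planted_peptides(target, rng)
    planted_ids = {p.span_label() for p in planted_peps}
    area = simulate_lip_areas(truth_full, planted_peps + null_peps,
                              planted=planted_ids)
    counts = simulate_darts_counts(truth_full,
                                   concentrations=darts_concentrations)
    return SyntheticBundle(
        truth=truth_full, proteins=proteins, regions=regions,
        target_id=target.id, planted_peptides=planted_peps,
        null_peptides=null_peps, darts_table=counts, area_matrix=area,
    )
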