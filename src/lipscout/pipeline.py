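"""End-to-end orchestration: DARTS ranking -> MRM planning -> quantification
-> region mapping, with every stage result written as a TSV.

When input files are not supplied the pipeline runs on a synthetic bundle
generated from the configured seed, so the whole chain is exercisable
without any laboratory data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import darts as _darts
from . import lipquant as _lip
from . import mapping as _map
from .config import PipelineConfig
from .digest import ENZYMES
from .mass import precursor_mz
from .planner import PlannerConfig, build_method, method_to_frame, write_transition_list
from .proteins import read_fasta, write_fasta
from .simulate import SyntheticBundle, simulate_bundle

log = logging.getLogger("lipscout")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return inner
    return wrap


@_stage("darts")
def _run_darts(config: PipelineConfig, bundle: SyntheticBundle | None,
               out: Path) -> tuple[list[_darts.ProtectionResult], list[float]]:
    if config.darts_counts:
        table = _darts.MatchCountTable.read_tsv(config.darts_counts)
        concs = sorted({
            float(c.split("@")[1]) for c in table.frame["condition"]
            if c.startswith("treated@")
        })
    else:
        table = bundle.darts_table
        concs = [1.0, 10.0, 100.0]
    log.info("DARTS scoring: %d proteins, concentrations %s",
             len(table.protein_ids), concs)
    ranked = _darts.rank_targets(table, concs)
    frame = _darts.results_to_frame(ranked, concs)
    frame.to_csv(out / "darts_report.tsv", sep="\t", index=False,
                 lineterminator="\n")
    if config.lane_profile:
        profile = _darts.LaneProfile.read_tsv(config.lane_profile)
        lanes = [profile.lanes[0]] + profile.lanes[1:]
        bands = _darts.nominate_bands(profile, lanes,
                                      config.band_increase_threshold)
        pd.DataFrame({"mw_bin_kda": bands}).to_csv(
            out / "nominated_bands.tsv", sep="\t", index=False,
            lineterminator="\n")
        log.info("band nomination: %d of %d bins", len(bands),
                 len(profile.frame))
    return ranked, concs


@_stage("plan")
def _run_plan(config: PipelineConfig, proteins, candidate_id: str, out: Path):
    targets = [p for p in proteins if p.id == candidate_id] or proteins[:1]
    planner = PlannerConfig(
        min_length=config.min_peptide_length,
        max_length=config.max_peptide_length,
        min_mz=config.min_precursor_mz,
        max_mz=config.max_precursor_mz,
        charge=config.precursor_charge,
        transitions_per_precursor=config.transitions_per_precursor,
        enzyme=ENZYMES[config.enzyme],
    )
    method = build_method(targets, planner)
    log.info("MRM planning for %s: %d precursors, %d transitions each",
             candidate_id, method.n_precursors,
             config.transitions_per_precursor)
    write_transition_list(method, out / "transitions.tsv")
    return method


@_stage("lipquant")
def _run_lipquant(config: PipelineConfig, bundle: SyntheticBundle | None,
                  out: Path) -> tuple[list[_lip.PeptideStat], pd.DataFrame]:
    if config.areas:
        matrix = _lip.AreaMatrix.read_tsv(config.areas)
    else:
        matrix = bundle.area_matrix
    concs = [float(c) for c in config.concentrations]
    log.info("t-LiP quantification: %d precursors, alpha=%.3g, "
             "concentrations %s", len(matrix.precursor_ids), config.alpha,
             concs)
    stats = _lip.compute_stats(matrix, concs, alpha=config.alpha)
    protected = _lip.select_protected(stats, alpha=config.alpha,
                                      concentrations=concs)
    extra_cols = [c for c in ("peptide", "start", "end", "charge", "q1_mz", "rt")
                  if c in matrix.frame.columns]
    extra = (matrix.frame[["precursor_id"] + extra_cols]
             .drop_duplicates("precursor_id") if extra_cols else None)
    frame = _lip.stats_to_frame(stats, concs, extra=extra)
    frame.to_csv(out / "peptide_stats.tsv", sep="\t", index=False,
                 lineterminator="\n")
    prot_frame = _lip.stats_to_frame(protected, concs, extra=extra)
    prot_frame.to_csv(out / "protected_peptides.tsv", sep="\t", index=False,
                      lineterminator="\n")
    return protected, frame


@_stage("map")
def _run_map(config: PipelineConfig, bundle: SyntheticBundle | None,
             protected: list[_lip.PeptideStat], candidate_id: str,
             stats_frame: pd.DataFrame, out: Path):
    spans = []
    sub = stats_frame[stats_frame["precursor_id"].isin(
        {p.precursor_id for p in protected})]
    if {"start", "end"} <= set(sub.columns):
        spans = [(int(r["start"]), int(r["end"])) for _, r in sub.iterrows()]
    if config.annotations:
        regions = _map.read_region_tsv(config.annotations).get(candidate_id, [])
    elif bundle is not None:
        regions = bundle.regions.get(candidate_id, [])
    else:
        regions = []
    if config.active_sites:
        sites = _map.read_active_site_tsv(config.active_sites).get(
            candidate_id, _map.ActiveSiteSet("none", ()))
    else:
        sites = _map.ActiveSiteSet("none", ())
    report = _map.protection_map_report(spans, regions, sites)
    _map.report_to_frame(report).to_csv(out / "region_map.tsv", sep="\t",
                                        index=False, lineterminator="\n")
    log.info("region mapping: %d protected spans, regions hit: %s",
             len(spans), sorted(_map.protected_regions(report)))
    return report


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the output directory.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("enzyme=%s max_missed=%d alpha=%.3g k=%d seed=%d",
             config.enzyme, config.max_missed, config.alpha,
             config.transitions_per_precursor, config.seed)

    bundle = None
    needs_synthetic = not (config.darts_counts and config.areas and config.fasta)
    if needs_synthetic:
        bundle = simulate_bundle(config.seed)
        write_fasta(bundle.proteins, out / "proteins.fasta")
        bundle.darts_table.write_tsv(out / "darts_counts.tsv")
        bundle.area_matrix.write_tsv(out / "areas.tsv")
        with open(out / "truth.json", "w") as handle:
            json.dump(bundle.truth_dict(), handle, indent=2, sort_keys=True)

    ranked, darts_concs = _run_darts(config, bundle, out)
    candidate_id = ranked[0].protein_id if ranked else ""

    if config.fasta:
        proteins = read_fasta(config.fasta)
    else:
        proteins = bundle.proteins
    _run_plan(config, proteins, candidate_id, out)

    protected, stats_frame = _run_lipquant(config, bundle, out)
    report = _run_map(config, bundle, protected, candidate_id, stats_frame, out)

    summary = {
        "candidate_targets": [
            {"protein_id": r.protein_id,
             "protection_top": r.per_concentration[-1][1].percent,
             "dose_consistent": r.dose_consistent}
            for r in ranked[:10]
        ],
        "top_target": candidate_id,
        "n_protected_peptides": len(protected),
        "protected_regions": _map.protected_regions(report),
    }
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    log.info("pipeline complete: top target %s, %d protected peptides",
             candidate_id, len(protected))
    return out
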