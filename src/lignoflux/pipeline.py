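"""End-to-end orchestration: observations -> FBA -> MOMA -> trends -> MC.

A single :class:`PipelineConfig` (fully serializable; embedded verbatim in
the run manifest) drives all stages.  One global seed fans out
deterministically to the synthetic-data generator and to each Monte Carlo
experiment, so a rerun with the same config is byte-identical apart from
file timestamps.  A mutant internode whose constraint set is infeasible is
recorded in the manifest and does not abort the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import data as data_mod
from .data import INTERNODES, TRANSGENIC_LINES, generate_synthetic_study, read_observations
from .fba import FBAProblem, FluxDistribution, MonomerComposition, wildtype_reference
from .moma import KnockdownSpec, knockdown_constraints, solve_moma
from .montecarlo import AdmissibilityConfig, SamplingConfig, run_ensemble
from .network import build_reference_network
from .trends import TrendConfig, classify_trend, pairwise_flux_correlation, partition_ratios

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "results"
    observations_path: str | None = None  # None -> generate synthetic study
    seed: int = 7
    network_variant: str = "extended"
    fba_policy: str = "main-route"
    noise_sigma: float = 0.1
    trend_unchanged_rel_range: float = 0.05
    trend_spearman_cutoff: float = 0.6
    mc_n_draws: int = 2000
    mc_factor: float = 0.2
    mc_influx: float = 0.5
    mc_significance_threshold: float = 0.05
    mc_sg_window: tuple[float, float] = (0.09, 0.64)
    #: (kinetics, target enzyme) pairs to run
    mc_experiments: tuple[tuple[str, str], ...] = (("mm", "CCoAOMT"), ("mm", "CCR1"))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mc_sg_window"] = list(self.mc_sg_window)
        d["mc_experiments"] = [list(x) for x in self.mc_experiments]
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "mc_sg_window" in raw:
            raw["mc_sg_window"] = tuple(raw["mc_sg_window"])
        if "mc_experiments" in raw:
            raw["mc_experiments"] = tuple(tuple(x) for x in raw["mc_experiments"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _flux_payload(line: str, internode: str, dist: FluxDistribution) -> dict:
    return {
        "line": line,
        "internode": internode,
        "policy": dist.selection_policy_tag,
        "objective": dist.objective_value,
        "fluxes": {k: round(v, 12) for k, v in dist.values.items()},
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = build_reference_network(config.network_variant)
    trend_cfg = TrendConfig(
        unchanged_rel_range=config.trend_unchanged_rel_range,
        spearman_cutoff=config.trend_spearman_cutoff,
    )

    # --- observations -----------------------------------------------------
    if config.observations_path is None:
        design = data_mod.StudyDesign(noise_sigma=config.noise_sigma)
        table = generate_synthetic_study(design, seed=config.seed)
    else:
        table = read_observations(config.observations_path)
    obs_path = out / "observations.csv"
    data_mod.write_observations(table, obs_path)

    def comp_of(line: str, internode: str) -> MonomerComposition:
        row = table[(table.line_id == line) & (table.internode == internode)].iloc[0]
        return MonomerComposition.from_percent(row.h_pct, row.g_pct, row.s_pct)

    internodes = [k for k in INTERNODES if k in set(table.internode)]
    lines = [l for l in TRANSGENIC_LINES if l in set(table.line_id)]

    # --- wild-type FBA ----------------------------------------------------
    wt_refs: dict[str, FluxDistribution] = {}
    files: list[Path] = [obs_path]
    infeasible: list[dict] = []
    for key in internodes:
        problem = FBAProblem(net, comp_of("WT", key))
        ref = wildtype_reference(problem, config.fba_policy)
        wt_refs[key] = ref
        p = out / "wt" / f"internode_{key}.json"
        _write_json(p, _flux_payload("WT", key, ref))
        files.append(p)

    # --- MOMA per line x internode ---------------------------------------
    moma_dists: dict[tuple[str, str], FluxDistribution] = {}
    for line in lines:
        alpha = float(table[table.line_id == line].alpha.iloc[0])
        spec = KnockdownSpec(line, alpha)
        # A knockdown that caps v1 itself (PAL) contradicts the fixed v1 = 1
        # normalization; the cap then replaces the normalization equality.
        caps = knockdown_constraints(net, spec, wt_refs[internodes[0]])
        fix_v1 = caps.get("v1", 1.0) >= 1.0
        for key in internodes:
            res = solve_moma(net, spec, comp_of(line, key), wt_refs[key], fix_v1=fix_v1)
            if not res.feasible:
                infeasible.append({"line": line, "internode": key})
                logger.warning("MOMA infeasible for %s internode %s", line, key)
                continue
            moma_dists[(line, key)] = res.fluxes
            p = out / "moma" / f"{line}_internode_{key}.json"
            payload = _flux_payload(line, key, res.fluxes)
            payload["distance"] = res.distance
            _write_json(p, payload)
            files.append(p)

    # --- trends -----------------------------------------------------------
    trend_rows = []
    for line in ["WT"] + lines:
        dists = (
            wt_refs
            if line == "WT"
            else {k: moma_dists[(line, k)] for k in internodes if (line, k) in moma_dists}
        )
        if len(dists) < 3:
            continue
        for s in partition_ratios(dists, net):
            if any(v is None for v in s.values):
                category = "undefined"
            else:
                category = classify_trend(s.values, trend_cfg).name
            row = {"line": line, "branch_point": s.branch_point, "ratio_id": s.ratio_id,
                   "category": category}
            row.update({f"i{k}": v for k, v in zip(s.internodes, s.values)})
            trend_rows.append(row)
    trends_path = out / "trends.csv"
    pd.DataFrame(trend_rows).to_csv(trends_path, index=False)
    files.append(trends_path)

    # --- v13/v14 correlation over non-CCoAOMT mutants ----------------------
    pool = [d for (line, _k), d in moma_dists.items() if line != "CCoAOMT"]
    corr_path = out / "correlations.json"
    if len(pool) >= 3:
        corr = pairwise_flux_correlation(pool, "v13", "v14")
        _write_json(corr_path, {"flux_pair": list(corr.flux_pair),
                                "pearson_rho": corr.pearson_rho,
                                "n_points": corr.n_points})
        files.append(corr_path)

    # --- Monte Carlo ensembles ---------------------------------------------
    adm = AdmissibilityConfig(sg_window=config.mc_sg_window)
    for i, (kin, target) in enumerate(config.mc_experiments):
        sampling = SamplingConfig(
            n_draws=config.mc_n_draws,
            kinetics=kin,
            influx=config.mc_influx,
            seed=config.seed * 1000 + i,  # deterministic per-stage fan-out
        )
        summary, _ = run_ensemble(
            sampling, adm, target, config.mc_factor,
            config.mc_significance_threshold, keep_records=False,
        )
        p = out / "mc" / f"{kin}_{target}.json"
        _write_json(p, summary.to_dict())
        files.append(p)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "infeasible": infeasible,
        "n_wildtype_internodes": len(wt_refs),
        "n_moma_solutions": len(moma_dists),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
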