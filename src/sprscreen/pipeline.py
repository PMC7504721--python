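"""End-to-end campaign orchestration: simulate → process → triage →
affinity → activity, with a validated configuration, per-stage logging and
a machine-readable report whose JSON mirrors the text summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import activity as act
from .affinity import AffinityResult, aggregate_replicates, fit_steady_state
from .library import Compound, synthetic_library
from .processing import (ReportPointKind, SolventCalibration, SurfaceDef,
                         apply_solvent_correction, double_reference,
                         fit_solvent_calibration, measure_ref_bulk,
                         report_point, select_calibration)
from .simulate import (ArtifactModel, BinderClass, Campaign, CompoundProfile,
                       InjectionSchedule, KineticModel, simulate_campaign,
                       simulate_dose_series, simulate_elisa_plate)
from .triage import (ScreenRecord, TriageConfig, abnormal_shape, call_hit,
                     campaign_summary, clean_screen, theoretical_rmax)

log = logging.getLogger("sprscreen")


# -- configuration -------------------------------------------------------------

def _from_dict(cls, data: Mapping):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected on load so a
    typo in a threshold name cannot silently fall back to a default."""

    seed: int = 0
    n_compounds: int = 200
    outdir: str = "results"
    noise_sd: float = 0.3  # RU
    surface_name: str = "ligand"
    ligand_mw: float = 92000.0  # Da
    immobilization: float = 9200.0  # RU
    class_fractions: Mapping[str, float] = field(default_factory=lambda: {
        "clean_binder": 0.05, "non_binder": 0.80,
        "sticky": 0.10, "superstoichiometric": 0.05})
    triage: TriageConfig = field(default_factory=TriageConfig)
    max_kd_fits: int = 5
    kd_replicates: int = 3
    elisa_ic50: float | None = None  # M; enables the activity stage
    elisa_hill: float = 1.0
    elisa_noise_cv: float = 0.05

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        if "triage" in data and isinstance(data["triage"], Mapping):
            data["triage"] = _from_dict(TriageConfig, data["triage"])
        return _from_dict(cls, data)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def surface(self) -> SurfaceDef:
        return SurfaceDef(name=self.surface_name, ligand_mw=self.ligand_mw,
                          immobilization=self.immobilization)


# -- processing a simulated / loaded campaign ----------------------------------

def _calibration_blocks(campaign: Campaign, stage: str) -> list[SolventCalibration]:
    """Fit one solvent calibration per contiguous run of calibration cycles;
    each calibration covers cycles from its block up to the next block."""
    recs = [r for r in campaign.cycles if r.meta.stage == stage]
    blocks: list[list] = []
    current: list = []
    for r in recs:
        if r.meta.is_calibration:
            current.append(r)
        elif current:
            blocks.append(current)
            current = []
    if current:
        blocks.append(current)
    cals = []
    last_cycle = max(r.meta.cycle for r in recs)
    for i, block in enumerate(blocks):
        start = block[0].meta.cycle
        end = blocks[i + 1][0].meta.cycle - 1 if i + 1 < len(blocks) else last_cycle
        cal = fit_solvent_calibration(
            [(r.active, r.reference) for r in block], cycle_span=(start, end))
        cals.append(cal)
    return cals


def _blanks(campaign: Campaign, stage: str) -> list:
    return [r for r in campaign.cycles
            if r.meta.stage == stage and r.meta.is_blank]


def _nearest_blank(blanks: Sequence, cycle: int):
    return min(blanks, key=lambda r: abs(r.meta.cycle - cycle))


def process_campaign(campaign: Campaign, *, solvent_correct: bool = True) -> pd.DataFrame:
    """Reduce every sample cycle of a campaign to corrected report points.

    Per stage: fit piecewise solvent calibrations from the calibration
    cycles, double-reference each sample cycle against its nearest buffer
    blank, extract binding and residual report points, and solvent-correct
    the binding point using the cycle's reference bulk response.

    Returns one row per (compound, stage) with columns ``binding_ru``,
    ``residual_ru``, ``ref_bulk_ru`` and ``in_range``.
    """
    rows = []
    for stage in ("clean", "binding"):
        recs = [r for r in campaign.cycles
                if r.meta.stage == stage and not r.meta.is_calibration
                and not r.meta.is_blank]
        if not recs:
            continue
        cals = _calibration_blocks(campaign, stage) if solvent_correct else []
        blanks = _blanks(campaign, stage)
        for r in recs:
            blank = _nearest_blank(blanks, r.meta.cycle)
            corrected = double_reference(
                r.active, r.reference,
                blank=(blank.active, blank.reference))
            binding = report_point(corrected, ReportPointKind.BINDING)
            residual = report_point(corrected, ReportPointKind.RESIDUAL)
            ref_bulk = measure_ref_bulk(r.reference)
            in_range = True
            if solvent_correct:
                cal = select_calibration(cals, r.meta.cycle)
                binding, in_range = apply_solvent_correction(binding, ref_bulk, cal)
            rows.append({
                "cycle": r.meta.cycle, "compound_id": r.meta.compound_id,
                "stage": stage, "conc_M": r.meta.conc_M,
                "binding_ru": binding.value, "residual_ru": residual.value,
                "ref_bulk_ru": ref_bulk, "in_range": in_range,
            })
    return pd.DataFrame(rows)


def triage_campaign(
    processed: pd.DataFrame,
    library: Sequence[Compound],
    surface: SurfaceDef,
    cfg: TriageConfig = TriageConfig(),
    insoluble: set[str] = frozenset(),
) -> list[ScreenRecord]:
    """Run the screening cascade over processed report points.

    Order matches the campaign: insolubility flag → clean screen (residual
    on the bare surface) → solvent-correction range check → abnormal-shape
    heuristic → Rmax-normalized hit calling with the superstoichiometric
    exclusion.
    """
    by_id = {c.id: c for c in library}
    clean = processed[processed["stage"] == "clean"].set_index("compound_id")
    binding = processed[processed["stage"] == "binding"].set_index("compound_id")
    records = []
    for cid, compound in by_id.items():
        rec = ScreenRecord(compound_id=cid)
        if cid in insoluble:
            rec.flags.add("insoluble")
            rec.hit = False
            records.append(rec)
            log.debug("%s: excluded (insoluble)", cid)
            continue
        if cid in clean.index:
            rec.residual_ru = float(clean.loc[cid, "residual_ru"])
            if rec.residual_ru > cfg.clean_threshold:
                rec.flags.add("clean_fail")
                rec.hit = False
                records.append(rec)
                log.debug("%s: failed clean screen (%.2f RU)", cid, rec.residual_ru)
                continue
        if cid not in binding.index:
            rec.flags.add("not_screened")
            rec.hit = False
            records.append(rec)
            continue
        row = binding.loc[cid]
        rec.binding_ru = float(row["binding_ru"])
        rec.rmax_theoretical = theoretical_rmax(surface, compound, n=cfg.stoich_n)
        if not bool(row["in_range"]):
            rec.flags.add("out_of_calibration")
        binding_resid = float(row["residual_ru"])
        if (binding_resid > rec.binding_ru + 3 * cfg.baseline_noise_ru
                or rec.binding_ru < -3 * cfg.baseline_noise_ru):
            rec.flags.add("abnormal_shape")
        call_hit(rec, cfg)
        records.append(rec)
    return records


def records_frame(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "compound_id": r.compound_id, "binding_ru": r.binding_ru,
        "residual_ru": r.residual_ru, "rmax_theoretical": r.rmax_theoretical,
        "pct_rmax": r.pct_rmax, "flags": ";".join(sorted(r.flags)),
        "hit": r.hit,
    } for r in records])


def hit_confusion(records: Sequence[ScreenRecord], truth: pd.DataFrame) -> dict:
    """Sensitivity/specificity of hit calling and of the clean screen
    against the simulator's planted ground truth."""
    t = truth.set_index("compound_id")
    pred_hit = {r.compound_id: bool(r.hit) for r in records}
    pred_clean_fail = {r.compound_id: "clean_fail" in r.flags for r in records}

    def rates(pred: Mapping[str, bool], col: str) -> tuple[float, float]:
        tp = fn = tn = fp = 0
        for cid, yhat in pred.items():
            y = bool(t.loc[cid, col])
            tp += y and yhat
            fn += y and not yhat
            tn += (not y) and (not yhat)
            fp += (not y) and yhat
        sens = tp / (tp + fn) if tp + fn else 1.0
        spec = tn / (tn + fp) if tn + fp else 1.0
        return sens, spec

    hit_sens, hit_spec = rates(pred_hit, "expected_hit")
    cln_sens, cln_spec = rates(pred_clean_fail, "expected_clean_fail")
    return {"hit_sensitivity": hit_sens, "hit_specificity": hit_spec,
            "clean_sensitivity": cln_sens, "clean_specificity": cln_spec}


# -- affinity and activity stages ----------------------------------------------

def fit_hit_affinities(
    campaign: Campaign,
    records: Sequence[ScreenRecord],
    library: Sequence[Compound],
    artifacts: ArtifactModel,
    *,
    replicates: int = 3,
    max_fits: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose-series follow-up of called hits: simulate replicate dilution
    series from each hit's planted kinetics, extract plateau report points
    and fit the Rmax-constrained steady-state KD."""
    by_id = {c.id: c for c in library}
    truth = campaign.truth.set_index("compound_id")
    hits = [r for r in records if r.hit][:max_fits]
    rows = []
    for k, rec in enumerate(hits):
        cid = rec.compound_id
        km = KineticModel.from_equilibrium(float(truth.loc[cid, "kd_eq_M"]),
                                           stoich_n=float(truth.loc[cid, "stoich_n"]))
        profile = CompoundProfile(cid, by_id[cid].mw, BinderClass.CLEAN, km)
        reps = simulate_dose_series(profile, None, campaign.surface,
                                    campaign.schedule, artifacts,
                                    replicates=replicates, seed=seed + 7 * k + 1)
        rmax = theoretical_rmax(campaign.surface, by_id[cid])
        fits = []
        for cycles in reps:
            series = []
            for active, reference in cycles:
                corrected = double_reference(active, reference)
                rp = report_point(corrected, ReportPointKind.BINDING)
                series.append((active.meta.conc_M, rp.value))
            fits.append(fit_steady_state(series, rmax))
        agg = aggregate_replicates(fits)
        rows.append({
            "compound_id": cid, "kd_mean_M": agg.kd_mean, "kd_sd_M": agg.kd_sd,
            "n_reps": agg.n_replicates,
            "kd_true_M": float(truth.loc[cid, "kd_eq_M"]),
            "rss": float(np.nansum(agg.rss_per_replicate)),
        })
    return pd.DataFrame(rows)


def fit_elisa_ic50(ic50: float, hill: float, noise_cv: float, seed: int,
                   compound_id: str = "CMP") -> act.DoseResponseResult:
    """Simulate one dose-response plate and fit its IC50 from per-column
    control-normalized percent activity."""
    plate = simulate_elisa_plate(ic50, hill, noise_cv=noise_cv, seed=seed,
                                 compound_id=compound_id)
    norm = act.normalize_plate(plate)
    samples = norm[norm["role"] == "sample"]
    doses = list(zip(samples["conc_M"], samples["pct_activity"]))
    return act.fit_ic50(doses, model="fixed_slope")


# -- full pipeline --------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic campaign and return the report bundle.

    Deterministic for a given config (all randomness flows from
    ``cfg.seed``); writes records, affinity and activity CSVs plus JSON and
    text summaries into ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = synthetic_library(cfg.n_compounds, seed=cfg.seed)
    surface = cfg.surface()
    artifacts = ArtifactModel(noise_sd=cfg.noise_sd, seed=cfg.seed)

    log.info("simulating %d-compound campaign", cfg.n_compounds)
    campaign = simulate_campaign(library, surface, artifacts,
                                 class_fractions=cfg.class_fractions,
                                 seed=cfg.seed)
    log.info("processing %d cycles", len(campaign.cycles))
    processed = process_campaign(campaign)
    records = triage_campaign(processed, library, surface, cfg.triage)
    summary = campaign_summary(records, library)
    confusion = hit_confusion(records, campaign.truth)

    log.info("fitting affinities for up to %d hits", cfg.max_kd_fits)
    affinities = fit_hit_affinities(campaign, records, library, artifacts,
                                    replicates=cfg.kd_replicates,
                                    max_fits=cfg.max_kd_fits, seed=cfg.seed)

    activity_rows = []
    if cfg.elisa_ic50 is not None:
        res = fit_elisa_ic50(cfg.elisa_ic50, cfg.elisa_hill,
                             cfg.elisa_noise_cv, cfg.seed)
        activity_rows.append({
            "compound_id": "CMP", "ic50_M": res.ic50,
            "ci_lo_M": res.ci95[0], "ci_hi_M": res.ci95[1],
            "model": res.model, "extrapolated": res.extrapolated,
        })
    activity_df = pd.DataFrame(activity_rows)

    bundle = {
        "config": _config_dict(cfg),
        "summary": summary,
        "confusion": confusion,
        "records": records_frame(records),
        "affinity": affinities,
        "activity": activity_df,
    }
    bundle["records"].to_csv(outdir / "records.csv", index=False)
    affinities.to_csv(outdir / "affinity.csv", index=False)
    activity_df.to_csv(outdir / "activity.csv", index=False)
    text, js = render_summary(bundle)
    (outdir / "summary.txt").write_text(text)
    (outdir / "summary.json").write_text(json.dumps(js, indent=2, sort_keys=True))
    return bundle


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["class_fractions"] = dict(d["class_fractions"])
    return d


def render_summary(bundle: dict) -> tuple[str, dict]:
    """Human-readable text plus a JSON object mirroring every number in it."""
    s = bundle["summary"]
    conf = bundle.get("confusion", {})
    aff: pd.DataFrame = bundle.get("affinity", pd.DataFrame())
    act_df: pd.DataFrame = bundle.get("activity", pd.DataFrame())

    js = {
        "screened_total": s["total"],
        "insoluble": s["insoluble"],
        "clean_screen_failures": s["clean_fail"],
        "carried_forward": s["carried_forward"],
        "out_of_calibration": s["out_of_calibration"],
        "superstoichiometric": s["superstoichiometric"],
        "hits": s["hits"],
        "hit_rate_pct": s["hit_rate_pct"],
        "confusion": {k: round(v, 4) for k, v in conf.items()},
        "kd_table": aff.to_dict(orient="records") if len(aff) else [],
        "ic50_table": act_df.to_dict(orient="records") if len(act_df) else [],
    }
    lines = [
        "screening campaign summary",
        "==========================",
        f"compounds screened: {js['screened_total']}",
        f"insoluble: {js['insoluble']}",
        f"clean-screen failures: {js['clean_screen_failures']}",
        f"carried forward: {js['carried_forward']}",
        f"out of solvent calibration: {js['out_of_calibration']}",
        f"superstoichiometric: {js['superstoichiometric']}",
        f"hits: {js['hits']} ({js['hit_rate_pct']}%)",
    ]
    if conf:
        lines.append("triage vs planted truth: "
                     + ", ".join(f"{k}={v:.4f}" for k, v in js["confusion"].items()))
    for row in js["kd_table"]:
        lines.append(f"KD {row['compound_id']}: "
                     f"{row['kd_mean_M'] * 1e6:.0f} ± {row['kd_sd_M'] * 1e6:.0f} µM "
                     f"(n={row['n_reps']})")
    for row in js["ic50_table"]:
        lines.append(f"IC50 {row['compound_id']}: {row['ic50_M'] * 1e6:.0f} µM "
                     f"(95% CI {row['ci_lo_M'] * 1e6:.0f}-{row['ci_hi_M'] * 1e6:.0f})")
    if js["screened_total"] == 0:
        lines.append("0 screened")
    return "\n".join(lines) + "\n", js
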