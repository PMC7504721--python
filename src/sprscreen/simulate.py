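"""Synthetic Biacore-style screening data.

Generates 1:1 Langmuir binding cycles with the artifacts a fragment screen
has to cope with — DMSO bulk-refractive-index mismatch with an
excluded-volume offset, baseline drift, Gaussian read noise, slowly
dissociating non-specific ("sticky") binders and superstoichiometric
binders — plus dilution series, whole screening campaigns with planted
ground truth, and ELISA dose-response plates with per-column controls.

Kinetics use the closed-form solution of dR/dt = ka·C·(Rmax − R) − kd·R:

    association:   R(t) = Req · (1 − exp(−(ka·C + kd)·(t − t_start)))
    dissociation:  R(t) = R(t_stop) · exp(−kd·(t − t_stop))

with Req = C · Rmax_theor · n / (C + KD), KD = kd/ka. An ODE integrator is
deliberately not used here; it lives in the test suite as an independent
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .processing import CycleMeta, Sensorgram, SurfaceDef

MICRO = 1e-6


@dataclass(frozen=True)
class KineticModel:
    """1:1 Langmuir rate constants plus binding stoichiometry ``stoich_n``
    (number of analyte molecules per immobilized ligand; > 2 models the
    superstoichiometric behavior the screen excludes)."""

    ka: float  # M^-1 s^-1
    kd_rate: float  # s^-1
    stoich_n: float = 1.0

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd_rate <= 0:
            raise ValueError("rate constants must be positive")
        if self.stoich_n < 0:
            raise ValueError("stoichiometry must be >= 0")

    @property
    def kd_eq(self) -> float:
        """Equilibrium dissociation constant KD = kd/ka in M."""
        return self.kd_rate / self.ka

    @classmethod
    def from_equilibrium(cls, kd_eq: float, kd_rate: float = 1.0, stoich_n: float = 1.0):
        return cls(ka=kd_rate / kd_eq, kd_rate=kd_rate, stoich_n=stoich_n)


@dataclass(frozen=True)
class InjectionSchedule:
    """Cycle timing: 30 s association by default, dissociation long enough
    to place the 10 s post-injection residual report point."""

    t_start: float = 10.0
    t_stop: float = 40.0
    t_dissoc_end: float = 70.0
    hz: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.t_start < self.t_stop < self.t_dissoc_end):
            raise ValueError("need t_start < t_stop < t_dissoc_end")
        if self.hz <= 0:
            raise ValueError("sampling rate must be positive")

    def times(self) -> np.ndarray:
        n = int(round(self.t_dissoc_end * self.hz)) + 1
        return np.arange(n) / self.hz


@dataclass(frozen=True)
class ArtifactModel:
    """Instrument artifacts.

    ``bulk_coeff`` converts DMSO mismatch (actual − nominal, % v/v) into
    the bulk refractive-index jump seen on every surface during the
    injection. ``excl_coeffs`` is the excluded-volume polynomial (constant,
    linear, quadratic in the bulk response) describing the offset the
    active surface retains after reference subtraction — the artifact the
    solvent correction removes.
    """

    dmso_nominal: float = 5.0
    dmso_actual: float = 5.0
    bulk_coeff: float = 100.0  # RU per % v/v mismatch
    excl_coeffs: tuple[float, float, float] = (0.0, 0.012, 2.0e-4)
    drift: float = 0.0  # RU/s, common mode
    noise_sd: float = 0.0  # RU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def bulk_ru(self, dmso_actual: float | None = None) -> float:
        actual = self.dmso_actual if dmso_actual is None else dmso_actual
        return self.bulk_coeff * (actual - self.dmso_nominal)

    def excl_offset(self, bulk: float) -> float:
        c0, c1, c2 = self.excl_coeffs
        return c0 + c1 * bulk + c2 * bulk * bulk


class BinderClass(str, Enum):
    CLEAN = "clean_binder"
    NON_BINDER = "non_binder"
    STICKY = "sticky"
    SUPERSTOICH = "superstoichiometric"


@dataclass(frozen=True)
class CompoundProfile:
    """Ground-truth behavior of one compound in the simulator."""

    compound_id: str
    mw: float
    binder_class: BinderClass = BinderClass.CLEAN
    kinetics: KineticModel | None = None
    residual_ru: float = 0.0  # non-specific sticky amplitude
    sticky_tau_on: float = 3.0  # s
    sticky_tau_off: float = 300.0  # s; >> 10 s so the residual point sees it

    def __post_init__(self) -> None:
        if self.binder_class is BinderClass.STICKY and self.residual_ru <= 0:
            raise ValueError("sticky compounds need residual_ru > 0")


def theoretical_rmax_ru(surface: SurfaceDef, mw: float, n: float = 1.0) -> float:
    """Rmax = immobilization × (MW analyte / MW ligand) × n, in RU."""
    return surface.immobilization * (mw / surface.ligand_mw) * n


def _binding_trace(
    times: np.ndarray, profile: CompoundProfile, conc: float,
    surface: SurfaceDef, schedule: InjectionSchedule,
) -> np.ndarray:
    out = np.zeros_like(times)
    km = profile.kinetics
    if km is None or conc == 0 or surface.immobilization == 0:
        return out
    rmax = theoretical_rmax_ru(surface, profile.mw, n=1.0)
    req = conc * rmax * km.stoich_n / (conc + km.kd_eq)
    kobs = km.ka * conc + km.kd_rate
    assoc = (times >= schedule.t_start) & (times <= schedule.t_stop)
    out[assoc] = req * (1.0 - np.exp(-kobs * (times[assoc] - schedule.t_start)))
    r_stop = req * (1.0 - np.exp(-kobs * (schedule.t_stop - schedule.t_start)))
    dissoc = times > schedule.t_stop
    out[dissoc] = r_stop * np.exp(-km.kd_rate * (times[dissoc] - schedule.t_stop))
    return out


def _sticky_trace(
    times: np.ndarray, profile: CompoundProfile, schedule: InjectionSchedule
) -> np.ndarray:
    out = np.zeros_like(times)
    if profile.residual_ru <= 0:
        return out
    assoc = (times >= schedule.t_start) & (times <= schedule.t_stop)
    out[assoc] = profile.residual_ru * (
        1.0 - np.exp(-(times[assoc] - schedule.t_start) / profile.sticky_tau_on)
    )
    r_stop = profile.residual_ru * (
        1.0 - np.exp(-(schedule.t_stop - schedule.t_start) / profile.sticky_tau_on)
    )
    dissoc = times > schedule.t_stop
    out[dissoc] = r_stop * np.exp(-(times[dissoc] - schedule.t_stop) / profile.sticky_tau_off)
    return out


def simulate_cycle(
    profile: CompoundProfile,
    conc: float,
    surface: SurfaceDef,
    schedule: InjectionSchedule,
    artifacts: ArtifactModel,
    *,
    dmso_actual: float | None = None,
    rng: np.random.Generator | None = None,
    meta: CycleMeta | None = None,
) -> tuple[Sensorgram, Sensorgram]:
    """One injection cycle: (active, reference) traces.

    The reference trace carries bulk, drift and noise only; the active
    trace additionally carries the 1:1 binding response, the sticky
    residual and the excluded-volume offset (present while sample flows).
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(artifacts.seed) if rng is None else rng
    times = schedule.times()
    injection = (times >= schedule.t_start) & (times <= schedule.t_stop)

    bulk = artifacts.bulk_ru(dmso_actual)
    common = artifacts.drift * times + bulk * injection
    reference = common.copy()
    active = common + artifacts.excl_offset(bulk) * injection
    active = active + _binding_trace(times, profile, conc, surface, schedule)
    active = active + _sticky_trace(times, profile, schedule)
    if artifacts.noise_sd > 0:
        active = active + rng.normal(0.0, artifacts.noise_sd, times.size)
        reference = reference + rng.normal(0.0, artifacts.noise_sd, times.size)

    base = meta or CycleMeta()
    dmso = artifacts.dmso_actual if dmso_actual is None else dmso_actual
    meta_a = replace(base, compound_id=profile.compound_id, conc_M=conc,
                     dmso_pct=dmso, role="active", flow_cell=surface.flow_cell)
    meta_r = replace(meta_a, role="reference", flow_cell=1)
    mk = lambda resp, m: Sensorgram(times=times, response=resp,
                                    t_start=schedule.t_start, t_stop=schedule.t_stop, meta=m)
    return mk(active, meta_a), mk(reference, meta_r)


BLANK_PROFILE = CompoundProfile(compound_id="__blank__", mw=100.0,
                                binder_class=BinderClass.NON_BINDER)


def default_concentration_series(top: float = 500 * MICRO, points: int = 7) -> np.ndarray:
    """Two-fold dilution series, ascending; the default 7 points run
    7.8125–500 µM (printed as 7.8–500)."""
    return top / (2.0 ** np.arange(points - 1, -1, -1))


def simulate_dose_series(
    profile: CompoundProfile,
    concentrations: Sequence[float] | None,
    surface: SurfaceDef,
    schedule: InjectionSchedule,
    artifacts: ArtifactModel,
    replicates: int = 3,
    seed: int | None = None,
) -> list[list[tuple[Sensorgram, Sensorgram]]]:
    """Replicate dilution-series cycle sets with independent noise per
    replicate. Returns ``[replicate][concentration] -> (active, reference)``."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    concs = (default_concentration_series() if concentrations is None
             else np.asarray(list(concentrations), dtype=float))
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(artifacts.seed if seed is None else seed)
    out = []
    for rep in range(replicates):
        cycles = []
        for i, conc in enumerate(concs):
            meta = CycleMeta(cycle=rep * len(concs) + i + 1)
            cycles.append(simulate_cycle(profile, float(conc), surface, schedule,
                                         artifacts, rng=rng, meta=meta))
        out.append(cycles)
    return out


# -- whole campaigns ----------------------------------------------------------

@dataclass
class CycleRecord:
    meta: CycleMeta
    active: Sensorgram
    reference: Sensorgram


@dataclass
class Campaign:
    """A simulated screen: all cycles (clean-screen stage over a bare
    surface, then binding stage over the ligand surface, with solvent
    calibration and blank cycles interleaved) plus planted ground truth."""

    cycles: list[CycleRecord]
    truth: pd.DataFrame
    surface: SurfaceDef
    blank_surface: SurfaceDef
    schedule: InjectionSchedule
    screen_conc: float

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.cycles:
            for role, s in (("active", rec.active), ("reference", rec.reference)):
                rows.append(pd.DataFrame({
                    "cycle": rec.meta.cycle, "flow_cell": s.meta.flow_cell,
                    "role": role, "time_s": s.times, "response_RU": s.response,
                }))
        return pd.concat(rows, ignore_index=True)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "cycle": r.meta.cycle, "compound_id": r.meta.compound_id,
            "conc_M": r.meta.conc_M, "dmso_pct": r.meta.dmso_pct,
            "stage": r.meta.stage, "is_calibration": r.meta.is_calibration,
            "is_blank": r.meta.is_blank,
        } for r in self.cycles])


DEFAULT_CLASS_FRACTIONS: Mapping[str, float] = {
    "clean_binder": 0.05,
    "non_binder": 0.80,
    "sticky": 0.10,
    "superstoichiometric": 0.05,
}


@dataclass(frozen=True)
class CampaignDesign:
    """Study-condition knobs for a simulated screen. The defaults mirror a
    single-concentration fragment screen at 500 µM with DMSO calibration
    every 50 cycles over a 4–5.5% (v/v) solvent range."""

    screen_conc: float = 500 * MICRO
    calibration_every: int = 50
    calibration_dmso: tuple[float, ...] = tuple(np.linspace(4.0, 5.5, 7))
    dmso_jitter_sd: float = 0.15  # % v/v spread of per-cycle mismatch
    clean_kd_range: tuple[float, float] = (50 * MICRO, 250 * MICRO)
    superstoich_kd_range: tuple[float, float] = (10 * MICRO, 60 * MICRO)
    superstoich_n_range: tuple[float, float] = (2.5, 4.0)
    sticky_residual_range: tuple[float, float] = (8.0, 15.0)
    kd_rate_range: tuple[float, float] = (0.5, 2.0)  # s^-1; fast dissociation


def _assign_classes(n: int, fractions: Mapping[str, float],
                    rng: np.random.Generator) -> list[BinderClass]:
    keys = [BinderClass(k) for k in fractions]
    fracs = np.array([fractions[k.value] for k in keys], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    counts = np.floor(fracs * n).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    rem = n - counts.sum()
    order = np.argsort(-(fracs * n - counts))
    for i in range(rem):
        counts[order[i % len(keys)]] += 1
    labels = [k for k, c in zip(keys, counts) for _ in range(int(c))]
    rng.shuffle(labels)
    return labels


def _profile_for(cid: str, mw: float, cls: BinderClass, design: CampaignDesign,
                 rng: np.random.Generator) -> CompoundProfile:
    def log_uniform(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    kd_rate = float(rng.uniform(*design.kd_rate_range))
    if cls is BinderClass.CLEAN:
        km = KineticModel.from_equilibrium(log_uniform(*design.clean_kd_range), kd_rate)
        return CompoundProfile(cid, mw, cls, km)
    if cls is BinderClass.SUPERSTOICH:
        km = KineticModel.from_equilibrium(
            log_uniform(*design.superstoich_kd_range), kd_rate,
            stoich_n=float(rng.uniform(*design.superstoich_n_range)))
        return CompoundProfile(cid, mw, cls, km)
    if cls is BinderClass.STICKY:
        return CompoundProfile(cid, mw, cls, None,
                               residual_ru=float(rng.uniform(*design.sticky_residual_range)))
    return CompoundProfile(cid, mw, cls, None)


def _expected_labels(profile: CompoundProfile, design: CampaignDesign,
                     surface: SurfaceDef, schedule: InjectionSchedule) -> dict:
    """Noise-free expectations used as ground truth for triage testing."""
    c = design.screen_conc
    rmax1 = theoretical_rmax_ru(surface, profile.mw, 1.0)
    # residual at +10 s on a bare surface
    sticky_stop = 0.0
    if profile.residual_ru > 0:
        sticky_stop = profile.residual_ru * (
            1 - np.exp(-(schedule.t_stop - schedule.t_start) / profile.sticky_tau_on))
        sticky_stop *= np.exp(-10.0 / profile.sticky_tau_off)
    clean_fail = sticky_stop > 5.0
    km = profile.kinetics
    resp = 0.0 if km is None else c * rmax1 * km.stoich_n / (c + km.kd_eq)
    superstoich = resp > 2.0 * rmax1
    hit = (not clean_fail) and (not superstoich) and resp >= 0.60 * rmax1
    return {
        "binder_class": profile.binder_class.value,
        "kd_eq_M": np.nan if km is None else km.kd_eq,
        "stoich_n": np.nan if km is None else km.stoich_n,
        "residual_ru": profile.residual_ru,
        "expected_response_RU": resp,
        "expected_clean_fail": clean_fail,
        "expected_superstoich": superstoich,
        "expected_hit": hit,
    }


def simulate_campaign(
    library: Sequence,
    surface: SurfaceDef,
    artifacts: ArtifactModel,
    *,
    class_fractions: Mapping[str, float] = DEFAULT_CLASS_FRACTIONS,
    design: CampaignDesign = CampaignDesign(),
    schedule: InjectionSchedule = InjectionSchedule(),
    seed: int | None = None,
) -> Campaign:
    """Simulate a single-concentration screen over ``library``.

    Every compound receives a clean-screen cycle on a bare surface and a
    binding cycle on the ligand surface. Solvent-calibration cycle sets
    and a buffer blank are inserted at the start of each stage and every
    ``design.calibration_every`` cycles. Ground-truth class labels and the
    noise-free expected outcomes are returned for confusion-matrix tests.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    rng = np.random.default_rng(artifacts.seed if seed is None else seed)
    classes = _assign_classes(len(library), class_fractions, rng)
    profiles = [_profile_for(c.id, c.mw, cls, design, rng)
                for c, cls in zip(library, classes)]

    blank_surface = SurfaceDef(name="blank", ligand_mw=surface.ligand_mw,
                               immobilization=0.0, flow_cell=surface.flow_cell,
                               is_reference=True)
    cycles: list[CycleRecord] = []
    counter = 0

    def add(profile, conc, surf, *, dmso=None, stage="binding",
            is_calibration=False, is_blank=False):
        nonlocal counter
        counter += 1
        meta = CycleMeta(cycle=counter, stage=stage,
                         is_calibration=is_calibration, is_blank=is_blank)
        if dmso is None:
            dmso = artifacts.dmso_nominal + rng.normal(0.0, design.dmso_jitter_sd)
        a, r = simulate_cycle(profile, conc, surf, schedule, artifacts,
                              dmso_actual=float(dmso), rng=rng, meta=meta)
        a.meta = replace(a.meta, cycle=counter, stage=stage,
                         is_calibration=is_calibration, is_blank=is_blank)
        r.meta = replace(r.meta, cycle=counter, stage=stage,
                         is_calibration=is_calibration, is_blank=is_blank)
        cycles.append(CycleRecord(meta=a.meta, active=a, reference=r))

    def calibration_block(surf, stage):
        for d in design.calibration_dmso:
            add(BLANK_PROFILE, 0.0, surf, dmso=d, stage=stage, is_calibration=True)
        add(BLANK_PROFILE, 0.0, surf, dmso=artifacts.dmso_nominal,
            stage=stage, is_blank=True)

    for stage, surf in (("clean", blank_surface), ("binding", surface)):
        for i, profile in enumerate(profiles):
            if i % design.calibration_every == 0:
                calibration_block(surf, stage)
            add(profile, design.screen_conc, surf, stage=stage)
        calibration_block(surf, stage)

    truth = pd.DataFrame(
        [{"compound_id": p.compound_id,
          **_expected_labels(p, design, surface, schedule)} for p in profiles]
    )
    return Campaign(cycles=cycles, truth=truth, surface=surface,
                    blank_surface=blank_surface, schedule=schedule,
                    screen_conc=design.screen_conc)


# -- ELISA plates -------------------------------------------------------------

def inhibition_fraction(conc: float | np.ndarray, ic50: float, hill: float = 1.0):
    """Fractional inhibition C^h / (C^h + IC50^h); 0 at C=0, 1 as C→∞."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        frac = np.where(c > 0, c ** hill / (c ** hill + ic50 ** hill), 0.0)
    return frac if frac.shape else float(frac)


def simulate_elisa_plate(
    ic50: float,
    hill: float = 1.0,
    concentrations: Sequence[float] | None = None,
    replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
    *,
    compound_id: str = "CMP",
    pos_absorbance: float = 2.0,
    neg_absorbance: float = 0.08,
    controls_per_column: int = 1,
) -> pd.DataFrame:
    """Dose-response ELISA plate with per-column positive (full activity)
    and negative (no serum) controls and multiplicative read noise.

    Well signal: A = neg + (pos − neg) · (1 − inhibition(C)).
    Columns are concentrations; rows are replicate wells plus controls.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    concs = (default_concentration_series() if concentrations is None
             else np.asarray(list(concentrations), dtype=float))
    rng = np.random.default_rng(seed)
    rows = []
    for col, conc in enumerate(concs, start=1):
        signal = neg_absorbance + (pos_absorbance - neg_absorbance) * (
            1.0 - inhibition_fraction(conc, ic50, hill))
        wells = ([("sample", signal, conc)] * replicates
                 + [("positive_control", pos_absorbance, 0.0)] * controls_per_column
                 + [("negative_control", neg_absorbance, 0.0)] * controls_per_column)
        for rownum, (role, mean_a, c) in enumerate(wells, start=1):
            a = mean_a * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv > 0 else mean_a
            rows.append({
                "plate": 1, "well": f"{chr(64 + rownum)}{col}", "row": rownum,
                "col": col, "role": role,
                "compound_id": compound_id if role == "sample" else None,
                "conc_M": c, "absorbance": a,
            })
    return pd.DataFrame(rows)
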