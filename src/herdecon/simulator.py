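"""Stochastic weekly-step dairy-herd model.

The engine keeps the whole herd (and all Monte-Carlo replicates) in
flat numpy arrays indexed ``(replicate, animal slot)`` and advances one
week at a time. Every stochastic event is a monotone threshold test of
one uniform draw, and the shapes and order of draws per week are fixed,
so two runs with the same seed but different parameters share their
randomness replicate-by-replicate (common random numbers with monotone
coupling) — the property the paired-scenario design relies on.

Time grid: 52 whole weeks per simulated year, 40-week gestation,
7-week dry period. Annual incidences I (per 100 cow-years) become
weekly onset hazards ``h = r / (1 - r (d - 1))`` with ``r = (I/100)/52``
and episode length ``d``; a cow cannot start a second episode of the
same disease while one is active, and the correction keeps the expected
calendar case rate exactly ``r`` per cow-week (renewal argument).
Dystocia is drawn at calving with probability ``(I/100) / c`` where
``c`` estimates calvings per cow-year.

Replacement policy: all heifer calves are reared; a heifer calving for
the first time enters the herd if the cow count is below target and is
otherwise sold as a pregnant heifer; cows still open at 300 days in
milk are marked do-not-breed and culled at the end of lactation.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .config_io import DISEASES, HerdParameters
from .errors import SimulationError, ValidationError

log = logging.getLogger(__name__)

WEEKS_PER_YEAR = 52
GESTATION_WEEKS = 40
DRY_WEEKS = 7
DRY_OFF_PREG_WEEK = GESTATION_WEEKS - DRY_WEEKS  # dry when >= 33 weeks pregnant
OESTRUS_WEEKLY_P = 1.0 / 3.0  # 21-day cycle on a weekly grid
DNB_WEEK = 43  # open beyond ~300 d in milk -> do-not-breed
DNB_CULL_WEEK = 46  # do-not-breed cows culled at end of lactation
OPEN_HEIFER_SALE_WEEKS = 96  # heifers still open at ~22 months are sold
EARLY_WINDOW = (1, 2)  # rearing weeks ~ 3-14 d postpartum
LATE_WINDOW = (27, 65)  # rearing weeks ~ 189-458 d postpartum
DAYS_PER_SIM_YEAR = 7.0 * WEEKS_PER_YEAR
WEEKS_PER_MONTH = DAYS_PER_SIM_YEAR / 12.0 / 7.0

_DIS_INDEX = {d: i for i, d in enumerate(DISEASES)}
_DYS = _DIS_INDEX["dystocia"]
_WEEKLY_IDX = np.array([i for d, i in _DIS_INDEX.items() if d != "dystocia"])

# Wood-type lactation curve shape on a weekly grid: w^b * exp(-c w).
_WOOD_B = 0.25
_WOOD_C = 0.03
_MAX_WIM = 200
_BAND = 0.18  # uniform-band width per weekly disease (caps hazard at 0.18)


# ---------------------------------------------------------------------------
# lactation curve


def _wood_shape(weeks: np.ndarray) -> np.ndarray:
    w = np.asarray(weeks, dtype=float)
    return np.where(w >= 1, np.power(np.maximum(w, 1e-9), _WOOD_B) * np.exp(-_WOOD_C * w), 0.0)


def _wood_305d_norm() -> float:
    # 305 d = 43 full weeks + 4 days of week 44
    full = _wood_shape(np.arange(1, 44)).sum()
    return float(full + (4.0 / 7.0) * _wood_shape(np.array([44.0]))[0])


_WOOD_NORM = _wood_305d_norm()


def lactation_yield(parity_class, week_in_milk: int, params: HerdParameters) -> float:
    """kg ECM produced in one week of lactation.

    The Wood curve ``w^0.25 exp(-0.03 w)`` is scaled so the cumulative
    yield over 305 days equals the parity-class 305-d ECM. Yield is zero
    before calving week 1 and after dry-off (handled by the caller).
    """
    cls = str(parity_class)
    if cls not in params.ecm_305d:
        raise ValueError(f"unknown parity class {parity_class!r}; expected 1, 2 or 3+")
    if week_in_milk < 0:
        raise ValueError("week_in_milk must be >= 0")
    if week_in_milk == 0:
        return 0.0
    scale = float(params.ecm_305d[cls]) / _WOOD_NORM
    return float(scale * _wood_shape(np.array([week_in_milk]))[0])


# ---------------------------------------------------------------------------
# reproduction calibration


def _truncated_geometric_mean(p: float, max_weeks: int) -> float:
    k = np.arange(1, max_weeks + 1)
    pmf = p * (1.0 - p) ** (k - 1)
    total = pmf.sum()
    if total <= 0:
        return float(max_weeks)
    return float((k * pmf).sum() / total)


def _solve_weekly_conception(target_mean_weeks: float, max_weeks: int) -> float:
    """Weekly conception probability whose truncated-geometric mean wait
    (successes within ``max_weeks``) equals the target."""
    lo, hi = 1e-5, 0.999999
    top = _truncated_geometric_mean(lo, max_weeks)
    if target_mean_weeks >= top:
        log.warning(
            "target wait %.1f weeks unattainable within %d weeks; clamping",
            target_mean_weeks,
            max_weeks,
        )
        return lo
    if target_mean_weeks <= 1.0:
        return hi
    return float(
        brentq(
            lambda p: _truncated_geometric_mean(p, max_weeks) - target_mean_weeks,
            lo,
            hi,
            xtol=1e-10,
        )
    )


def compute_repro_calibration(params: HerdParameters) -> tuple[float, float]:
    """Solve the (oestrus_scale_cows, heifer_breeding_start_weeks) pair
    that reproduces the calibrated calving interval and age at first
    calving under the weekly oestrus/insemination model.

    The cow-side scale multiplies the detection probability so that the
    mean *completed* calving interval (conceptions before the
    do-not-breed limit) matches ``calving_interval_days``; completed
    intervals are what herd recording reports.
    """
    first_week = max(1, math.ceil(params.start_breeding_days / 7.0))
    window = max(1, DNB_WEEK - first_week)
    target_wait = params.calving_interval_days / 7.0 - GESTATION_WEEKS - (first_week - 1)
    w = _solve_weekly_conception(target_wait, window)
    base = OESTRUS_WEEKLY_P * params.heat_obs_rate_cows * params.conception_rate_cows
    scale = w / base if base > 0 else 0.0
    if scale * params.heat_obs_rate_cows > 1.0:
        log.warning("oestrus detection scale clamps detection probability at 1")
        scale = 1.0 / params.heat_obs_rate_cows

    p_h = (
        OESTRUS_WEEKLY_P
        * params.heat_obs_rate_heifers
        * params.conception_rate_heifers
    )
    afc_weeks = params.age_first_calving_months * WEEKS_PER_MONTH
    wait_h = 1.0 / p_h if p_h > 0 else afc_weeks
    start_h = max(26.0, afc_weeks - (GESTATION_WEEKS - 1) - wait_h)
    return float(scale), float(start_h)


# ---------------------------------------------------------------------------
# derived simulation constants


@dataclass(frozen=True)
class _Derived:
    wood_tab: np.ndarray  # (3, _MAX_WIM+1) weekly kg by parity class
    ecm305: np.ndarray  # (3,)
    first_breed_week: int
    p_det_cows: float
    cr_cows: float
    p_det_heifers: float
    cr_heifers: float
    heifer_start_week: float
    hazard: np.ndarray  # (6,), dystocia slot 0
    dys_per_calving: float
    sb_base: float
    sb_add_dys: float
    mort_week: float
    add_mort_week: np.ndarray  # (6,)
    add_cull_week: np.ndarray  # (6,)
    dys_calving_mort: float
    cm: np.ndarray  # (6,) conception multipliers
    loss_rate: np.ndarray  # (6,) fraction of 305-d ECM lost per episode week
    dur: np.ndarray  # (6,) int
    h_mort_tab: np.ndarray  # weekly death probability by heifer age
    maint_wk: float
    sfu_per_kg: float
    heifer_sfu_wk: float
    powder_wk: float
    milk_weeks: int
    live_wt: float
    target: int

    @classmethod
    def from_params(cls, params: HerdParameters) -> "_Derived":
        ecm = np.array([params.ecm_305d[c] for c in ("1", "2", "3+")], dtype=float)
        weeks = np.arange(_MAX_WIM + 1, dtype=float)
        wood = (ecm[:, None] / _WOOD_NORM) * _wood_shape(weeks)[None, :]

        if params.oestrus_scale_cows is None or params.heifer_breeding_start_weeks is None:
            scale, start_h = compute_repro_calibration(params)
        else:
            scale, start_h = params.oestrus_scale_cows, params.heifer_breeding_start_weeks
        if params.oestrus_scale_cows is not None:
            scale = params.oestrus_scale_cows
        if params.heifer_breeding_start_weeks is not None:
            start_h = params.heifer_breeding_start_weeks

        dur = np.array(
            [params.disease_effects[d].effect_duration_weeks for d in DISEASES], dtype=int
        )
        cm = np.array(
            [params.disease_effects[d].conception_multiplier for d in DISEASES], dtype=float
        )
        loss_frac = np.array(
            [params.disease_effects[d].milk_loss_frac_of_305d for d in DISEASES], dtype=float
        )
        add_mort = np.array(
            [params.disease_effects[d].added_mortality_risk for d in DISEASES], dtype=float
        )
        add_cull = np.array(
            [params.disease_effects[d].added_cull_risk for d in DISEASES], dtype=float
        )

        hazard = np.zeros(len(DISEASES))
        for d, i in _DIS_INDEX.items():
            if d == "dystocia":
                continue
            r = (params.incidence_per_100cy[d] / 100.0) / WEEKS_PER_YEAR
            denom = 1.0 - r * (dur[i] - 1)
            hazard[i] = r / denom if denom > 0 else r

        # calvings per cow-year (renewal estimate) for the dystocia draw
        first_week = max(1, math.ceil(params.start_breeding_days / 7.0))
        base = OESTRUS_WEEKLY_P * params.heat_obs_rate_cows * scale * params.conception_rate_cows
        w = min(base, 1.0)
        p_fail = (1.0 - w) ** max(1, DNB_WEEK - first_week)
        cycle_ok = params.calving_interval_days / DAYS_PER_SIM_YEAR
        cycle_fail = DNB_CULL_WEEK / WEEKS_PER_YEAR
        e_len = (1.0 - p_fail) * cycle_ok + p_fail * cycle_fail
        m_yr = params.cow_mortality / 100.0 + sum(
            (params.incidence_per_100cy[d] / 100.0)
            * (params.disease_effects[d].added_cull_risk + params.disease_effects[d].added_mortality_risk)
            / 100.0
            for d in DISEASES
            if d != "dystocia"
        )
        e_cycle = e_len * (1.0 - 0.5 * m_yr * e_len)
        c_hat = 1.0 / e_cycle if e_cycle > 0 else 1.0
        dys_eff = params.disease_effects["dystocia"]
        dys_p = min(1.0, (params.incidence_per_100cy["dystocia"] / 100.0) / c_hat)
        sb_base = max(0.0, params.stillbirth_rate / 100.0 - dys_p * dys_eff.stillbirth_risk_add / 100.0)

        add_mort_week = (add_mort / 100.0) / dur
        add_mort_week[_DYS] = 0.0  # applied once at calving instead
        add_cull_week = (add_cull / 100.0) / dur

        max_age = OPEN_HEIFER_SALE_WEEKS + GESTATION_WEEKS + 8
        h_mort = np.zeros(max_age + 1, dtype=np.float32)
        n_early = EARLY_WINDOW[1] - EARLY_WINDOW[0] + 1
        n_late = LATE_WINDOW[1] - LATE_WINDOW[0] + 1
        h_mort[EARLY_WINDOW[0] : EARLY_WINDOW[1] + 1] = 1.0 - (
            1.0 - params.early_calf_mortality / 100.0
        ) ** (1.0 / n_early)
        h_mort[LATE_WINDOW[0] : LATE_WINDOW[1] + 1] = 1.0 - (
            1.0 - params.late_calf_mortality / 100.0
        ) ** (1.0 / n_late)

        fm = params.feed_model
        return cls(
            wood_tab=wood,
            ecm305=ecm,
            first_breed_week=first_week,
            p_det_cows=min(1.0, OESTRUS_WEEKLY_P * params.heat_obs_rate_cows * scale),
            cr_cows=params.conception_rate_cows,
            p_det_heifers=OESTRUS_WEEKLY_P * params.heat_obs_rate_heifers,
            cr_heifers=params.conception_rate_heifers,
            heifer_start_week=start_h,
            hazard=hazard,
            dys_per_calving=dys_p,
            sb_base=sb_base,
            sb_add_dys=dys_eff.stillbirth_risk_add / 100.0,
            mort_week=(params.cow_mortality / 100.0) / WEEKS_PER_YEAR,
            add_mort_week=add_mort_week,
            add_cull_week=add_cull_week,
            dys_calving_mort=dys_eff.added_mortality_risk / 100.0,
            cm=cm,
            loss_rate=loss_frac / dur,
            dur=dur,
            h_mort_tab=h_mort,
            maint_wk=7.0 * fm.maintenance_sfu_per_day,
            sfu_per_kg=fm.sfu_per_kg_ecm,
            heifer_sfu_wk=7.0 * fm.heifer_sfu_per_day,
            powder_wk=7.0 * fm.calf_milk_powder_kg_per_day,
            milk_weeks=fm.milk_feeding_weeks,
            live_wt=params.cow_live_weight_kg,
            target=int(params.herd_size_target),
        )


# ---------------------------------------------------------------------------
# per-animal views (used by tests and the single-cow API)


@dataclass
class CowState:
    """Per-cow view of the state arrays."""

    animal_id: tuple[int, int]  # (replicate, slot)
    parity: int
    week_in_milk: int
    repro_status: str  # open | pregnant | do-not-breed
    weeks_pregnant: int
    active_diseases: set = field(default_factory=set)  # {(disease, weeks_remaining)}
    alive: bool = True


@dataclass
class HeiferState:
    animal_id: tuple[int, int]
    age_weeks: int
    repro_status: str
    weeks_pregnant: int
    alive: bool = True


# ---------------------------------------------------------------------------
# herd state


_COUNT_FIELDS = (
    "cow_weeks",
    "heifer_weeks",
    "kg_ecm",
    "calvings",
    "stillbirths",
    "live_calves_female",
    "live_calves_male",
    "calf_deaths_early",
    "calf_deaths_late",
    "cow_deaths",
    "cows_slaughtered",
    "heifers_sold_pregnant",
    "heifers_sold_open",
    "heifers_slaughtered",
    "inseminations_cows",
    "inseminations_heifers",
    "conceptions_cows",
    "conceptions_heifers",
    "oestrus_events_cows",
    "oestrus_events_heifers",
    "first_calvings",
    "feed_sfu_cows",
    "feed_sfu_heifers",
    "milk_powder_kg",
    "ci_sum_days",
    "ci_count",
)


class HerdState:
    """Vectorized herd state for a batch of replicates."""

    def __init__(self, params: HerdParameters, n_replicates: int = 1):
        self.params = params
        self.derived = _Derived.from_params(params)
        R = int(n_replicates)
        target = int(params.herd_size_target)
        # admissions only fill up to target, so the cow pool never grows
        C = target + 8
        H = int(target * 1.7) + 24
        self.R, self.C, self.H = R, C, H
        self.c_active = np.zeros((R, C), dtype=bool)
        self.c_parity = np.zeros((R, C), dtype=np.int16)
        self.c_wim = np.zeros((R, C), dtype=np.int16)
        self.c_preg = np.zeros((R, C), dtype=np.int16)
        self.c_dnb = np.zeros((R, C), dtype=bool)
        self.c_dis = np.zeros((len(DISEASES), R, C), dtype=np.int16)
        self.h_active = np.zeros((R, H), dtype=bool)
        self.h_age = np.zeros((R, H), dtype=np.int16)
        self.h_preg = np.zeros((R, H), dtype=np.int16)
        self.week = 0
        self.acc = {k: np.zeros(R) for k in _COUNT_FIELDS}
        self.acc["disease_cases"] = np.zeros((R, len(DISEASES)))

    # -- construction -----------------------------------------------------

    @classmethod
    def initialize(cls, params: HerdParameters, n_replicates: int, rng: np.random.Generator):
        """Steady-state-like start: target cows with parity distribution
        0.35/0.27/0.38, uniform lactation stage, reproduction status
        consistent with the breeding calendar; 85% of target as heifers
        of uniform age. Burn-in removes any residual initialization
        effect."""
        st = cls(params, n_replicates)
        dv = st.derived
        R, target = st.R, dv.target
        n = target
        st.c_active[:, :n] = True
        st.c_parity[:, :n] = rng.choice(
            [1, 2, 3], size=(R, n), p=[0.35, 0.27, 0.38]
        ).astype(np.int16)
        wim = rng.integers(1, 46, size=(R, n))
        w = dv.p_det_cows * dv.cr_cows
        wait = rng.geometric(min(max(w, 1e-6), 1.0), size=(R, n))
        conc_week = dv.first_breed_week - 1 + wait
        preg = np.clip(wim - conc_week, 0, GESTATION_WEEKS - 1)
        st.c_wim[:, :n] = wim
        st.c_preg[:, :n] = preg
        nh = int(0.85 * target)
        st.h_active[:, :nh] = True
        max_age = int(dv.heifer_start_week + 20)
        age = rng.integers(1, max_age, size=(R, nh))
        wait_h = rng.geometric(min(max(dv.p_det_heifers * dv.cr_heifers, 1e-6), 1.0), size=(R, nh))
        conc_age = dv.heifer_start_week - 1 + wait_h
        st.h_age[:, :nh] = age
        st.h_preg[:, :nh] = np.clip(age - conc_age, 0, GESTATION_WEEKS - 1)
        return st

    # -- per-animal access (tests / debugging) ----------------------------

    def cow(self, rep: int, slot: int) -> CowState:
        status = (
            "pregnant"
            if self.c_preg[rep, slot] > 0
            else "do-not-breed"
            if self.c_dnb[rep, slot]
            else "open"
        )
        active = {
            (DISEASES[i], int(w))
            for i, w in enumerate(self.c_dis[:, rep, slot])
            if w > 0
        }
        return CowState(
            animal_id=(rep, slot),
            parity=int(self.c_parity[rep, slot]),
            week_in_milk=int(self.c_wim[rep, slot]),
            repro_status=status,
            weeks_pregnant=int(self.c_preg[rep, slot]),
            active_diseases=active,
            alive=bool(self.c_active[rep, slot]),
        )

    def add_cow(self, cow: CowState) -> None:
        rep, slot = cow.animal_id
        self.c_active[rep, slot] = cow.alive
        self.c_parity[rep, slot] = cow.parity
        self.c_wim[rep, slot] = cow.week_in_milk
        self.c_preg[rep, slot] = cow.weeks_pregnant
        self.c_dnb[rep, slot] = cow.repro_status == "do-not-breed"
        for disease, weeks in cow.active_diseases:
            self.c_dis[_DIS_INDEX[disease], rep, slot] = weeks

    def add_heifer(self, heifer: HeiferState) -> None:
        rep, slot = heifer.animal_id
        self.h_active[rep, slot] = heifer.alive
        self.h_age[rep, slot] = heifer.age_weeks
        self.h_preg[rep, slot] = heifer.weeks_pregnant

    def cow_counts(self) -> np.ndarray:
        return self.c_active.sum(axis=1)


# ---------------------------------------------------------------------------
# weekly step


def _weekly_draws(rng: np.random.Generator, R: int, C: int, H: int) -> dict:
    """One week of uniforms, fixed shapes and order (the CRN contract)."""
    n_cow = R * C
    n_h = R * H
    flat = rng.random(n_cow * 4 + n_h * 3, dtype=np.float32)
    sizes = {
        "cow_repro": (n_cow, (R, C)),
        "cow_calv": (n_cow, (R, C)),
        "cow_dis": (n_cow, (R, C)),
        "cow_exit": (n_cow, (R, C)),
        "h_repro": (n_h, (R, H)),
        "h_calv": (n_h, (R, H)),
        "h_exit": (n_h, (R, H)),
    }
    out, pos = {}, 0
    for name, (n, shape) in sizes.items():
        out[name] = flat[pos : pos + n].reshape(shape)
        pos += n
    return out


def _conditional_uniform(u: np.ndarray, event: np.ndarray, p) -> np.ndarray:
    """Transform u ~ U(0,1) into a fresh uniform independent of the
    threshold event {u < p}. Events are assumed sparse: the non-event
    branch is computed densely and event entries are patched."""
    p = np.asarray(p, dtype=np.float32)
    safe_p = np.maximum(p, np.float32(1e-9))
    safe_q = np.maximum(1.0 - p, np.float32(1e-9))
    v = (u - p) / safe_q
    idx = np.nonzero(event)
    pe = safe_p[idx] if p.ndim else safe_p
    v[idx] = u[idx] / pe
    return v


def _take_first_k(mask: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Per-row: the first k[r] True positions of mask[r]."""
    order = np.cumsum(mask, axis=1, dtype=np.int32)
    return mask & (order <= k[:, None])


def _count(mask: np.ndarray) -> np.ndarray:
    return np.count_nonzero(mask, axis=1)


def _step_impl(st: HerdState, dr: Mapping[str, np.ndarray]) -> None:
    dv = st.derived
    acc = st.acc
    c_active, c_parity, c_wim, c_preg = st.c_active, st.c_parity, st.c_wim, st.c_preg
    c_dnb, c_dis = st.c_dnb, st.c_dis
    h_active, h_age, h_preg = st.h_active, st.h_age, st.h_preg

    n_cows = _count(c_active)
    n_heifers = _count(h_active)
    acc["cow_weeks"] += n_cows
    acc["heifer_weeks"] += n_heifers

    # 1. lactation yield (net of disease milk losses); dry when heavily
    #    pregnant
    cls = (np.minimum(c_parity, 3) - 1).astype(np.intp)
    ecm_by_cow = dv.ecm305[cls]
    base = dv.wood_tab[cls, np.minimum(c_wim, _MAX_WIM)]
    ep = c_dis > 0  # per-disease episode masks, fixed for this week
    loss_frac = np.zeros(base.shape, dtype=np.float32)
    for i in range(len(DISEASES)):
        if dv.loss_rate[i] > 0:
            loss_frac += np.float32(dv.loss_rate[i]) * ep[i]
    milking = c_active & (c_wim >= 1) & (c_preg < DRY_OFF_PREG_WEEK)
    y = np.where(milking, np.maximum(base - loss_frac * ecm_by_cow, 0.0), 0.0)
    kg_week = y.sum(axis=1)
    acc["kg_ecm"] += kg_week

    # 2. feed energy
    acc["feed_sfu_cows"] += dv.maint_wk * n_cows + dv.sfu_per_kg * kg_week
    acc["feed_sfu_heifers"] += n_heifers * dv.heifer_sfu_wk
    acc["milk_powder_kg"] += _count(h_active & (h_age < dv.milk_weeks)) * dv.powder_wk

    # 3. oestrus, insemination, conception (cows); nested thresholds on
    #    one uniform: conceive < inseminate < oestrus
    elig = c_active & (c_preg == 0) & ~c_dnb & (c_wim >= dv.first_breed_week)
    p_conc = np.full(elig.shape, np.float32(dv.p_det_cows * dv.cr_cows), dtype=np.float32)
    for i in range(len(DISEASES)):
        if dv.cm[i] < 1.0:
            p_conc *= np.where(ep[i], np.float32(dv.cm[i]), np.float32(1.0))
    u = dr["cow_repro"]
    oest = elig & (u < OESTRUS_WEEKLY_P)
    ins = elig & (u < dv.p_det_cows)
    conc = elig & (u < p_conc)
    acc["oestrus_events_cows"] += _count(oest)
    acc["inseminations_cows"] += _count(ins)
    acc["conceptions_cows"] += _count(conc)
    c_dnb |= c_active & (c_preg == 0) & ~conc & (c_wim >= DNB_WEEK)

    # 4. gestation advance and calving
    c_preg += c_preg > 0
    calv = c_active & (c_preg >= GESTATION_WEEKS)
    c_preg[conc] = 1

    acc["calvings"] += _count(calv)
    acc["ci_sum_days"] += 7.0 * (c_wim * calv).sum(axis=1)
    acc["ci_count"] += _count(calv)  # all cow-slot calvings are re-calvings

    u = dr["cow_calv"]
    dys = calv & (u < dv.dys_per_calving)
    v = _conditional_uniform(u, dys, dv.dys_per_calving)
    p_sb = np.full(u.shape, np.float32(dv.sb_base), dtype=np.float32)
    p_sb[dys] = np.float32(dv.sb_base + dv.sb_add_dys)
    sb = calv & (v < p_sb)
    w_u = _conditional_uniform(v, sb, p_sb)
    live = calv & ~sb
    female = live & (w_u < 0.5)
    acc["stillbirths"] += _count(sb)
    acc["live_calves_female"] += _count(female)
    acc["live_calves_male"] += _count(live & ~female)
    acc["disease_cases"][:, _DYS] += _count(dys)
    c_dis[_DYS][dys] = dv.dur[_DYS]
    calv_mort_bump = np.float32(dv.dys_calving_mort) * dys
    c_parity[calv] += 1
    c_wim[calv] = 0
    c_preg[calv] = 0

    # newborn heifer calves enter the rearing pool
    n_female = _count(female)
    free_h = ~h_active
    if np.any(_count(free_h) < n_female):
        raise SimulationError("heifer slot pool exhausted; raise slot capacity")
    born_slots = _take_first_k(free_h, n_female)
    h_active |= born_slots
    h_age[born_slots] = 0
    h_preg[born_slots] = 0

    # 5. heifer breeding, gestation, first calving (entry or sale)
    h_elig = h_active & (h_preg == 0) & (h_age >= dv.heifer_start_week)
    uh = dr["h_repro"]
    h_oest = h_elig & (uh < OESTRUS_WEEKLY_P)
    h_ins = h_elig & (uh < dv.p_det_heifers)
    h_conc = h_elig & (uh < dv.p_det_heifers * dv.cr_heifers)
    acc["oestrus_events_heifers"] += _count(h_oest)
    acc["inseminations_heifers"] += _count(h_ins)
    acc["conceptions_heifers"] += _count(h_conc)
    h_preg += h_preg > 0
    h_calv = h_active & (h_preg >= GESTATION_WEEKS)
    h_preg[h_conc] = 1

    deficit = np.maximum(dv.target - _count(c_active), 0)
    admit = _take_first_k(h_calv, deficit)
    sold_preg = h_calv & ~admit
    acc["heifers_sold_pregnant"] += _count(sold_preg)

    # calving draws for admitted heifers (they calve as they enter)
    uhc = dr["h_calv"]
    h_dys = admit & (uhc < dv.dys_per_calving)
    vh = _conditional_uniform(uhc, h_dys, dv.dys_per_calving)
    p_sb_h = np.full(uhc.shape, np.float32(dv.sb_base), dtype=np.float32)
    p_sb_h[h_dys] = np.float32(dv.sb_base + dv.sb_add_dys)
    h_sb = admit & (vh < p_sb_h)
    wh = _conditional_uniform(vh, h_sb, p_sb_h)
    h_live = admit & ~h_sb
    h_female = h_live & (wh < 0.5)
    n_admit = _count(admit)
    acc["calvings"] += n_admit
    acc["first_calvings"] += n_admit
    acc["stillbirths"] += _count(h_sb)
    acc["live_calves_female"] += _count(h_female)
    acc["live_calves_male"] += _count(h_live & ~h_female)
    acc["disease_cases"][:, _DYS] += _count(h_dys)

    n_female2 = _count(h_female)
    free_h2 = (free_h | admit | sold_preg) & ~born_slots  # freeing this week
    if np.any(_count(free_h2) < n_female2):
        raise SimulationError("heifer slot pool exhausted; raise slot capacity")
    born2 = _take_first_k(free_h2, n_female2)

    # transfer admitted heifers into free cow slots as fresh parity-1 cows
    free_c = ~c_active
    if np.any(_count(free_c) < n_admit):
        raise SimulationError("cow slot pool exhausted; raise slot capacity")
    new_cows = _take_first_k(free_c, n_admit)
    c_active |= new_cows
    c_parity[new_cows] = 1
    c_wim[new_cows] = 0
    c_preg[new_cows] = 0
    c_dnb[new_cows] = False
    c_dis[:, new_cows] = 0

    h_active &= ~(admit | sold_preg)
    h_active |= born2
    h_age[born2] = 0
    h_preg[born2] = 0

    # open heifers past the sale age leave
    sold_open = h_active & (h_preg == 0) & (h_age >= OPEN_HEIFER_SALE_WEEKS)
    acc["heifers_sold_open"] += _count(sold_open)
    h_active &= ~sold_open

    # 6. disease onsets from weekly hazards (one episode at a time).
    #    All five weekly diseases share one uniform through disjoint
    #    bands [k*0.18, k*0.18 + h): marginal onset rates are exact and
    #    each band is monotone in its own hazard (CRN coupling); the
    #    only (negligible) difference from independent draws is that two
    #    diseases cannot start in the same cow-week.
    ud = dr["cow_dis"]
    for k, i in enumerate(_WEEKLY_IDX):
        if dv.hazard[i] <= 0:
            continue
        lo = np.float32(k * _BAND)
        onset = c_active & (c_dis[i] == 0) & (ud >= lo) & (ud < lo + np.float32(dv.hazard[i]))
        c_dis[i][onset] = dv.dur[i]
        acc["disease_cases"][:, i] += _count(onset)

    # 7. cow exits: death then culling as a nested ladder on one uniform
    p_death = np.float32(dv.mort_week) + calv_mort_bump
    p_cull = np.zeros(p_death.shape, dtype=np.float32)
    for i in range(len(DISEASES)):
        if dv.add_mort_week[i] > 0:
            p_death = p_death + np.float32(dv.add_mort_week[i]) * ep[i]
        if dv.add_cull_week[i] > 0:
            p_cull += np.float32(dv.add_cull_week[i]) * ep[i]
    p_cull += c_dnb & (c_wim >= DNB_CULL_WEEK)
    ue = dr["cow_exit"]
    die = c_active & (ue < p_death)
    cull = c_active & ~die & (ue < np.minimum(p_death + p_cull, np.float32(1.0)))
    acc["cow_deaths"] += _count(die)
    acc["cows_slaughtered"] += _count(cull)
    c_active &= ~(die | cull)

    # 8. rearing mortality in the early/late windows
    p_h = dv.h_mort_tab[np.minimum(h_age, len(dv.h_mort_tab) - 1)]
    h_die = h_active & (dr["h_exit"] < p_h)
    early = h_age <= EARLY_WINDOW[1]
    acc["calf_deaths_early"] += _count(h_die & early)
    acc["calf_deaths_late"] += _count(h_die & ~early)
    h_active &= ~h_die

    # 9. clocks (inactive slots tick too, harmlessly: every activation
    #    resets its slot's clocks)
    c_wim += c_active
    np.subtract(c_dis, 1, out=c_dis, where=c_dis > 0)
    h_age += h_active
    st.week += 1


def step_week(state: HerdState, params: HerdParameters, rng: np.random.Generator) -> HerdState:
    """Advance the herd by one week, drawing this week's randomness from
    ``rng``. ``params`` must be the parameter set the state was built
    with (the state caches derived constants)."""
    if state.params is not params and state.params != params:
        state.params = params
        state.derived = _Derived.from_params(params)
    _step_impl(state, _weekly_draws(rng, state.R, state.C, state.H))
    return state


# ---------------------------------------------------------------------------
# annual technical results


@dataclass
class AnnualTechnicalResult:
    """Physical outputs of one replicate-year."""

    replicate_id: int
    year_index: int
    cow_years: float
    heifer_years: float
    kg_ecm_delivered: float
    disease_cases: dict
    calvings: float
    stillbirths: float
    live_calves_female: float
    live_calves_male: float
    calf_deaths_early: float
    calf_deaths_late: float
    cow_deaths: float
    cows_slaughtered: float
    cows_slaughtered_weight_kg: float
    heifers_sold_pregnant: float
    heifers_sold_open: float
    heifers_slaughtered: float
    inseminations_cows: float
    inseminations_heifers: float
    conceptions_cows: float
    conceptions_heifers: float
    oestrus_events_cows: float
    oestrus_events_heifers: float
    first_calvings: float
    cows_start_of_year: float
    cows_end_of_year: float
    feed_sfu_cows: float
    feed_sfu_heifers: float
    feed_sfu_cows_concentrate: float
    feed_sfu_cows_roughage: float
    feed_sfu_heifers_concentrate: float
    feed_sfu_heifers_roughage: float
    milk_powder_kg: float
    calving_interval_sum_days: float
    calving_interval_count: float
    realized_trait_levels: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stillbirths > self.calvings + 1e-9:
            raise ValidationError("stillbirths cannot exceed calvings")
        for name in ("cow_years", "calvings", "cow_deaths", "cows_slaughtered"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.realized_trait_levels:
            self.realized_trait_levels = _realized_levels(self)


def _ratio(num: float, den: float) -> float:
    return float(num) / float(den) if den > 0 else 0.0


def _realized_levels(t: "AnnualTechnicalResult") -> dict:
    cy = t.cow_years
    levels = {
        "ecm": _ratio(t.kg_ecm_delivered, cy),
        "stillbirth": 100.0 * _ratio(t.stillbirths, t.calvings),
        "early_calf_mortality": 100.0 * _ratio(t.calf_deaths_early, t.live_calves_female),
        "late_calf_mortality": 100.0 * _ratio(t.calf_deaths_late, t.live_calves_female),
        "cow_mortality": 100.0 * _ratio(t.cow_deaths, cy),
        "cr_cows": 100.0 * _ratio(t.conceptions_cows, t.inseminations_cows),
        "cr_heifers": 100.0 * _ratio(t.conceptions_heifers, t.inseminations_heifers),
        "ho_cows": 100.0 * _ratio(t.inseminations_cows, t.oestrus_events_cows),
        "ho_heifers": 100.0 * _ratio(t.inseminations_heifers, t.oestrus_events_heifers),
        "calving_interval_days": _ratio(t.calving_interval_sum_days, t.calving_interval_count),
    }
    for disease in DISEASES:
        levels[disease] = 100.0 * _ratio(t.disease_cases.get(disease, 0.0), cy)
    return levels


def annual_aggregate(
    counts: Mapping[str, float],
    replicate_id: int,
    year_index: int,
    params: HerdParameters | None = None,
) -> AnnualTechnicalResult:
    """Build a validated :class:`AnnualTechnicalResult` from raw annual
    event counts (the accumulator of the weekly engine, or any mapping
    with the same keys). Realized trait levels are derived as
    100 x cases / cow-years (or the appropriate denominator)."""
    fm = params.feed_model if params is not None else None
    sfu_c = float(counts.get("feed_sfu_cows", 0.0))
    sfu_h = float(counts.get("feed_sfu_heifers", 0.0))
    conc_share = fm.concentrate_share if fm else 0.0
    h_conc_share = fm.heifer_concentrate_share if fm else 0.0
    live_wt = params.cow_live_weight_kg if params is not None else 0.0
    cases = counts.get("disease_cases", {})
    if not isinstance(cases, Mapping):
        cases = {d: float(cases[i]) for d, i in _DIS_INDEX.items()}
    return AnnualTechnicalResult(
        replicate_id=replicate_id,
        year_index=year_index,
        cow_years=float(counts.get("cow_weeks", 0.0)) / WEEKS_PER_YEAR,
        heifer_years=float(counts.get("heifer_weeks", 0.0)) / WEEKS_PER_YEAR,
        kg_ecm_delivered=float(counts.get("kg_ecm", 0.0)),
        disease_cases={d: float(cases.get(d, 0.0)) for d in DISEASES},
        calvings=float(counts.get("calvings", 0.0)),
        stillbirths=float(counts.get("stillbirths", 0.0)),
        live_calves_female=float(counts.get("live_calves_female", 0.0)),
        live_calves_male=float(counts.get("live_calves_male", 0.0)),
        calf_deaths_early=float(counts.get("calf_deaths_early", 0.0)),
        calf_deaths_late=float(counts.get("calf_deaths_late", 0.0)),
        cow_deaths=float(counts.get("cow_deaths", 0.0)),
        cows_slaughtered=float(counts.get("cows_slaughtered", 0.0)),
        cows_slaughtered_weight_kg=float(counts.get("cows_slaughtered", 0.0)) * live_wt,
        heifers_sold_pregnant=float(counts.get("heifers_sold_pregnant", 0.0)),
        heifers_sold_open=float(counts.get("heifers_sold_open", 0.0)),
        heifers_slaughtered=float(counts.get("heifers_slaughtered", 0.0)),
        inseminations_cows=float(counts.get("inseminations_cows", 0.0)),
        inseminations_heifers=float(counts.get("inseminations_heifers", 0.0)),
        conceptions_cows=float(counts.get("conceptions_cows", 0.0)),
        conceptions_heifers=float(counts.get("conceptions_heifers", 0.0)),
        oestrus_events_cows=float(counts.get("oestrus_events_cows", 0.0)),
        oestrus_events_heifers=float(counts.get("oestrus_events_heifers", 0.0)),
        first_calvings=float(counts.get("first_calvings", 0.0)),
        cows_start_of_year=float(counts.get("cows_start_of_year", 0.0)),
        cows_end_of_year=float(counts.get("cows_end_of_year", 0.0)),
        feed_sfu_cows=sfu_c,
        feed_sfu_heifers=sfu_h,
        feed_sfu_cows_concentrate=sfu_c * conc_share,
        feed_sfu_cows_roughage=sfu_c * (1.0 - conc_share),
        feed_sfu_heifers_concentrate=sfu_h * h_conc_share,
        feed_sfu_heifers_roughage=sfu_h * (1.0 - h_conc_share),
        milk_powder_kg=float(counts.get("milk_powder_kg", 0.0)),
        calving_interval_sum_days=float(counts.get("ci_sum_days", 0.0)),
        calving_interval_count=float(counts.get("ci_count", 0.0)),
    )


def combine_annual_results(results: Sequence[AnnualTechnicalResult]) -> AnnualTechnicalResult:
    """Pool several replicate-years into one technical record (counts
    summed, realized levels recomputed)."""
    if not results:
        raise ValueError("no results to combine")
    first = results[0]
    total = dataclasses.replace(first)
    sum_fields = [
        f.name
        for f in dataclasses.fields(AnnualTechnicalResult)
        if f.name
        not in (
            "replicate_id",
            "year_index",
            "disease_cases",
            "realized_trait_levels",
            "cows_start_of_year",
            "cows_end_of_year",
        )
    ]
    for name in sum_fields:
        setattr(total, name, sum(getattr(r, name) for r in results))
    total.disease_cases = {
        d: sum(r.disease_cases.get(d, 0.0) for r in results) for d in DISEASES
    }
    total.cows_start_of_year = first.cows_start_of_year
    total.cows_end_of_year = results[-1].cows_end_of_year
    total.realized_trait_levels = _realized_levels(total)
    return total


# ---------------------------------------------------------------------------
# simulation drivers


class SimulationOutput:
    """Batch simulation result: retained annual records per replicate."""

    def __init__(self, records: list[list[AnnualTechnicalResult]]):
        self._records = records

    @property
    def n_replicates(self) -> int:
        return len(self._records)

    def replicate(self, i: int) -> list[AnnualTechnicalResult]:
        return self._records[i]

    def __iter__(self) -> Iterable[list[AnnualTechnicalResult]]:
        return iter(self._records)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for rep in self._records:
            for r in rep:
                row = dataclasses.asdict(r)
                cases = row.pop("disease_cases")
                levels = row.pop("realized_trait_levels")
                row.update({f"cases_{k}": v for k, v in cases.items()})
                row.update({f"level_{k}": v for k, v in levels.items()})
                rows.append(row)
        return pd.DataFrame(rows)


def simulate_batch(
    params: HerdParameters,
    years: int,
    burn_in: int,
    seed: int,
    n_replicates: int,
) -> SimulationOutput:
    """Run ``n_replicates`` herds in lock-step for ``years`` simulated
    years and return the annual records of the last ``years - burn_in``
    years. Deterministic in (params, years, burn_in, seed,
    n_replicates); the weekly draw layout is fixed, so runs that differ
    only in parameters share randomness replicate-by-replicate."""
    if burn_in < 0 or years <= burn_in:
        raise ValueError("need years > burn_in >= 0")
    ss = np.random.SeedSequence(seed)
    init_ss, run_ss = ss.spawn(2)
    st = HerdState.initialize(params, n_replicates, np.random.Generator(np.random.PCG64(init_ss)))
    rng = np.random.Generator(np.random.PCG64(run_ss))
    records: list[list[AnnualTechnicalResult]] = [[] for _ in range(n_replicates)]
    for year in range(years):
        cows_start = st.cow_counts().astype(float)
        for _ in range(WEEKS_PER_YEAR):
            _step_impl(st, _weekly_draws(rng, st.R, st.C, st.H))
        cows_end = st.cow_counts().astype(float)
        extinct = (cows_end == 0) & (st.h_active.sum(axis=1) == 0)
        if np.any(extinct):
            reps = np.nonzero(extinct)[0].tolist()
            raise SimulationError(
                f"herd extinct in year {year} (replicates {reps})"
            )
        if year >= burn_in:
            for i in range(n_replicates):
                counts = {
                    k: (v[i] if np.ndim(v[i]) == 0 else v[i]) for k, v in st.acc.items()
                }
                counts["cows_start_of_year"] = cows_start[i]
                counts["cows_end_of_year"] = cows_end[i]
                records[i].append(
                    annual_aggregate(counts, replicate_id=i, year_index=year, params=params)
                )
        for k, v in st.acc.items():
            v[...] = 0.0
    return SimulationOutput(records)


def simulate_herd(
    params: HerdParameters, years: int, burn_in: int, seed: int
) -> list[AnnualTechnicalResult]:
    """Single-replicate convenience wrapper around :func:`simulate_batch`."""
    return simulate_batch(params, years, burn_in, seed, n_replicates=1).replicate(0)
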