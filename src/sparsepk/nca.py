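"""Noncompartmental analysis (NCA) of concentration-time profiles.

The estimators here are the classic noncompartmental set: observed
Cmax/Tmax, linear-trapezoidal AUClast and AUMClast with explicit handling
of below-quantification-limit (BLQ) samples, a terminal-phase log-linear
elimination rate constant (lambda-z, written K), and the derived chain

    T0.5e = ln 2 / K        (elimination half-life)
    MRT   = 1 / K           (mean residence time, default estimator)
    Vd    = dose / (K * AUClast)
    CL    = K * Vd

BLQ policy
----------
The default trapezoid rule enters BLQ samples as concentration 0 and
integrates from the profile's first sampled time through the FIRST BLQ
sample after the last quantifiable one, then stops. Segments with both
endpoints BLQ contribute nothing. This is the scheme that reproduces
destructive-sampling rodent study tables in which BLQ is reported as
0 mg/L; alternatives (dropping BLQ rows, or substituting LOQ/2) are
available via ``blq_rule``.

MRT estimator
-------------
``MRT = 1/K`` treats the body as a single well-stirred compartment in its
terminal phase. The moment-based estimator AUMClast/AUClast is offered as
``mrt_method="aumc_auc"``; the two differ whenever the observed window
truncates the tail.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .io import ConcentrationPoint, SubjectProfile

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

BlqRule = Literal["zero_through_first_blq", "drop_blq", "loq_half"]
LambdaZMode = Literal["auto", "window", "fixed"]


@dataclass(frozen=True)
class TrapezoidResult:
    """Linear-trapezoid AUC/AUMC over a profile's integration window."""

    auclast: float  # mg.h/L
    aumclast: float  # mg.h^2/L
    t_first: float
    t_last_integrated: float
    c_last_quantifiable: float


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal-phase log-linear regression result.

    ``k_per_h`` is None when the selected points do not decline (slope >= 0);
    downstream parameters cannot be derived from such a fit.
    """

    k_per_h: float | None
    intercept_ln_conc: float
    n_points: int
    window: tuple[float, float]
    r_squared: float
    adj_r_squared: float = float("nan")

    @property
    def ok(self) -> bool:
        return self.k_per_h is not None and self.k_per_h > 0


@dataclass(frozen=True)
class NCAResult:
    """Full per-profile NCA parameter set (one report row).

    Incomplete results (no quantifiable decline, or no dose) carry NaN in
    the derived fields and ``complete=False``.
    """

    subject_id: str
    cmax_mg_per_L: float
    tmax_h: float
    auclast_mg_h_per_L: float
    k_per_h: float = float("nan")
    t_half_h: float = float("nan")
    mrt_h: float = float("nan")
    vd_L: float = float("nan")
    cl_L_per_h: float = float("nan")
    dose_mg: float = float("nan")
    complete: bool = True
    lambda_z: LambdaZFit | None = None


@dataclass(frozen=True)
class NCAConfig:
    """Every policy knob of the pipeline, in one place.

    ln2_constant defaults to full precision; the rounded literal 0.693 used
    by some legacy reports can be substituted.
    """

    blq_rule: BlqRule = "zero_through_first_blq"
    loq_mg_per_L: float = 0.0  # used by the loq_half rule
    lambda_z_mode: LambdaZMode = "auto"
    fixed_k_per_h: float | None = None
    lambda_z_window: tuple[float, float] | None = None
    ln2_constant: float = LN2
    mrt_method: Literal["inverse_k", "aumc_auc"] = "inverse_k"
    pooled_rounding_dp: int | None = None

    def __post_init__(self) -> None:
        if self.lambda_z_mode == "fixed":
            if self.fixed_k_per_h is None or self.fixed_k_per_h <= 0:
                raise ValueError("fixed lambda-z mode requires fixed_k_per_h > 0")
        if self.lambda_z_mode == "window" and self.lambda_z_window is None:
            raise ValueError("window lambda-z mode requires lambda_z_window")


def find_cmax(profile: SubjectProfile) -> tuple[float, float]:
    """Maximum observed concentration and its time; ties go to the earliest.

    An all-BLQ profile yields (0, first sampled time) with a warning.
    """
    if not profile.points:
        raise ValueError(f"subject {profile.subject_id!r}: empty profile")
    conc = profile.concentrations
    idx = int(np.argmax(conc))  # argmax returns the first maximum: earliest time
    if conc[idx] == 0 and profile.blq_flags.all():
        logger.warning(
            "subject %s: all observations BLQ; Cmax degenerate", profile.subject_id
        )
    return float(conc[idx]), float(profile.times[idx])


def _integration_window(
    points: Sequence[ConcentrationPoint], blq_rule: BlqRule, loq: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Times, concentrations and last quantifiable conc for integration."""
    quant_idx = [i for i, p in enumerate(points) if not p.blq]
    if not quant_idx:
        t = np.array([p.time_h for p in points])
        return t, np.zeros_like(t), 0.0
    last_q = quant_idx[-1]
    c_last_q = points[last_q].conc_mg_per_L

    if blq_rule == "drop_blq":
        kept = [points[i] for i in quant_idx]
        t = np.array([p.time_h for p in kept])
        c = np.array([p.conc_mg_per_L for p in kept])
        return t, c, c_last_q

    # extend through the first BLQ sample after the last quantifiable point
    end = last_q + 1 if last_q + 1 < len(points) else last_q
    window = points[: end + 1]
    t = np.array([p.time_h for p in window])
    if blq_rule == "zero_through_first_blq":
        c = np.array([0.0 if p.blq else p.conc_mg_per_L for p in window])
    elif blq_rule == "loq_half":
        c = np.array([loq / 2.0 if p.blq else p.conc_mg_per_L for p in window])
    else:
        raise ValueError(f"unknown blq_rule {blq_rule!r}")
    return t, c, c_last_q


def integrate_trapezoid(
    profile: SubjectProfile,
    blq_rule: BlqRule = "zero_through_first_blq",
    *,
    loq_mg_per_L: float = 0.0,
) -> TrapezoidResult:
    """Linear-trapezoid AUClast and AUMClast with BLQ handling.

    Integration starts at the profile's first sampled time (no t=0 point is
    imputed for subjects first sampled later). AUMClast integrates t*C(t)
    by the same rule over the same window.
    """
    if len(profile.points) < 2:
        raise ValueError(f"subject {profile.subject_id!r}: need >=2 points to integrate")
    t, c, c_last_q = _integration_window(profile.points, blq_rule, loq_mg_per_L)
    auc = float(np.trapezoid(c, t))
    aumc = float(np.trapezoid(t * c, t))
    return TrapezoidResult(
        auclast=auc,
        aumclast=aumc,
        t_first=float(t[0]),
        t_last_integrated=float(t[-1]),
        c_last_quantifiable=c_last_q,
    )


def _regress(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln(conc) on time: (slope, intercept, r_squared)."""
    fit = stats.linregress(t, np.log(c))
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def fit_lambda_z(
    profile: SubjectProfile,
    mode: Literal["auto", "window"] = "auto",
    window: tuple[float, float] | None = None,
) -> LambdaZFit:
    """Terminal elimination rate constant by log-linear regression.

    auto mode considers every contiguous run of quantifiable points that
    ends at the last quantifiable observation and starts at or after Tmax,
    and keeps the run with the best adjusted R-squared. Runs of >=3 points
    are preferred (adjusted R-squared is undefined at n=2); a 2-point run
    is used only when nothing larger exists. Ties go to the longer run.
    window mode regresses over the user-supplied [start, end] hours.

    A non-declining selection (slope >= 0) is returned flagged, with
    ``k_per_h`` unset, rather than raising.
    """
    quant = [(p.time_h, p.conc_mg_per_L) for p in profile.points if not p.blq and p.conc_mg_per_L > 0]
    if len(quant) < 2:
        raise ValueError(
            f"subject {profile.subject_id!r}: need >=2 positive quantifiable points "
            f"for lambda-z (have {len(quant)})"
        )
    t_all = np.array([q[0] for q in quant])
    c_all = np.array([q[1] for q in quant])

    if mode == "window":
        if window is None:
            raise ValueError("window mode requires an explicit (start, end) window")
        mask = (t_all >= window[0]) & (t_all <= window[1])
        if mask.sum() < 2:
            raise ValueError(f"lambda-z window {window} contains <2 quantifiable points")
        return _fit_window(t_all[mask], c_all[mask])

    _, tmax = find_cmax(profile)
    start_candidates = [i for i in range(len(t_all) - 1) if t_all[i] >= tmax]
    if not start_candidates:
        start_candidates = [len(t_all) - 2]  # fall back to the last two points

    best: tuple[float, int, LambdaZFit] | None = None
    for i in start_candidates:
        t, c = t_all[i:], c_all[i:]
        n = len(t)
        slope, intercept, r2 = _regress(t, c)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n >= 3 else -math.inf
        if slope >= 0:
            continue
        fit = LambdaZFit(
            k_per_h=-slope,
            intercept_ln_conc=intercept,
            n_points=n,
            window=(float(t[0]), float(t[-1])),
            r_squared=r2,
            adj_r_squared=adj,
        )
        key = (adj, n)
        if best is None or key > (best[0], best[1]):
            best = (adj, n, fit)
    if best is not None:
        return best[2]

    # no declining run: flag, report fit quality of the full candidate span
    i0 = start_candidates[0]
    slope, intercept, r2 = _regress(t_all[i0:], c_all[i0:])
    logger.warning("subject %s: no declining terminal phase", profile.subject_id)
    return LambdaZFit(
        k_per_h=None,
        intercept_ln_conc=intercept,
        n_points=len(t_all) - i0,
        window=(float(t_all[i0]), float(t_all[-1])),
        r_squared=r2,
    )


def _fit_window(t: np.ndarray, c: np.ndarray) -> LambdaZFit:
    n = len(t)
    slope, intercept, r2 = _regress(t, c)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n >= 3 else float("nan")
    k = -slope if slope < 0 else None
    if k is None:
        logger.warning("lambda-z window fit is non-declining (slope %.4g)", slope)
    return LambdaZFit(
        k_per_h=k,
        intercept_ln_conc=intercept,
        n_points=n,
        window=(float(t[0]), float(t[-1])),
        r_squared=r2,
        adj_r_squared=adj,
    )


def derive_parameters(
    auclast: float,
    k: LambdaZFit | float,
    dose_mg: float,
    *,
    subject_id: str = "",
    cmax_mg_per_L: float = float("nan"),
    tmax_h: float = float("nan"),
    ln2_constant: float = LN2,
    mrt_method: Literal["inverse_k", "aumc_auc"] = "inverse_k",
    aumclast: float | None = None,
) -> NCAResult:
    """Half-life, MRT, volume of distribution and clearance from K and AUC.

    T0.5e = ln2/K, MRT = 1/K (or AUMC/AUC), Vd = dose/(K*AUClast),
    CL = K*Vd. ``k`` may be a fitted :class:`LambdaZFit` or a plain rate
    constant in 1/h (e.g. a published value used as a fixed input).
    """
    fit = k if isinstance(k, LambdaZFit) else None
    k_val = k.k_per_h if isinstance(k, LambdaZFit) else float(k)
    if k_val is None or k_val <= 0:
        raise ValueError("elimination rate constant must be positive")
    if auclast <= 0:
        raise ValueError("AUClast must be positive")
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    if mrt_method == "aumc_auc":
        if aumclast is None:
            raise ValueError("mrt_method='aumc_auc' requires aumclast")
        mrt = aumclast / auclast
    else:
        mrt = 1.0 / k_val
    t_half = ln2_constant / k_val
    vd = dose_mg / (k_val * auclast)
    cl = k_val * vd
    return NCAResult(
        subject_id=subject_id,
        cmax_mg_per_L=cmax_mg_per_L,
        tmax_h=tmax_h,
        auclast_mg_h_per_L=auclast,
        k_per_h=k_val,
        t_half_h=t_half,
        mrt_h=mrt,
        vd_L=vd,
        cl_L_per_h=cl,
        dose_mg=dose_mg,
        complete=True,
        lambda_z=fit,
    )


def pooled_mean_profile(
    profiles: Sequence[SubjectProfile],
    rounding_dp: int | None = None,
) -> SubjectProfile:
    """Group-level mean profile over the union of sampled times.

    At each time the mean runs over the subjects actually sampled there
    (staggered designs contribute disjoint time sets), with BLQ entering as
    0 mg/L. A pooled point is flagged BLQ only when every contributor was.
    ``rounding_dp`` optionally rounds the means (half away from zero)
    before downstream NCA, matching reports that tabulate rounded means.
    The pooled dose and body weight are the subject means when available.
    """
    if not profiles:
        raise ValueError("no profiles to pool")
    from .io import round_half_away

    all_times = sorted({p.time_h for prof in profiles for p in prof.points})
    points = []
    for t in all_times:
        contributors = [
            p for prof in profiles for p in prof.points if p.time_h == t
        ]
        mean_c = float(np.mean([p.conc_mg_per_L for p in contributors]))
        if rounding_dp is not None:
            mean_c = round_half_away(mean_c, rounding_dp)
        all_blq = all(p.blq for p in contributors)
        points.append(ConcentrationPoint(t, 0.0 if all_blq else mean_c, all_blq))
    doses = [p.dose_mg for p in profiles if p.dose_mg is not None]
    weights = [p.body_weight_g for p in profiles if p.body_weight_g is not None]
    return SubjectProfile(
        subject_id="pooled_mean",
        points=tuple(points),
        dose_mg=float(np.mean(doses)) if len(doses) == len(profiles) else None,
        body_weight_g=float(np.mean(weights)) if len(weights) == len(profiles) else None,
    )


def run_nca(profile: SubjectProfile, config: NCAConfig = NCAConfig()) -> NCAResult:
    """Run the full NCA chain on one profile.

    Composes :func:`find_cmax`, :func:`integrate_trapezoid`,
    :func:`fit_lambda_z` (or a fixed/windowed K per config) and
    :func:`derive_parameters`. Profiles without a usable declining phase
    yield a partial result (Cmax/Tmax/AUClast only) flagged incomplete
    instead of raising.
    """
    cmax, tmax = find_cmax(profile)
    trap = integrate_trapezoid(
        profile, config.blq_rule, loq_mg_per_L=config.loq_mg_per_L
    )
    partial = NCAResult(
        subject_id=profile.subject_id,
        cmax_mg_per_L=cmax,
        tmax_h=tmax,
        auclast_mg_h_per_L=trap.auclast,
        dose_mg=profile.dose_mg if profile.dose_mg is not None else float("nan"),
        complete=False,
    )
    if trap.auclast <= 0:
        return partial

    if config.lambda_z_mode == "fixed":
        k: LambdaZFit | float = float(config.fixed_k_per_h)  # validated in config
    else:
        try:
            fit = fit_lambda_z(
                profile,
                mode=config.lambda_z_mode,
                window=config.lambda_z_window,
            )
        except ValueError:
            return partial
        if not fit.ok:
            return dataclasses.replace(partial, lambda_z=fit)
        k = fit

    if profile.dose_mg is None:
        raise ValueError(
            f"subject {profile.subject_id!r} has no dose; attach a dose table first"
        )
    return derive_parameters(
        trap.auclast,
        k,
        profile.dose_mg,
        subject_id=profile.subject_id,
        cmax_mg_per_L=cmax,
        tmax_h=tmax,
        ln2_constant=config.ln2_constant,
        mrt_method=config.mrt_method,
        aumclast=trap.aumclast,
    )
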