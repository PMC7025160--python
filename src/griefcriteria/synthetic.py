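"""Synthetic bereaved-cohort generator with a latent grief-severity trait.

Respondent-level data from the military-family bereavement cohort the
analysis emulates are not public, so this module generates cohorts with
the statistical structure the analysis assumes: a two-class latent
grief-severity trait (a resilient majority class and a persistent-grief
class) drives correlated ordinal responses on all three instruments
through a graded-response mechanism,

    P(X_ij >= c | theta_i) = expit(a_j * (theta_i - b_jc)),

with per-item strictly increasing thresholds ``b_jc`` and instrument-level
trait perturbations that keep cross-instrument totals strongly but not
perfectly correlated. The impairment-frequency probe and months since
death are drawn from the same trait and a uniform window, respectively.

Shipped defaults are calibrated (see :func:`calibrate`) so that at the
study's sample size (n = 1732) the simulated marginals match the printed
prevalences: ~37% with ICG total >= 30 and ~16% meeting the joint clinical
threshold (ICG >= 30 and WSAS >= 20).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit

from .instruments import (
    BANKS,
    CGQ_BANK,
    ICG_BANK,
    WSAS_BANK,
    CasenessRule,
    RespondentRecord,
    classify_caseness,
    score_total,
)

__all__ = [
    "GeneratorConfig",
    "RecoveryResult",
    "CalibrationError",
    "default_config",
    "generate_cohort",
    "calibrate",
    "recover_parameters",
]

#: Default cohort size, matching the study sample (N = 1732).
DEFAULT_N = 1732
#: Default RNG seed, fixed for reproducible shipped cohorts.
DEFAULT_SEED = 1732


class CalibrationError(RuntimeError):
    """Raised when calibration cannot reach the target marginals.

    Carries ``achieved`` — the closest (p_icg30, p_joint_case) reached.
    """

    def __init__(self, message: str, achieved: tuple[float, float]):
        super().__init__(f"{message}; closest achieved marginals {achieved}")
        self.achieved = achieved


def _graded_thresholds(locations: Sequence[float], n_levels: int, step: float) -> np.ndarray:
    """Per-item threshold matrix b_jc = loc_j + step * (c - (n_levels+1)/2), c=1..n_levels."""
    locs = np.asarray(locations, dtype=float)[:, None]
    offsets = step * (np.arange(1, n_levels + 1) - (n_levels + 1) / 2.0)
    return locs + offsets[None, :]


def _default_item_params() -> tuple[dict, dict]:
    """Default discriminations and threshold matrices per instrument."""
    cgq_locs = np.concatenate(
        [
            [0.0, 0.2],                      # core: yearning, preoccupation (common)
            np.linspace(0.7, 1.5, 9),        # shared associated symptoms
            [1.8, 1.9, 2.0],                 # rarer associated symptoms
            np.linspace(0.4, 1.6, 12),       # remaining CGQ content
        ]
    )
    icg_locs = np.linspace(0.0, 1.6, ICG_BANK.n_items)
    wsas_locs = np.linspace(1.2, 1.8, WSAS_BANK.n_items)
    discriminations = {
        "CGQ": np.full(CGQ_BANK.n_items, 1.7),
        "ICG": np.full(ICG_BANK.n_items, 1.7),
        "WSAS": np.full(WSAS_BANK.n_items, 1.7),
    }
    thresholds = {
        "CGQ": _graded_thresholds(cgq_locs, CGQ_BANK.max_code, 0.7),
        "ICG": _graded_thresholds(icg_locs, ICG_BANK.max_code, 0.7),
        "WSAS": _graded_thresholds(wsas_locs, WSAS_BANK.max_code, 0.35),
    }
    return discriminations, thresholds


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator; defaults are the calibrated study conditions."""

    n: int = DEFAULT_N
    mixture_weight: float = 0.31  # probability of the persistent-grief class
    class_means: tuple[float, float] = (-0.55, 1.42)  # (resilient, persistent)
    class_sds: tuple[float, float] = (0.85, 0.75)
    item_discriminations: Mapping[str, np.ndarray] = field(
        default_factory=lambda: _default_item_params()[0]
    )
    item_thresholds: Mapping[str, np.ndarray] = field(
        default_factory=lambda: _default_item_params()[1]
    )
    cross_instrument_noise: Mapping[str, float] = field(
        default_factory=lambda: {"CGQ": 0.35, "ICG": 0.25, "WSAS": 0.60}
    )
    impairment_link: Mapping[str, object] = field(
        default_factory=lambda: {
            "discrimination": 1.7,
            "thresholds": (-0.8, -0.2, 0.6, 1.4),
        }
    )
    months_since_death_range: tuple[float, float] = (13.0, 120.0)
    missing_rate: float = 0.0
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError(f"mixture_weight {self.mixture_weight} outside [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate {self.missing_rate} outside [0, 1)")
        if any(sd <= 0 for sd in self.class_sds):
            raise ValueError("class_sds must be positive")
        lo, hi = self.months_since_death_range
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid months_since_death_range {self.months_since_death_range}")
        for name, bank in BANKS.items():
            thr = np.asarray(self.item_thresholds[name], dtype=float)
            if thr.shape != (bank.n_items, bank.max_code):
                raise ValueError(
                    f"{name}: thresholds shape {thr.shape}, expected "
                    f"({bank.n_items}, {bank.max_code})"
                )
            if not np.all(np.diff(thr, axis=1) > 0):
                raise ValueError(f"{name}: item thresholds must be strictly increasing")
            if np.asarray(self.item_discriminations[name]).shape != (bank.n_items,):
                raise ValueError(f"{name}: need one discrimination per item")
        imp = np.asarray(self.impairment_link["thresholds"], dtype=float)
        if imp.shape != (4,) or not np.all(np.diff(imp) > 0):
            raise ValueError("impairment_link thresholds must be 4 strictly increasing values")


def default_config(**overrides) -> GeneratorConfig:
    """Calibrated default configuration, optionally with fields overridden."""
    return replace(GeneratorConfig(), **overrides)


# ---------------------------------------------------------------------------
# generation


def _draw_graded(rng, theta: np.ndarray, disc: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Draw ordinal responses: one uniform per (person, item) through the cumulative curves."""
    # p_ge[i, j, c] = P(X_ij >= c+1 | theta_i), non-increasing in c
    p_ge = expit(disc[None, :, None] * (theta[:, None, None] - thresholds[None, :, :]))
    u = rng.random((theta.size, thresholds.shape[0]))
    return (u[:, :, None] < p_ge).sum(axis=2)


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> list[RespondentRecord]:
    """Generate a cohort of respondents; reproducible given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return []

    is_persistent = rng.random(n) < config.mixture_weight
    means = np.where(is_persistent, config.class_means[1], config.class_means[0])
    sds = np.where(is_persistent, config.class_sds[1], config.class_sds[0])
    theta = rng.normal(means, sds)

    responses: dict[str, np.ndarray] = {}
    for name, bank in BANKS.items():
        theta_instr = theta + rng.normal(0.0, config.cross_instrument_noise[name], n)
        responses[name] = _draw_graded(
            rng,
            theta_instr,
            np.asarray(config.item_discriminations[name], dtype=float),
            np.asarray(config.item_thresholds[name], dtype=float),
        )

    imp_disc = float(config.impairment_link["discrimination"])
    imp_thr = np.asarray(config.impairment_link["thresholds"], dtype=float)
    p_ge = expit(imp_disc * (theta[:, None] - imp_thr[None, :]))
    impairment = (rng.random(n)[:, None] < p_ge).sum(axis=1)

    lo, hi = config.months_since_death_range
    months = rng.uniform(lo, hi, n)

    missing: dict[str, np.ndarray] = {
        name: (rng.random(responses[name].shape) < config.missing_rate)
        for name in BANKS
    }

    width = max(4, len(str(n)))
    records = []
    for i in range(n):
        item_maps = {}
        for name, bank in BANKS.items():
            vals = responses[name][i]
            mask = missing[name][i]
            item_maps[name] = {
                item: (None if mask[j] else int(vals[j]))
                for j, item in enumerate(bank.item_ids)
            }
        records.append(
            RespondentRecord(
                respondent_id=f"r{i + 1:0{width}d}",
                cgq=item_maps["CGQ"],
                icg=item_maps["ICG"],
                wsas=item_maps["WSAS"],
                impairment_frequency=int(impairment[i]),
                months_since_death=float(months[i]),
            )
        )
    return records


def _marginals(config: GeneratorConfig, n: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo estimates of P(ICG >= 30) and P(case) under ``config``."""
    cohort = generate_cohort(replace(config, n=n, seed=seed, missing_rate=0.0))
    rule = CasenessRule()
    icg = np.array([score_total(r, "ICG") for r in cohort], dtype=float)
    case = np.array([classify_caseness(r, rule) == "case" for r in cohort])
    return float(np.mean(icg >= rule.icg_cutoff)), float(np.mean(case))


# ---------------------------------------------------------------------------
# calibration


def calibrate(
    target_marginals: Mapping[str, float],
    config: GeneratorConfig = GeneratorConfig(),
    tol: float = 0.02,
    mc_n: int = 20_000,
) -> GeneratorConfig:
    """Adjust mixture weight and persistent-class mean to hit target marginals.

    Parameters
    ----------
    target_marginals
        ``{"p_icg30": ..., "p_joint_case": ...}`` — target probabilities in
        (0, 1) with ``p_joint_case <= p_icg30``.
    config
        Starting configuration; only ``mixture_weight`` and
        ``class_means[1]`` are searched, everything else is held fixed.
    tol
        Both Monte-Carlo marginals (at ``mc_n`` respondents) must land
        within this absolute tolerance (default +-2 percentage points).

    The search is deterministic: a fixed evaluation seed, a coarse grid
    over the persistent-class mean, and bisection on the mixture weight
    against the ICG marginal at each candidate mean.
    """
    p_icg = float(target_marginals["p_icg30"])
    p_joint = float(target_marginals["p_joint_case"])
    if not (0.0 < p_icg < 1.0 and 0.0 < p_joint < 1.0):
        raise ValueError(f"targets must lie in (0, 1), got {target_marginals}")
    if p_joint > p_icg:
        raise ValueError(
            f"p_joint_case ({p_joint}) cannot exceed p_icg30 ({p_icg}): "
            "caseness requires ICG >= 30"
        )
    config.validate()
    eval_seed = config.seed

    current = _marginals(config, mc_n, eval_seed)
    if abs(current[0] - p_icg) <= tol and abs(current[1] - p_joint) <= tol:
        return config

    def achieved(weight: float, mu1: float) -> tuple[float, float]:
        candidate = replace(
            config,
            mixture_weight=weight,
            class_means=(config.class_means[0], mu1),
        )
        return _marginals(candidate, mc_n, eval_seed)

    def solve_weight(mu1: float) -> tuple[float, tuple[float, float]]:
        # ICG marginal is monotone in the weight of the (higher-mean) persistent class
        lo_w, hi_w = 0.0, 1.0
        best = (0.5, achieved(0.5, mu1))
        for _ in range(18):
            mid = 0.5 * (lo_w + hi_w)
            marg = achieved(mid, mu1)
            if abs(marg[0] - p_icg) < abs(best[1][0] - p_icg):
                best = (mid, marg)
            if marg[0] < p_icg:
                lo_w = mid
            else:
                hi_w = mid
        return best

    best_overall: Optional[tuple[float, float, tuple[float, float]]] = None
    mu0 = config.class_means[0]
    for mu1 in np.linspace(mu0 + 0.5, mu0 + 3.5, 13):
        weight, marg = solve_weight(float(mu1))
        if abs(marg[0] - p_icg) > tol:
            continue
        err = abs(marg[1] - p_joint)
        if best_overall is None or err < abs(best_overall[2][1] - p_joint):
            best_overall = (weight, float(mu1), marg)
        if err <= tol:
            break

    if best_overall is None:
        raise CalibrationError("ICG marginal unreachable on searched grid", current)
    weight, mu1, marg = best_overall
    if abs(marg[0] - p_icg) > tol or abs(marg[1] - p_joint) > tol:
        raise CalibrationError("targets not reachable within tolerance", marg)
    return replace(config, mixture_weight=weight, class_means=(mu0, mu1))


# ---------------------------------------------------------------------------
# parameter recovery (test surface)


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of the two-component fit on ICG totals (latent-class proxy)."""

    ok: bool
    n_classes: int
    mixture_weight: float
    class_means: tuple[float, ...]  # on the ICG total-score scale
    message: str = ""


def recover_parameters(cohort: Sequence[RespondentRecord]) -> RecoveryResult:
    """Estimate the persistent-class weight from ICG totals via a Gaussian mixture.

    Fits a two-component mixture to complete-case ICG totals; the weight
    of the higher-mean component estimates ``mixture_weight``, with class
    means reported on the total-score scale. A single class is declared
    when the fitted components are not genuinely bimodal — Ashman's
    D = |mu2 - mu1| / sqrt((s1^2 + s2^2) / 2) below 2.5 — because a
    two-component fit always improves the likelihood on the skewed,
    bounded totals a single latent class produces. Used as a test surface
    for the generator, not as an analysis step.
    """
    from sklearn.mixture import GaussianMixture

    totals = np.array(
        [t for r in cohort if (t := score_total(r, "ICG")) is not None], dtype=float
    )
    if totals.size == 0:
        return RecoveryResult(False, 0, math.nan, (), "no complete ICG totals")
    if np.ptp(totals) == 0:
        return RecoveryResult(False, 0, math.nan, (), "degenerate cohort: constant ICG totals")

    X = totals[:, None]
    gm2 = GaussianMixture(2, n_init=5, random_state=0).fit(X)
    order = np.argsort(gm2.means_[:, 0])
    means = gm2.means_[order, 0]
    variances = gm2.covariances_[order, 0, 0]
    ashman_d = (means[1] - means[0]) / math.sqrt((variances[0] + variances[1]) / 2.0)
    if ashman_d < 2.5:
        return RecoveryResult(
            True, 1, 1.0, (float(totals.mean()),), "single class detected"
        )
    weight_high = float(gm2.weights_[order[-1]])
    return RecoveryResult(True, 2, weight_high, tuple(float(m) for m in means))
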