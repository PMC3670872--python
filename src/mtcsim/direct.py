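"""Classical pairwise random-effects meta-analysis of 2x2 tables.

Per-study log odds ratios with Woolf variances are pooled under the
random-effects model ``y_i ~ Normal(theta, v_i + tau^2)``, with the
between-study variance ``tau^2`` estimated by restricted maximum
likelihood (Fisher scoring from a DerSimonian-Laird start).  This is the
focused many-vs-one analysis — e.g. one drug against its head-to-head
comparators pooled — that complements the all-pairs network model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .network import TrialNetwork

__all__ = [
    "StudyEffect",
    "PooledResult",
    "NonInformativeStudyError",
    "table_to_effect",
    "effects_from_tables",
    "effects_from_network",
    "reml_pool",
    "restricted_loglik",
]


class NonInformativeStudyError(ValueError):
    """Both arms have zero (or all) responders: the table carries no
    information about the odds ratio."""


@dataclass(frozen=True)
class StudyEffect:
    """One study's log odds ratio ``y`` and within-study variance ``v``."""

    y: float
    v: float

    def __post_init__(self):
        if self.v <= 0:
            raise ValueError(f"within-study variance must be positive, got {self.v}")


@dataclass(frozen=True)
class PooledResult:
    """Random-effects pooled log-OR with Wald inference and REML tau^2."""

    log_or: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    tau2: float
    k_studies: int

    def to_frame(self) -> pd.DataFrame:
        """One-row summary frame, convenient for CSV export."""
        return pd.DataFrame([self.__dict__])


def table_to_effect(
    r1: int, n1: int, r2: int, n2: int, correction: float = 0.5
) -> StudyEffect:
    """Log-OR of arm 1 versus arm 2 from a 2x2 table, with Woolf variance.

    When any of the four cells (r, n - r per arm) is zero, ``correction``
    is added to all four cells of that study before computing
    ``y = log[(r1 (n2-r2)) / (r2 (n1-r1))]`` and
    ``v = 1/r1 + 1/(n1-r1) + 1/r2 + 1/(n2-r2)``.
    Double-zero / double-all tables raise :class:`NonInformativeStudyError`.
    """
    for r, n, lab in ((r1, n1, "arm 1"), (r2, n2, "arm 2")):
        if not 0 <= r <= n:
            raise ValueError(f"{lab}: responders {r} outside [0, {n}]")
    if (r1 == 0 and r2 == 0) or (r1 == n1 and r2 == n2):
        raise NonInformativeStudyError(
            f"table ({r1}/{n1}, {r2}/{n2}) is non-informative for the odds ratio"
        )
    cells = np.array([r1, n1 - r1, r2, n2 - r2], dtype=float)
    if np.any(cells == 0):
        if correction <= 0:
            raise ValueError("zero cell present but correction is not positive")
        cells = cells + correction
    a, b, c, d = cells
    y = float(np.log(a * d / (b * c)))
    v = float(np.sum(1.0 / cells))
    return StudyEffect(y=y, v=v)


def effects_from_tables(df: pd.DataFrame, correction: float = 0.5) -> list[StudyEffect]:
    """Effects from a 2x2-per-row frame with columns study,r1,n1,r2,n2;
    non-informative studies are excluded with a warning."""
    out = []
    for row in df.itertuples(index=False):
        try:
            out.append(
                table_to_effect(
                    int(row.r1), int(row.n1), int(row.r2), int(row.n2), correction
                )
            )
        except NonInformativeStudyError as exc:
            warnings.warn(f"study {getattr(row, 'study', '?')}: excluded ({exc})")
    return out


def effects_from_network(
    net: TrialNetwork, correction: float = 0.5
) -> list[StudyEffect]:
    """One effect per two-arm trial: first-listed arm versus second."""
    out = []
    for trial in net.trials:
        if len(trial.arms) != 2:
            raise ValueError(
                f"trial {trial.id!r} has {len(trial.arms)} arms; direct pooling"
                " expects two-arm trials"
            )
        a1, a2 = trial.arms
        if a1.r is None or a2.r is None:
            raise ValueError(f"trial {trial.id!r} has unset responders")
        try:
            out.append(table_to_effect(a1.r, a1.n, a2.r, a2.n, correction))
        except NonInformativeStudyError as exc:
            warnings.warn(f"trial {trial.id!r}: excluded ({exc})")
    return out


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of tau^2 (additive constants dropped)."""
    w = 1.0 / (v + tau2)
    theta = np.sum(w * y) / np.sum(w)
    return float(
        -0.5 * np.sum(np.log(v + tau2))
        - 0.5 * np.log(np.sum(w))
        - 0.5 * np.sum(w * (y - theta) ** 2)
    )


def _dl_start(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    theta = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - theta) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return max(0.0, float((q - (len(y) - 1)) / denom))


def reml_pool(
    effects: Sequence[StudyEffect],
    tol: float = 1e-8,
    max_iter: int = 200,
) -> PooledResult:
    """REML random-effects pooling of per-study log odds ratios.

    tau^2 is found by Fisher scoring on the restricted likelihood starting
    from the DerSimonian-Laird estimate, floored at zero, converged when
    successive iterates differ by less than ``tol``.  The pooled effect is
    the inverse-variance weighted mean with weights ``1/(v_i + tau^2)``.
    """
    if len(effects) == 0:
        raise ValueError("need at least one study effect")
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    k = len(y)
    if k == 1:
        tau2 = 0.0
    else:
        tau2 = _dl_start(y, v)
        converged = False
        for _ in range(max_iter):
            w = 1.0 / (v + tau2)
            sw = np.sum(w)
            theta = np.sum(w * y) / sw
            # restricted score and expected information in tau^2
            score = 0.5 * (
                np.sum(w**2 * (y - theta) ** 2) - np.sum(w) + np.sum(w**2) / sw
            )
            info = 0.5 * (
                np.sum(w**2) - 2.0 * np.sum(w**3) / sw + (np.sum(w**2) / sw) ** 2
            )
            if info <= 0:
                break
            new = tau2 + score / info
            if new < 0.0:
                # boundary: halve toward zero instead of jumping, otherwise
                # Fisher scoring can oscillate between 0 and an interior point
                new = 0.0 if tau2 < tol else tau2 / 2.0
            # step-halving keeps the restricted likelihood non-decreasing,
            # preventing oscillation across a small interior optimum
            ll_cur = restricted_loglik(tau2, y, v)
            for _ in range(40):
                if restricted_loglik(new, y, v) >= ll_cur - 1e-13 or abs(new - tau2) < tol:
                    break
                new = 0.5 * (new + tau2)
            if abs(new - tau2) < tol:
                tau2 = new
                converged = True
                break
            tau2 = new
        else:
            raise RuntimeError(
                f"REML did not converge in {max_iter} iterations; last tau^2 = {tau2:.6g}"
            )
        if not converged and tau2 > 0.0:
            # stepped out of the loop via non-positive information: accept the
            # boundary/flat point, which the grid oracle confirms in tests
            pass
    w = 1.0 / (v + tau2)
    theta = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = theta / se
    p = float(2.0 * norm.sf(abs(z)))
    zcrit = norm.ppf(0.975)
    return PooledResult(
        log_or=theta,
        se=se,
        odds_ratio=float(np.exp(theta)),
        ci_low=float(np.exp(theta - zcrit * se)),
        ci_high=float(np.exp(theta + zcrit * se)),
        z=float(z),
        p_value=p,
        tau2=float(tau2),
        k_studies=k,
    )
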