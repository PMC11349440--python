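"""Quasi-periods of population cycles from AR characteristic roots.

A stationary AR(p) process ``Y_t = theta_1 Y_{t-1} + ... + theta_p Y_{t-p} + e``
has characteristic polynomial ``z^p - theta_1 z^{p-1} - ... - theta_p``.
Each complex-conjugate root pair ``r e^{+-i w}`` (w in (0, pi)) damps with
modulus r and contributes a quasi-cycle of length ``2 pi / w`` years; a real
positive root contributes a pure exponential decay of the growth rate.  For
an AR(2) with complex roots the period has the closed form
``2 pi / arccos(theta_1 / (2 sqrt(-theta_2)))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CycleError(ValueError):
    pass


@dataclass
class CycleReport:
    """Root decomposition of one AR coefficient vector.

    Complex pairs are counted once and sorted by modulus descending; the
    intercept is never part of the characteristic polynomial.
    """

    order: int
    roots: np.ndarray
    pair_moduli: np.ndarray
    periods: np.ndarray  # years, aligned with pair_moduli
    real_root_moduli: np.ndarray
    real_roots: np.ndarray
    stationary: bool

    def to_frame(self, subgroup="") -> pd.DataFrame:
        rows = []
        for i, (m, per) in enumerate(zip(self.pair_moduli, self.periods)):
            rows.append(
                {"subgroup": subgroup, "order": self.order, "root_index": i,
                 "modulus": m, "period_years": per, "kind": "complex-pair"}
            )
        for j, m in enumerate(self.real_root_moduli):
            rows.append(
                {"subgroup": subgroup, "order": self.order,
                 "root_index": len(self.pair_moduli) + j, "modulus": m,
                 "period_years": np.nan, "kind": "real"}
            )
        df = pd.DataFrame(rows)
        df["label"] = classify_decay(self)
        return df


def cycle_lengths(ar_coeffs) -> CycleReport:
    """Characteristic roots, damping moduli and quasi-periods for (theta_1..theta_p)."""
    theta = np.atleast_1d(np.asarray(ar_coeffs, dtype=float))
    if theta.ndim != 1 or len(theta) < 1:
        raise CycleError("need at least one AR coefficient")
    if np.all(theta == 0):
        raise CycleError("all-zero AR coefficients have no characteristic roots")
    poly = np.concatenate([[1.0], -theta])
    roots = np.roots(poly)
    tol = 1e-9
    complex_roots = roots[roots.imag > tol]  # one per conjugate pair
    real_roots = np.real(roots[np.abs(roots.imag) <= tol])
    moduli = np.abs(complex_roots)
    order = np.argsort(-moduli)
    complex_roots = complex_roots[order]
    moduli = moduli[order]
    omegas = np.abs(np.angle(complex_roots))
    periods = 2.0 * np.pi / omegas
    return CycleReport(
        order=len(theta),
        roots=roots,
        pair_moduli=moduli,
        periods=periods,
        real_root_moduli=np.abs(real_roots),
        real_roots=real_roots,
        stationary=bool(np.all(np.abs(roots) < 1.0)),
    )


def coefficients_from_roots(moduli_omegas, real_roots=()) -> np.ndarray:
    """Build (theta_1..theta_p) from complex pairs (r, w) and real roots.

    Inverse of :func:`cycle_lengths`; useful for constructing processes with
    a prescribed quasi-period, e.g. ``r=0.8, w=2 pi/3.3`` gives an AR(2) that
    cycles every 3.3 years.
    """
    roots = []
    for r, w in moduli_omegas:
        roots.extend([r * np.exp(1j * w), r * np.exp(-1j * w)])
    roots.extend(real_roots)
    poly = np.real(np.poly(np.asarray(roots, dtype=complex)))
    return -poly[1:]


def ar2_period(theta1: float, theta2: float) -> float:
    """Closed-form AR(2) quasi-period 2 pi / arccos(theta_1 / (2 sqrt(-theta_2))).

    Defined only for complex roots, i.e. theta_1^2 + 4 theta_2 < 0.
    """
    if theta1**2 + 4 * theta2 >= 0:
        raise CycleError("AR(2) roots are real; no quasi-period")
    return 2.0 * np.pi / np.arccos(theta1 / (2.0 * np.sqrt(-theta2)))


def classify_decay(report: CycleReport) -> str:
    """{'pure-cycle', 'cycle-with-decay', 'decay-only', 'nonstationary'}.

    A decay component is present iff a real positive root exists; any root
    modulus >= 1 makes the process nonstationary.
    """
    if not report.stationary:
        return "nonstationary"
    has_cycle = len(report.pair_moduli) > 0
    has_decay = bool(np.any(report.real_roots > 0))
    if has_cycle and has_decay:
        return "cycle-with-decay"
    if has_cycle:
        return "pure-cycle"
    return "decay-only"


def posterior_periods(theta_draws) -> pd.DataFrame:
    """Propagate coefficient uncertainty: per-draw root finding.

    ``theta_draws`` is (n_draws, p); returns one row per draw and complex
    pair with modulus and period, for posterior summaries of cycle length.
    """
    rows = []
    for i, th in enumerate(np.asarray(theta_draws, dtype=float)):
        if np.all(th == 0):
            continue
        rep = cycle_lengths(th)
        for m, per in zip(rep.pair_moduli, rep.periods):
            rows.append({"draw": i, "modulus": m, "period_years": per})
    return pd.DataFrame(rows)
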