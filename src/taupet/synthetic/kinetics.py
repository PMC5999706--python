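"""Regional tracer kinetics for the synthetic PET phantom.

The model is a linear uptake ramp to a peak followed by bi-exponential
washout.  No absolute activity calibration is attempted; curves are in
arbitrary units and everything downstream is ratio-based.

The bi-exponential tail can be calibrated so that the fraction of peak
activity remaining at two post-injection times hits prescribed targets —
the phantom's handle for emulating tracers with distinct washout speed
(a fast arylquinoline-like profile retaining ~57%/11% of peak at
10/60 min, and a slower pyridoindole-like profile retaining ~72%/26%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = ["KineticParams"]


@dataclass(frozen=True)
class KineticParams:
    """Uptake-washout curve: linear rise to a peak, bi-exponential decay.

    Parameters
    ----------
    peak_time_min : float
        Time of the activity peak (minutes post-injection).
    peak_value : float
        Activity at the peak (arbitrary units), >= 0.
    fast_fraction : float
        Fraction of the peak carried by the fast-clearing component.
    k_fast_per_min, k_slow_per_min : float
        Clearance rate constants, k_fast >= k_slow >= 0.
    """

    peak_time_min: float
    peak_value: float
    fast_fraction: float = 0.5
    k_fast_per_min: float = 0.1
    k_slow_per_min: float = 0.01

    def __post_init__(self):
        if self.peak_time_min <= 0:
            raise ValueError("peak_time_min must be positive")
        if self.peak_value < 0:
            raise ValueError("peak_value must be non-negative")
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise ValueError("fast_fraction must be in [0, 1]")
        if self.k_fast_per_min < 0 or self.k_slow_per_min < 0:
            raise ValueError("rate constants must be non-negative")
        if self.k_fast_per_min < self.k_slow_per_min:
            raise ValueError("k_fast must be >= k_slow")

    def fraction_of_peak(self, t_min) -> np.ndarray:
        """Normalized curve value (in [0, 1] after the peak) at time t."""
        t = np.asarray(t_min, dtype=float)
        tau = t - self.peak_time_min
        decay = self.fast_fraction * np.exp(-self.k_fast_per_min * np.maximum(tau, 0.0)) + (
            1.0 - self.fast_fraction
        ) * np.exp(-self.k_slow_per_min * np.maximum(tau, 0.0))
        rise = np.clip(t / self.peak_time_min, 0.0, 1.0)
        return np.where(tau < 0, rise, decay)

    def curve(self, t_min) -> np.ndarray:
        """Activity (arbitrary units) at time t; non-negative for t >= 0."""
        return self.peak_value * self.fraction_of_peak(t_min)

    def scaled(self, factor: float) -> "KineticParams":
        """Same shape, peak multiplied by ``factor`` (e.g. genotype effect)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return replace(self, peak_value=self.peak_value * factor)

    @classmethod
    def from_washout_targets(
        cls,
        peak_time_min: float,
        peak_value: float,
        targets: tuple[tuple[float, float], tuple[float, float]],
        fast_fraction: float = 0.5,
    ) -> "KineticParams":
        """Calibrate (k_fast, k_slow) so fraction-of-peak hits two targets.

        ``targets`` is ``((t1_min, frac1), (t2_min, frac2))`` with
        ``t1 < t2`` and ``1 > frac1 > frac2 > 0``, both times after the
        peak.  Solved exactly (nested bisection); raises if infeasible.
        """
        (t1, g1), (t2, g2) = targets
        if not (t1 > peak_time_min and t2 > t1):
            raise ValueError("target times must be ordered and after the peak")
        if not (0.0 < g2 < g1 < 1.0):
            raise ValueError("target fractions must satisfy 0 < frac2 < frac1 < 1")
        f = fast_fraction
        tau1, tau2 = t1 - peak_time_min, t2 - peak_time_min

        def kf_given_ks(ks: float) -> float:
            # solve f*exp(-kf*tau1) + (1-f)*exp(-ks*tau1) = g1 for kf >= ks
            rest = (1.0 - f) * np.exp(-ks * tau1)
            target = g1 - rest
            if target <= 0 or target >= f * np.exp(-ks * tau1):
                raise ValueError("washout targets infeasible for this fast_fraction")
            return -np.log(target / f) / tau1

        def residual(ks: float) -> float:
            kf = kf_given_ks(ks)
            return f * np.exp(-kf * tau2) + (1.0 - f) * np.exp(-ks * tau2) - g2

        # A bi-exponential tail through both targets exists iff the tail is
        # heavier than the mono-exponential through target 1, i.e.
        # g1**(tau2/tau1) < g2.  The root in ks then lies between the rate
        # at which the slow component alone explains target 2 (residual > 0)
        # and the mono-exponential rate through target 1 (residual < 0).
        if g1 ** (tau2 / tau1) >= g2:
            raise ValueError(
                f"washout targets {targets} decay faster than a single exponential; "
                "a bi-exponential tail cannot be slower at the late time"
            )
        k_mono = -np.log(g1) / tau1
        ks_slow_only = -np.log(g2 / (1.0 - f)) / tau2 if g2 < (1.0 - f) else 1e-12
        lo = max(ks_slow_only, 1e-12)
        hi = 0.999 * k_mono
        try:
            r_lo, r_hi = residual(lo), residual(hi)
        except ValueError as exc:
            raise ValueError(f"cannot calibrate washout to {targets}: {exc}") from exc
        if r_lo * r_hi > 0:
            raise ValueError(f"washout targets {targets} infeasible with fast_fraction={f}")
        ks = brentq(residual, lo, hi, xtol=1e-14)
        kf = kf_given_ks(ks)
        return cls(peak_time_min, peak_value, f, float(kf), float(ks))
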