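"""Single-component cosinor rhythmometry with a fixed period.

The cosinor model describes a circadian rhythm as

    y(t) = M + A * cos(omega * (t - phi)),     omega = 2*pi / period,

with mesor M (rhythm-adjusted mean), amplitude A >= 0 (half the
peak-to-trough range) and acrophase phi (clock time of the fitted peak,
hours in [0, period)). The fit is linearised as

    y = M + b1 * cos(omega t) + b2 * sin(omega t)

and solved by ordinary least squares; then A = sqrt(b1^2 + b2^2) and
phi = atan2(b2, b1) / omega. The acrophase confidence interval comes from
the delta method on (b1, b2); the zero-amplitude test is the 2-df F test of
b1 = b2 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def format_clock(hours: float) -> str:
    """Fractional hours as hh:mm, flooring to the minute (10.4 -> '10:24')."""
    total = int(np.floor(float(hours) * 60.0 + 1e-9)) % (24 * 60)
    h, m = divmod(total, 60)
    return f"{h:02d}:{m:02d}"


@dataclass
class CosinorResults:
    """Fitted single-component cosinor."""

    mesor: float
    amplitude: float
    acrophase: float  # hours in [0, period)
    period: float
    acrophase_ci: tuple[float, float]  # hours, may straddle midnight
    acrophase_se: float  # hours
    amplitude_p: float
    residual_sd: float
    n_obs: int
    beta_cos: float
    beta_sin: float

    def predict(self, t_hours) -> np.ndarray:
        t = np.asarray(t_hours, dtype=float)
        omega = 2 * np.pi / self.period
        return self.mesor + self.amplitude * np.cos(omega * (t - self.acrophase))

    def acrophase_str(self) -> str:
        """Acrophase and CI in the 'hh:mm (hh:mm to hh:mm)' display form."""
        lo, hi = self.acrophase_ci
        if np.isnan(lo) or np.isnan(hi):
            return format_clock(self.acrophase)
        return f"{format_clock(self.acrophase)} ({format_clock(lo)} to {format_clock(hi)})"

    def summary(self) -> str:
        lines = [
            f"Cosinor fit (period {self.period:g} h)",
            "=" * 45,
            f"{'mesor':<14}{self.mesor: .4f}",
            f"{'amplitude':<14}{self.amplitude: .4f}",
            f"{'acrophase':<14}{self.acrophase: .4f} h = {format_clock(self.acrophase)}",
            f"{'acrophase CI':<14}{self.acrophase_str()}",
            f"{'amplitude p':<14}{self.amplitude_p:.3g}",
            f"{'residual sd':<14}{self.residual_sd: .4f}",
            f"{'N obs':<14}{self.n_obs:d}",
        ]
        return "\n".join(lines)


class Cosinor:
    """Model object for a fixed-period cosinor fit of y against time of day.

    ``t_hours`` may be clock time or internal (chronotype-aligned) time, in
    fractional hours; values outside [0, period) are wrapped by the cosine.
    """

    def __init__(self, t_hours, y, period: float = 24.0) -> None:
        t = np.asarray(t_hours, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(t) & np.isfinite(y)
        self.t, self.y = t[keep], y[keep]
        self.period = float(period)
        if period <= 0:
            raise ValueError("period must be positive")
        if len(self.t) < 4:
            raise ValueError("need at least 4 observations")
        if np.unique(np.mod(self.t, self.period)).size < 3:
            raise ValueError("rhythm unidentifiable: too few distinct time points")

    @classmethod
    def from_dataframe(cls, data, t: str, y: str, period: float = 24.0) -> "Cosinor":
        return cls(data[t], data[y], period=period)

    def fit(self, alpha: float = 0.05) -> CosinorResults:
        omega = 2 * np.pi / self.period
        n = len(self.t)
        X = np.column_stack([np.ones(n), np.cos(omega * self.t), np.sin(omega * self.t)])
        if np.linalg.matrix_rank(X) < 3:
            raise ValueError("rhythm unidentifiable: design matrix is rank deficient")
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        resid = self.y - X @ beta
        rss = float(resid @ resid)
        dfe = n - 3
        sigma2 = rss / dfe
        mesor, b1, b2 = (float(b) for b in beta)
        amplitude = float(np.hypot(b1, b2))
        acrophase = float((np.arctan2(b2, b1) / omega) % self.period)
        # delta method on theta = atan2(b2, b1)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        if amplitude > 0 and sigma2 > 0:
            grad = np.array([-b2, b1]) / amplitude**2
            var_theta = float(grad @ cov[1:, 1:] @ grad)
            se_hours = np.sqrt(max(var_theta, 0.0)) / omega
            zc = sps.norm.ppf(1 - alpha / 2)
            ci = (acrophase - zc * se_hours, acrophase + zc * se_hours)
        else:
            se_hours, ci = np.nan, (np.nan, np.nan)
        rss0 = float(((self.y - self.y.mean()) ** 2).sum())
        if sigma2 > 0:
            f_stat = ((rss0 - rss) / 2.0) / sigma2
            amp_p = float(sps.f.sf(f_stat, 2, dfe))
        else:
            amp_p = 0.0 if amplitude > 0 else 1.0
        return CosinorResults(
            mesor=mesor,
            amplitude=amplitude,
            acrophase=acrophase,
            period=self.period,
            acrophase_ci=(float(ci[0]), float(ci[1])),
            acrophase_se=float(se_hours),
            amplitude_p=amp_p,
            residual_sd=float(np.sqrt(sigma2)),
            n_obs=n,
            beta_cos=b1,
            beta_sin=b2,
        )


def cosinor_fit(t_hours, y, period: float = 24.0, alpha: float = 0.05) -> CosinorResults:
    """Convenience wrapper: build the model and fit in one call."""
    return Cosinor(t_hours, y, period=period).fit(alpha=alpha)
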