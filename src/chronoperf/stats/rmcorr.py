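"""Repeated-measures correlation via the ANCOVA common-slope formulation.

Aggregating repeated observations from several subjects and correlating the
pooled values violates independence and can even reverse the within-subject
relationship (Simpson's paradox). The repeated-measures correlation r_rm
removes between-subject variability by fitting

    y_ij = alpha_i + beta * x_ij + eps_ij

(subject-specific intercepts, one common slope) by least squares, and
reports the within-subject effect size

    r_rm = sign(beta) * sqrt(SS_slope / (SS_slope + SS_error)),

with degrees of freedom df = N - k - 1 for N observations from k subjects.
Significance comes from the F statistic on (1, df); the 95% CI uses the
Fisher z-transform with standard error 1/sqrt(df - 1), or optionally a
bootstrap over subjects.

Subjects whose x is constant within subject contribute no information about
the slope (their centred x is identically zero) but still enter the error
term and the df, exactly as in the ANCOVA; if *no* subject has within-
subject x variation the model is unidentifiable and fitting raises.

``rmcorr_lstsq`` recomputes the same quantities by explicit design-matrix
least squares (one indicator column per subject) and exists as an
independent verification oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def _clean(x, y, subjects):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    if not (len(x) == len(y) == len(subjects)):
        raise ValueError("x, y and subjects must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep], subjects[keep]


@dataclass
class RmcorrResults:
    """Fitted repeated-measures correlation."""

    r_rm: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float
    n_obs: int
    n_subjects: int
    slope: float
    ci_method: str = "fisher"

    @property
    def r(self) -> float:
        return self.r_rm

    def conf_int(self) -> tuple[float, float]:
        return self.ci_low, self.ci_high

    def summary(self) -> str:
        lines = [
            "Repeated-measures correlation",
            "=" * 45,
            f"{'r_rm':<14}{self.r_rm: .4f}",
            f"{'df':<14}{self.df:d}",
            f"{'p-value':<14}{self.p_value:.3g}",
            f"{'95% CI':<14}({self.ci_low:.4f}, {self.ci_high:.4f}) [{self.ci_method}]",
            f"{'common slope':<14}{self.slope: .6g}",
            f"{'N obs':<14}{self.n_obs:d}",
            f"{'N subjects':<14}{self.n_subjects:d}",
        ]
        return "\n".join(lines)


class RepeatedMeasuresCorrelation:
    """Model object: build from paired series and a subject id series.

    Missing pairs are removed listwise at construction. ``fit()`` returns a
    :class:`RmcorrResults`.
    """

    def __init__(self, x, y, subjects) -> None:
        self.x, self.y, self.subjects = _clean(x, y, subjects)
        self.subject_index = pd.factorize(self.subjects)[0]
        self.n_obs = len(self.x)
        self.n_subjects = int(self.subject_index.max()) + 1 if self.n_obs else 0
        self.df = self.n_obs - self.n_subjects - 1
        if self.df < 1:
            raise ValueError(
                f"need N - k - 1 >= 1 (N={self.n_obs} observations, k={self.n_subjects} subjects)"
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, x: str, y: str, subject: str) -> "RepeatedMeasuresCorrelation":
        return cls(data[x], data[y], data[subject])

    def _centered(self):
        idx = self.subject_index
        k = self.n_subjects
        counts = np.bincount(idx, minlength=k)
        xc = self.x - (np.bincount(idx, weights=self.x, minlength=k) / counts)[idx]
        yc = self.y - (np.bincount(idx, weights=self.y, minlength=k) / counts)[idx]
        return xc, yc

    def fit(
        self,
        ci_method: str = "fisher",
        alpha: float = 0.05,
        n_boot: int = 2000,
        seed: int | None = None,
    ) -> RmcorrResults:
        xc, yc = self._centered()
        sxx = float(xc @ xc)
        if sxx <= 0:
            raise ValueError("no within-subject variation in x")
        sxy = float(xc @ yc)
        syy = float(yc @ yc)
        slope = sxy / sxx
        ss_slope = sxy * sxy / sxx
        ss_error = max(syy - ss_slope, 0.0)
        denom = ss_slope + ss_error
        r = 0.0 if denom == 0 else np.sign(slope) * np.sqrt(ss_slope / denom)
        if ss_error == 0:
            p = 0.0 if ss_slope > 0 else 1.0
        else:
            f_stat = ss_slope / (ss_error / self.df)
            p = float(sps.f.sf(f_stat, 1, self.df))
        if ci_method == "fisher":
            lo, hi = self._fisher_ci(r, alpha)
        elif ci_method == "bootstrap":
            lo, hi = self._bootstrap_ci(alpha, n_boot, seed)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        return RmcorrResults(
            r_rm=float(r),
            df=self.df,
            p_value=p,
            ci_low=lo,
            ci_high=hi,
            n_obs=self.n_obs,
            n_subjects=self.n_subjects,
            slope=slope,
            ci_method=ci_method,
        )

    def _fisher_ci(self, r: float, alpha: float) -> tuple[float, float]:
        if self.df <= 1 or abs(r) >= 1:
            return (np.nan, np.nan) if self.df <= 1 else (r, r)
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(self.df - 1)
        zcrit = sps.norm.ppf(1 - alpha / 2)
        return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))

    def _bootstrap_ci(self, alpha: float, n_boot: int, seed: int | None) -> tuple[float, float]:
        rng = np.random.default_rng(seed)
        ids = np.arange(self.n_subjects)
        rows_by_subject = [np.flatnonzero(self.subject_index == i) for i in ids]
        reps = []
        for _ in range(n_boot):
            pick = rng.choice(ids, size=self.n_subjects, replace=True)
            xs, ys, ss = [], [], []
            for newid, sid in enumerate(pick):
                rows = rows_by_subject[sid]
                xs.append(self.x[rows])
                ys.append(self.y[rows])
                ss.append(np.full(len(rows), newid))
            try:
                m = RepeatedMeasuresCorrelation(np.concatenate(xs), np.concatenate(ys), np.concatenate(ss))
                reps.append(m.fit(ci_method="fisher").r_rm)
            except ValueError:
                continue
        if not reps:
            return np.nan, np.nan
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)


def rmcorr(x, y, subjects, **fit_kwargs) -> RmcorrResults:
    """Convenience wrapper: build the model and fit in one call."""
    return RepeatedMeasuresCorrelation(x, y, subjects).fit(**fit_kwargs)


def rmcorr_lstsq(x, y, subjects, alpha: float = 0.05) -> RmcorrResults:
    """Verification oracle: same contract as :func:`rmcorr`, computed by
    explicit least squares on [subject indicators | x] versus the reduced
    model without x. Intended for tests on small inputs."""
    x, y, subjects = _clean(x, y, subjects)
    idx = pd.factorize(subjects)[0]
    n, k = len(x), int(idx.max()) + 1
    df = n - k - 1
    if df < 1:
        raise ValueError("insufficient degrees of freedom")
    dummies = np.eye(k)[idx]
    full = np.column_stack([dummies, x])
    beta_full, *_ = np.linalg.lstsq(full, y, rcond=None)
    rss_full = float(((y - full @ beta_full) ** 2).sum())
    beta_red, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    rss_red = float(((y - dummies @ beta_red) ** 2).sum())
    ss_slope = max(rss_red - rss_full, 0.0)
    slope = float(beta_full[-1])
    denom = ss_slope + rss_full
    # Unidentifiable slope: x lies in the span of the subject indicators.
    if np.linalg.matrix_rank(full) <= k:
        raise ValueError("no within-subject variation in x")
    r = 0.0 if denom == 0 else np.sign(slope) * np.sqrt(ss_slope / denom)
    if rss_full == 0:
        p = 0.0 if ss_slope > 0 else 1.0
    else:
        p = float(sps.f.sf(ss_slope / (rss_full / df), 1, df))
    if df > 1 and abs(r) < 1:
        z, se = np.arctanh(r), 1.0 / np.sqrt(df - 1)
        zc = sps.norm.ppf(1 - alpha / 2)
        lo, hi = float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))
    else:
        lo = hi = np.nan
    return RmcorrResults(
        r_rm=float(r), df=df, p_value=p, ci_low=lo, ci_high=hi,
        n_obs=n, n_subjects=k, slope=slope,
    )
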