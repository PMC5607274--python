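"""Four-parameter-logistic (4PL) dose-response fitting and hit calling.

The model is

    R(c) = B + (T - B) / (1 + (c / IC50)^h)

with bottom ``B`` and top ``T`` in % inhibition, Hill slope ``h`` and the
half-maximal concentration ``IC50`` in uM; ``R(IC50) = (B + T)/2``
exactly.  Fitting is nonlinear least squares on log10 concentration with
the IC50 parameterized as log10(IC50), so the delta-method confidence
interval is read directly off the parameter covariance and
exponentiated.  A compound is a hit when its curve shows a genuine
dose-response relationship (DRR) and the IC50 point estimate is below
the potency criterion (10 uM by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, InputError

HIT_THRESHOLD_UM = 10.0


def four_pl(c, bottom, top, hill, ic50):
    """Evaluate the 4PL response at concentration ``c`` (uM)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def _model_log(logc, bottom, top, hill, log_ic50):
    # identical to four_pl with c = 10**logc, ic50 = 10**log_ic50
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


class FourPLModel:
    """4PL dose-response model bound to one compound's data.

    Parameters
    ----------
    data : DataFrame
        Columns ``concentration_uM`` and ``inhibition_pct`` (one row per
        replicate well; a ``replicate`` column is allowed and ignored).

    Examples
    --------
    >>> res = FourPLModel(table).fit()
    >>> res.ic50, res.ic50_ci
    """

    def __init__(self, data: pd.DataFrame):
        for col in ("concentration_uM", "inhibition_pct"):
            if col not in data.columns:
                raise InputError(f"dose-response table lacks column {col!r}")
        conc = np.asarray(data["concentration_uM"], dtype=float)
        if np.any(conc <= 0):
            raise FitError("all concentrations must be strictly positive")
        if len(np.unique(conc)) < 4:
            raise FitError(
                f"need >= 4 distinct concentrations, got {len(np.unique(conc))}"
            )
        self.data = data
        self.conc = conc
        self.logc = np.log10(conc)
        self.resp = np.asarray(data["inhibition_pct"], dtype=float)

    def _initializer(self):
        # R(c->0) = top, R(c->inf) = bottom under the (c/ic50)^h form with
        # h > 0; starting from the low/high-concentration means handles
        # rising inhibition curves (fitted hill < 0) equally well
        means = pd.Series(self.resp).groupby(self.logc).mean()
        t0 = float(means.iloc[0])
        b0 = float(means.iloc[-1])
        half = (b0 + t0) / 2.0
        lic0 = float(means.index[np.argmin(np.abs(means.to_numpy() - half))])
        return [b0, t0, 1.0, lic0]

    def fit(self, ci_method: str = "delta", n_boot: int = 500,
            seed: int = 0) -> "FourPLResults":
        """Least-squares fit; deterministic given the data.

        ``ci_method`` is ``"delta"`` (default, from the fit covariance on
        log10 IC50) or ``"bootstrap"`` (resample residuals ``n_boot``
        times, percentile interval).
        """
        p0 = self._initializer()
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    _model_log, self.logc, self.resp, p0=p0,
                    maxfev=20000, ftol=1e-8, xtol=1e-8,
                )
        except RuntimeError:
            popt, pcov = np.array(p0), np.full((4, 4), np.nan)
            converged = False
        bottom, top, hill, log_ic50 = popt
        resid = self.resp - _model_log(self.logc, *popt)
        dof = max(len(self.resp) - 4, 1)
        resid_sd = float(np.sqrt(np.sum(resid ** 2) / dof))
        if converged:
            if ci_method == "delta":
                se = float(np.sqrt(pcov[3, 3])) if np.isfinite(pcov[3, 3]) else np.nan
                if not np.isfinite(se) and resid_sd < 1e-6:
                    se = 0.0  # exact fit: the interval degenerates to the estimate
                tcrit = stats.t.ppf(0.975, dof)
                lo, hi = log_ic50 - tcrit * se, log_ic50 + tcrit * se
            elif ci_method == "bootstrap":
                lo, hi = self._bootstrap_ci(popt, resid, n_boot, seed)
            else:
                raise InputError(f"unknown ci_method {ci_method!r}")
            with np.errstate(over="ignore"):  # hopeless fits: CI bound -> inf
                ci = (float(10.0 ** np.float64(lo)), float(10.0 ** np.float64(hi)))
        else:
            ci = (np.nan, np.nan)
        return FourPLResults(
            model=self, bottom=float(bottom), top=float(top), hill=float(hill),
            ic50=float(10.0 ** log_ic50), log_ic50=float(log_ic50),
            ic50_ci=ci, resid_sd=resid_sd, converged=converged, cov=pcov,
        )

    def _bootstrap_ci(self, popt, resid, n_boot, seed):
        rng = np.random.default_rng(seed)
        fitted = _model_log(self.logc, *popt)
        draws = []
        for _ in range(n_boot):
            y = fitted + rng.choice(resid, size=len(resid), replace=True)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p, _ = optimize.curve_fit(_model_log, self.logc, y,
                                              p0=popt, maxfev=5000)
                draws.append(p[3])
            except RuntimeError:
                continue
        if len(draws) < n_boot // 2:
            return np.nan, np.nan
        return tuple(np.percentile(draws, [2.5, 97.5]))


@dataclass
class FourPLResults:
    """Fitted 4PL curve with IC50 interval and DRR diagnostics."""

    model: FourPLModel
    bottom: float
    top: float
    hill: float
    ic50: float
    log_ic50: float
    ic50_ci: tuple
    resid_sd: float
    converged: bool
    cov: np.ndarray

    @property
    def span(self) -> float:
        """Fitted response span |top - bottom| in % inhibition."""
        return abs(self.top - self.bottom)

    def predict(self, conc) -> np.ndarray:
        return four_pl(conc, self.bottom, self.top, self.hill, self.ic50)

    def assess_drr(self, min_span: float = 30.0, trend_alpha: float = 0.05):
        """Delegates to :func:`assess_drr`."""
        return assess_drr(self, min_span=min_span, trend_alpha=trend_alpha)

    @property
    def drr_ok(self) -> bool:
        return self.assess_drr()[0]

    def summary(self) -> str:
        ok, reasons = self.assess_drr()
        lines = [
            "4PL dose-response fit",
            "=" * 42,
            f"{'bottom (%)':<22}{self.bottom:>12.3f}",
            f"{'top (%)':<22}{self.top:>12.3f}",
            f"{'hill slope':<22}{self.hill:>12.3f}",
            f"{'IC50 (uM)':<22}{self.ic50:>12.4g}",
            f"{'95% CI (uM)':<22}[{self.ic50_ci[0]:.4g}, {self.ic50_ci[1]:.4g}]",
            f"{'residual SD (%)':<22}{self.resid_sd:>12.3f}",
            f"{'converged':<22}{str(self.converged):>12}",
            f"{'DRR ok':<22}{str(ok):>12}"
            + (f"  ({', '.join(reasons)})" if reasons else ""),
        ]
        return "\n".join(lines)


def fit_4pl(data: pd.DataFrame, ci_method: str = "delta") -> FourPLResults:
    """Convenience wrapper: ``FourPLModel(data).fit(ci_method)``."""
    return FourPLModel(data).fit(ci_method=ci_method)


def assess_drr(fit: FourPLResults, min_span: float = 30.0,
               trend_alpha: float = 0.05):
    """Decide whether a fit shows a real dose-response relationship.

    Requires (a) fitted span |top - bottom| >= ``min_span`` points and
    (b) a one-sided Spearman trend test of response against
    concentration rejecting flatness at ``trend_alpha``.  Returns
    ``(ok, reasons)`` where ``reasons`` lists the failed criteria.
    """
    reasons = []
    if not fit.converged:
        reasons.append("no convergence")
    if fit.span < min_span:
        reasons.append("span")
    resp = fit.model.resp
    if np.ptp(resp) == 0:
        reasons.append("trend")
    else:
        # two-sided: a genuine dose-response may rise or fall with
        # concentration depending on the sign convention of the readout
        rho = stats.spearmanr(fit.model.logc, resp)
        if not (rho.pvalue < trend_alpha):
            reasons.append("trend")
    return len(reasons) == 0, reasons


def call_hits(fits: dict, hit_threshold: float = HIT_THRESHOLD_UM,
              min_span: float = 30.0, trend_alpha: float = 0.05) -> pd.DataFrame:
    """Call hits over a ``{compound_id: FourPLResults}`` mapping.

    A compound is a hit iff its DRR is acceptable and the IC50 point
    estimate is strictly below ``hit_threshold`` uM.  Non-hits carry a
    reason: ``"insufficient potency"`` or ``"no DRR"``.
    """
    rows = []
    for cid in sorted(fits):
        fit = fits[cid]
        ok, _ = assess_drr(fit, min_span=min_span, trend_alpha=trend_alpha)
        if not ok:
            hit, reason = False, "no DRR"
        elif fit.ic50 < hit_threshold:
            hit, reason = True, ""
        else:
            hit, reason = False, "insufficient potency"
        rows.append((cid, fit.ic50, fit.ic50_ci[0], fit.ic50_ci[1], ok, hit, reason))
    return pd.DataFrame(rows, columns=["compound_id", "ic50_uM", "ci_lower_uM",
                                       "ci_upper_uM", "drr_ok", "hit", "reason"])


def call_hits_from_table(table: pd.DataFrame,
                         hit_threshold: float = HIT_THRESHOLD_UM) -> pd.DataFrame:
    """Call hits from already-summarized fits.

    ``table`` needs ``compound_id``, ``ic50_uM`` (NaN allowed when the
    curve had no DRR) and boolean ``drr_ok``.  Same rule as
    :func:`call_hits`: hit iff DRR ok and IC50 strictly below the
    threshold; the point estimate decides, not the CI bound.
    """
    for col in ("compound_id", "ic50_uM", "drr_ok"):
        if col not in table.columns:
            raise InputError(f"fit table lacks column {col!r}")
    out = table.copy()
    drr = out["drr_ok"].astype(bool)
    potent = out["ic50_uM"] < hit_threshold
    out["hit"] = drr & potent
    out["reason"] = np.where(~drr, "no DRR",
                             np.where(~potent, "insufficient potency", ""))
    return out
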