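"""Liability-threshold model linking survival between two environments.

Each accession i carries a Gaussian liability N(mu_i, sigma_E) in
environment E, and survives iff its liability falls below the
environment's threshold tau_E (the harsher environment has the lower
threshold, so it kills more). Writing survival in the milder environment
A as p_A,i = Phi((tau_A - mu_i)/sigma_A), the survival probability in the
harsher environment B follows

    p_B,i = 1/2 · erfc( alpha/sqrt(2) + beta · erfcinv(2 · p_A,i) )

with alpha = (tau_A - tau_B)/sigma_B and beta = sigma_A/sigma_B — the
only identifiable combinations of the per-environment thresholds and
scales (the accession means mu_i live only in the simulator). alpha = 0,
beta = 1 is the identity map; alpha > 0 means uniformly harsher.

Fitting is weighted nonlinear least squares of predicted against
observed harsh-environment survival, weights given by binomial trial
counts, with a coarse multi-start grid over (alpha, beta) to avoid local
minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


def predict_harsh(
    p_mild: float | np.ndarray, alpha: float, beta: float
) -> float | np.ndarray:
    """Harsh-environment survival implied by mild-environment survival.

    Strictly increasing, maps (0,1) -> (0,1). Boundary inputs 0 and 1 are
    handled by their limits (0 and 1 respectively) with a warning.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    p = np.asarray(p_mild, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("survival probabilities must lie in [0, 1]")
    if ((p == 0) | (p == 1)).any():
        warnings.warn("boundary survival probabilities mapped by their limits")
    with np.errstate(over="ignore"):
        out = 0.5 * special.erfc(alpha / np.sqrt(2.0) + beta * special.erfcinv(2.0 * p))
    # keep strictly-interior inputs strictly interior despite float saturation
    interior = (p > 0) & (p < 1)
    out = np.where(interior & (out <= 0.0), np.nextafter(0.0, 1.0), out)
    out = np.where(interior & (out >= 1.0), np.nextafter(1.0, 0.0), out)
    return float(out) if out.ndim == 0 else out


def shrink_boundary(survived: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Half-count-corrected survival: p = (k + 0.5)/(n + 1) at k in {0, n}.

    Observed survival of exactly 0 or 1 would push erfcinv to infinity;
    the half-count correction keeps boundary accessions usable.
    """
    survived = np.asarray(survived, dtype=float)
    total = np.asarray(total, dtype=float)
    p = survived / total
    at_bound = (survived == 0) | (survived == total)
    p[at_bound] = (survived[at_bound] + 0.5) / (total[at_bound] + 1.0)
    return p


@dataclass
class LiabilityResults:
    """Fitted (alpha, beta) with standard errors and diagnostics."""

    alpha: float
    beta: float
    bse: np.ndarray  # standard errors of (alpha, beta)
    converged: bool
    n_obs: int
    ssr: float  # weighted sum of squared residuals
    cov_params: np.ndarray

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta])

    def predict(self, p_mild: float | np.ndarray) -> float | np.ndarray:
        return predict_harsh(p_mild, self.alpha, self.beta)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Liability-threshold model (two environments)",
            "=" * 56,
            f"observations: {self.n_obs}    converged: {self.converged}",
            f"weighted SSR: {self.ssr:.6g}",
            "",
            f"{'param':<8}{'estimate':>12}{'std err':>12}{'[0.025':>12}{'0.975]':>12}",
            "-" * 56,
        ]
        for name, val, se, (lo, hi) in zip(
            ("alpha", "beta"), self.params, self.bse, ci
        ):
            lines.append(f"{name:<8}{val:>12.4f}{se:>12.4f}{lo:>12.4f}{hi:>12.4f}")
        lines += [
            "",
            "alpha = (tau_mild - tau_harsh)/sigma_harsh;"
            " beta = sigma_mild/sigma_harsh",
        ]
        return "\n".join(lines)


class LiabilityModel:
    """Weighted nonlinear least squares for the two-environment model.

    Parameters
    ----------
    p_mild : array
        Mild-environment survival probability per accession, strictly
        inside (0, 1) (apply :func:`shrink_boundary` first if needed).
    p_harsh : array
        Observed harsh-environment survival per accession.
    trials : array or None
        Binomial trial count per accession; used as weights when
        ``weighted`` (the default). ``None`` with ``weighted`` falls back
        to equal weights.
    subset : boolean array, optional
        Restrict the fit to a subset of accessions.
    """

    def __init__(
        self,
        p_mild: np.ndarray,
        p_harsh: np.ndarray,
        trials: np.ndarray | None = None,
        weighted: bool = True,
        subset: np.ndarray | None = None,
    ) -> None:
        p_mild = np.asarray(p_mild, dtype=float)
        p_harsh = np.asarray(p_harsh, dtype=float)
        if p_mild.shape != p_harsh.shape:
            raise ValueError("p_mild and p_harsh must be aligned")
        if subset is not None:
            subset = np.asarray(subset, dtype=bool)
            p_mild, p_harsh = p_mild[subset], p_harsh[subset]
            if trials is not None:
                trials = np.asarray(trials)[subset]
        inside = (p_mild > 0) & (p_mild < 1)
        if inside.sum() < 3:
            raise ValueError(
                "need at least 3 accessions with mild-environment survival "
                "strictly inside (0, 1)"
            )
        self.p_mild = p_mild[inside]
        self.p_harsh = p_harsh[inside]
        if trials is not None:
            self.trials = np.asarray(trials, dtype=float)[inside]
        else:
            self.trials = None
        self.weights = (
            self.trials if (weighted and self.trials is not None) else np.ones_like(self.p_mild)
        )
        if np.allclose(self.p_mild, self.p_mild[0]) and np.allclose(
            self.p_harsh, self.p_harsh[0]
        ):
            raise ValueError("degenerate data: all survival pairs identical")

    # coarse multi-start grid; beta strictly positive
    _ALPHA_STARTS = np.linspace(-3.0, 3.0, 7)
    _BETA_STARTS = np.array([0.25, 0.5, 1.0, 2.0, 4.0])

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        alpha, beta = params
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = predict_harsh(self.p_mild, alpha, beta)
        return np.sqrt(self.weights) * (self.p_harsh - pred)

    def fit(self, seed: int = 0, n_random_starts: int = 3) -> LiabilityResults:
        """Fit (alpha, beta) by multi-start weighted least squares."""
        rng = np.random.default_rng(seed)
        starts = [(a, b) for a in self._ALPHA_STARTS for b in self._BETA_STARTS]
        starts += [
            (rng.uniform(-3, 3), rng.uniform(0.1, 4.0)) for _ in range(n_random_starts)
        ]
        best = None
        for a0, b0 in starts:
            try:
                sol = optimize.least_squares(
                    self._residuals,
                    x0=np.array([a0, b0]),
                    bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                    method="trf",
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("liability fit failed from every start")

        m = len(self.p_mild)
        dof = max(m - 2, 1)
        s2 = 2.0 * best.cost / dof
        jtj = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
            bse = np.full(2, np.nan)
        return LiabilityResults(
            alpha=float(best.x[0]),
            beta=float(best.x[1]),
            bse=bse,
            converged=bool(best.success),
            n_obs=m,
            ssr=float(2.0 * best.cost),
            cov_params=cov,
        )


def fit_liability(
    pairs: pd.DataFrame,
    seed: int = 0,
    weighted: bool = True,
    subset: np.ndarray | None = None,
) -> LiabilityResults:
    """Fit the model from a per-accession survival table.

    ``pairs`` needs columns ``p_mild`` and ``p_harsh``; optional columns
    ``survived_mild``/``total_mild`` trigger the half-count boundary
    correction for mild-environment probabilities at 0 or 1, and
    ``total_harsh`` provides binomial weights.
    """
    if {"survived_mild", "total_mild"}.issubset(pairs.columns):
        p_mild = shrink_boundary(
            pairs["survived_mild"].to_numpy(), pairs["total_mild"].to_numpy()
        )
    else:
        p_mild = pairs["p_mild"].to_numpy(dtype=float)
    trials = (
        pairs["total_harsh"].to_numpy(dtype=float)
        if "total_harsh" in pairs.columns
        else None
    )
    model = LiabilityModel(
        p_mild,
        pairs["p_harsh"].to_numpy(dtype=float),
        trials=trials,
        weighted=weighted,
        subset=subset,
    )
    return model.fit(seed=seed)


def simulate_survival(
    mu_per_accession: np.ndarray,
    tau: float,
    sigma: float,
    n_trials: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate binomial survival under the liability model at one site.

    Survival probability per accession is P(liability < tau) =
    Phi((tau - mu_i)/sigma); a harsher site has the lower tau. Returns a
    DataFrame with p_true, survived, total.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    mu = np.asarray(mu_per_accession, dtype=float)
    p_true = stats.norm.cdf((tau - mu) / sigma)
    rng = np.random.default_rng(seed)
    survived = rng.binomial(n_trials, p_true)
    return pd.DataFrame(
        {
            "p_true": p_true,
            "survived": survived,
            "total": np.full(mu.shape, n_trials, dtype=int),
            "p_obs": survived / n_trials,
        }
    )
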