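"""Two-sample Mendelian randomization: instruments, Wald ratios, IVW and ML.

Given genome-wide-significant, mutually independent instruments for an
exposure (here: birth weight) and their effects on an outcome (lumbar
spine BMD) from a non-overlapping study, each instrument's Wald ratio
beta_y / beta_x estimates the causal effect; instruments are combined
by fixed-effect inverse-variance weighting (IVW) and by maximum
likelihood (ML) under the model

    beta_x_i ~ N(xi_i, se_x_i²),   beta_y_i ~ N(theta * xi_i, se_y_i²)

with free per-instrument true exposure effects xi_i and a single causal
effect theta.  IVW uses first-order delta-method Wald-ratio standard
errors (se_y / |beta_x|), adequate for the strong instruments the
p < 5e-8 selection rule admits; ML additionally accounts for
measurement error in beta_x and coincides with IVW as se_x -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from pleiocfdr.ldprune import LdPanel, compute_r2
from pleiocfdr.sumstats import SumstatsTable, _chrom_key

INSTRUMENT_P_MAX = 5e-8
INSTRUMENT_R2_MAX = 0.01

_INSTRUMENT_COLUMNS = ["snp_id", "beta_x", "se_x", "beta_y", "se_y"]


@dataclass
class MrResult:
    """One estimator's causal-effect estimate."""

    method: str  # "IVW" or "ML"
    estimate: float
    se: float
    p: float
    n_instruments: int

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        zc = stats.norm.isf((1 - level) / 2)
        return self.estimate - zc * self.se, self.estimate + zc * self.se


def select_instruments(
    exposure: SumstatsTable,
    panel: LdPanel,
    p_max: float = INSTRUMENT_P_MAX,
    r2_max: float = INSTRUMENT_R2_MAX,
) -> list[str]:
    """Greedy LD clumping of genome-wide-significant exposure SNPs.

    SNPs with p < ``p_max`` are considered in ascending-p order (ties
    broken by chrom, pos); a SNP is retained unless its r² with any
    already-retained SNP exceeds ``r2_max`` (genome-wide, no window
    limit).  Deterministic.

    Raises
    ------
    ValueError
        If no SNP passes ``p_max`` ("no instruments").
    """
    df = exposure.df
    sig = df[df["p"] < p_max]
    if sig.empty:
        raise ValueError("no instruments: no SNP passes the significance threshold")
    key, _ = _chrom_key(sig["chrom"])
    sig = sig.assign(_ck=key.to_numpy()).sort_values(
        ["p", "_ck", "pos"], kind="mergesort"
    )
    row_of = {s: i for i, s in enumerate(panel.meta["snp_id"])}
    missing = [s for s in sig["snp_id"] if s not in row_of]
    if missing:
        raise ValueError(f"instrument candidates absent from LD panel: {missing[:5]}")
    retained: list[str] = []
    for snp in sig["snp_id"]:
        ok = True
        for kept in retained:
            if compute_r2(panel.dosages[row_of[snp]], panel.dosages[row_of[kept]]) > r2_max:
                ok = False
                break
        if ok:
            retained.append(snp)
    return retained


def wald_ratios(instruments: pd.DataFrame) -> pd.DataFrame:
    """Fill per-instrument Wald ratios and first-order delta-method SEs.

    wald_ratio = beta_y / beta_x; wald_se = se_y / |beta_x|.

    Raises
    ------
    ValueError
        If any beta_x is 0 (naming the SNP).
    """
    for col in _INSTRUMENT_COLUMNS:
        if col not in instruments.columns:
            raise ValueError(f"instrument table missing column {col!r}")
    zero = instruments["beta_x"] == 0
    if zero.any():
        raise ValueError(
            f"beta_x = 0 for instrument(s): {instruments.loc[zero, 'snp_id'].tolist()}"
        )
    out = instruments.copy()
    out["wald_ratio"] = out["beta_y"] / out["beta_x"]
    out["wald_se"] = out["se_y"] / out["beta_x"].abs()
    return out


def ivw(instruments: pd.DataFrame) -> MrResult:
    """Fixed-effect inverse-variance-weighted estimate over Wald ratios.

    estimate = sum(w_i r_i) / sum(w_i) with w_i = 1 / wald_se_i²;
    se = 1 / sqrt(sum w_i); p two-sided normal.
    """
    if len(instruments) == 0:
        raise ValueError("no instruments")
    if "wald_ratio" not in instruments.columns:
        instruments = wald_ratios(instruments)
    r = instruments["wald_ratio"].to_numpy()
    w = 1.0 / instruments["wald_se"].to_numpy() ** 2
    est = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(est / se)))
    return MrResult("IVW", est, se, max(p, np.nextafter(0, 1)), len(instruments))


def _profile_negloglik(theta: float, bx, by, sx2, sy2) -> float:
    # xi profiled out analytically from the joint Gaussian likelihood
    return float(0.5 * np.sum((by - theta * bx) ** 2 / (sy2 + theta**2 * sx2)))


def _profile_grad(theta: float, bx, by, sx2, sy2) -> float:
    r = by - theta * bx
    v = sy2 + theta**2 * sx2
    return float(np.sum(-r * bx / v - r**2 * theta * sx2 / v**2))


def ml_estimate(
    instruments: pd.DataFrame, max_iter: int = 500, gtol: float = 1e-8
) -> MrResult:
    """Maximum-likelihood causal effect under the bivariate normal model.

    The joint likelihood over (theta, xi_1..xi_k) is maximized by BFGS
    with an analytic gradient from the IVW starting point, to gradient
    norm below ``gtol``.  The standard error of theta comes from the
    observed information of the profile log-likelihood (numeric second
    derivative).

    Raises
    ------
    RuntimeError
        On non-convergence, with the optimizer's diagnostics.
    """
    if len(instruments) == 0:
        raise ValueError("no instruments")
    if "wald_ratio" not in instruments.columns:
        instruments = wald_ratios(instruments)
    bx = instruments["beta_x"].to_numpy(dtype=float)
    by = instruments["beta_y"].to_numpy(dtype=float)
    sx2 = instruments["se_x"].to_numpy(dtype=float) ** 2
    sy2 = instruments["se_y"].to_numpy(dtype=float) ** 2
    k = len(bx)

    def negloglik(par):
        theta, xi = par[0], par[1:]
        return float(
            0.5 * np.sum((bx - xi) ** 2 / sx2) + 0.5 * np.sum((by - theta * xi) ** 2 / sy2)
        )

    def grad(par):
        theta, xi = par[0], par[1:]
        resy = by - theta * xi
        g_theta = -np.sum(resy * xi / sy2)
        g_xi = -(bx - xi) / sx2 - theta * resy / sy2
        return np.concatenate([[g_theta], g_xi])

    start = np.concatenate([[ivw(instruments).estimate], bx])
    res = optimize.minimize(
        negloglik,
        start,
        jac=grad,
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    theta = float(res.x[0])

    # polish on the profile: xi*(theta) is closed-form, so a handful of
    # 1-D Newton steps drives the full gradient norm below gtol even when
    # BFGS stops early on line-search precision loss
    converged = False
    for _ in range(100):
        g1 = _profile_grad(theta, bx, by, sx2, sy2)
        if abs(g1) < gtol:
            converged = True
            break
        h = 1e-6 * max(1.0, abs(theta))
        g2 = (
            _profile_grad(theta + h, bx, by, sx2, sy2)
            - _profile_grad(theta - h, bx, by, sx2, sy2)
        ) / (2 * h)
        theta -= g1 / g2 if g2 > 0 else np.sign(g1) * h
    if not converged:
        g1 = _profile_grad(theta, bx, by, sx2, sy2)
        raise RuntimeError(
            f"ML did not converge: BFGS status={res.status}, message={res.message!r}, "
            f"profile |grad|={abs(g1):.3e}"
        )

    h = 1e-5 * max(1.0, abs(theta))
    info = (
        _profile_grad(theta + h, bx, by, sx2, sy2) - _profile_grad(theta - h, bx, by, sx2, sy2)
    ) / (2 * h)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    p = float(2.0 * stats.norm.sf(abs(theta / se))) if np.isfinite(se) else float("nan")
    return MrResult("ML", theta, se, max(p, np.nextafter(0, 1)), k)


def simulate_mr_dataset(
    k: int,
    theta: float,
    se_x: float = 0.005,
    se_y: float = 0.01,
    xi_mean: float = 0.1,
    xi_sd: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate instrument-level summary data under the ML model.

    True exposure effects xi_i ~ N(xi_mean, xi_sd²) (strong instruments,
    consistent with a p < 5e-8 selection rule at the default SEs);
    beta_x_i ~ N(xi_i, se_x²) and beta_y_i ~ N(theta xi_i, se_y²).

    Returns (instrument table, truth dict with theta and the xi draws).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    xi = rng.normal(xi_mean, xi_sd, size=k)
    bx = xi + rng.normal(0.0, se_x, size=k)
    by = theta * xi + rng.normal(0.0, se_y, size=k)
    table = pd.DataFrame(
        {
            "snp_id": [f"iv{i + 1}" for i in range(k)],
            "beta_x": bx,
            "se_x": se_x,
            "beta_y": by,
            "se_y": se_y,
        }
    )
    return wald_ratios(table), {"theta": theta, "xi": xi}
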