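"""Region-level hypothesis testing and classification.

Per region, Wald statistics W = (estimate/se)^2 ~ chi2_1 test the phenotype
effects in the mean (delta) and log-variance (kappa) models. The two
p-values are aggregated with the Cauchy combination test

    T = [tan((1/2 - p_M) pi) + tan((1/2 - p_V) pi)] / 2
    p_joint = 1/2 - arctan(T) / pi

which is valid under arbitrary dependence of the inputs. Each p-value family
(mean, variance, joint) is adjusted separately with Benjamini-Hochberg, and
regions are called DMR / VMR / DVMR from the adjusted values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from . import io as mio
from .exceptions import ValidationError
from .hglm import FitConfig, build_region_design, fit_region

__all__ = [
    "wald_test", "cauchy_combine", "bh_adjust", "classify_regions", "analyze",
]

#: numerical guard for the Cauchy combination inputs
CCT_EPS = 1e-15


def wald_test(estimate, se):
    """Chi-square(1) Wald test: W = (estimate/se)^2, upper-tail p."""
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(estimate) & np.isfinite(se) & (se > 0)
    z = np.where(ok, estimate / np.where(ok, se, 1.0), np.nan)
    W = z * z
    p = np.where(ok, stats.chi2.sf(W, df=1), np.nan)
    if np.isscalar(se) or se.ndim == 0:
        return float(W), float(p)
    return W, p


def _tan_half(p):
    """tan((1/2 - p) * pi), with a stable 1/(p*pi) expansion for tiny p."""
    p = np.asarray(p, dtype=float)
    out = np.tan((0.5 - p) * np.pi)
    tiny = p < 1e-10
    if np.any(tiny):
        out = np.where(tiny, 1.0 / (p * np.pi), out)
    return out


def cauchy_combine(p_mean, p_var, epsilon: float = CCT_EPS):
    """Cauchy combination of two (possibly dependent) p-values."""
    pm = np.asarray(p_mean, dtype=float)
    pv = np.asarray(p_var, dtype=float)
    scalar = pm.ndim == 0 and pv.ndim == 0
    pm, pv = np.atleast_1d(pm), np.atleast_1d(pv)
    ok = np.isfinite(pm) & np.isfinite(pv)
    pm = np.clip(pm, epsilon, 1.0 - epsilon)
    pv = np.clip(pv, epsilon, 1.0 - epsilon)
    T = 0.5 * (_tan_half(pm) + _tan_half(pv))
    p_joint = 0.5 - np.arctan(T) / np.pi
    # extreme T: arctan saturates; fall back to the Cauchy tail 1/(pi*T)
    big = T > 1e10
    if np.any(big):
        p_joint = np.where(big, 1.0 / (np.pi * T), p_joint)
    T = np.where(ok, T, np.nan)
    p_joint = np.where(ok, np.clip(p_joint, 0.0, 1.0), np.nan)
    if scalar:
        return float(T[0]), float(p_joint[0])
    return T, p_joint


def bh_adjust(pvec):
    """Benjamini-Hochberg step-up adjustment.

    NaNs are passed through and excluded from the family size m.
    """
    p = np.asarray(pvec, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pp = p[ok]
    m = pp.size
    if m == 0:
        return q
    if np.any((pp < 0) | (pp > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    order = np.argsort(pp, kind="stable")
    ranked = pp[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def classify_regions(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign DMR/VMR/DVMR calls from the FDR-adjusted p-values.

    Adds independent boolean flags ``is_dmr``, ``is_vmr``, ``is_dvmr``
    (non-exclusive, matching how the three categories are counted) plus a
    single ``call`` column under the exclusive precedence DVMR > DMR > VMR.
    """
    out = results.copy()
    fm = out["fdr_mean"].to_numpy(dtype=float)
    fv = out["fdr_var"].to_numpy(dtype=float)
    fj = out["fdr_joint"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        is_dmr = fm < alpha
        is_vmr = fv < alpha
        is_dvmr = fj < alpha
    out["is_dmr"], out["is_vmr"], out["is_dvmr"] = is_dmr, is_vmr, is_dvmr
    call = np.where(is_dvmr, "DVMR",
                    np.where(is_dmr, "DMR",
                             np.where(is_vmr, "VMR", "none")))
    all_na = ~(np.isfinite(fm) | np.isfinite(fv) | np.isfinite(fj))
    call = np.where(all_na, "NA", call)
    out["call"] = call
    return out


def _fit_one(region_id, cpgs, matrix, design, config):
    rd = build_region_design(cpgs, matrix, design, region_id=region_id)
    fit = fit_region(rd, config)
    Wm, pm = wald_test(fit.delta_hat, fit.se_delta)
    Wv, pv = wald_test(fit.kappa_hat, fit.se_kappa)
    return {
        "region_id": region_id, "n_cpgs": len(cpgs),
        "delta_hat": fit.delta_hat, "se_delta": fit.se_delta,
        "kappa_hat": fit.kappa_hat, "se_kappa": fit.se_kappa,
        "sigma_b2": fit.sigma_b2,
        "W_mean": Wm, "W_var": Wv, "p_mean": pm, "p_var": pv,
        "converged": bool(fit.converged), "n_iter": int(fit.n_iter),
    }


def analyze(matrix, regions, design, config: FitConfig | None = None,
            alpha: float = 0.05, threads: int = 1) -> pd.DataFrame:
    """Fit every region and assemble the full results table.

    ``matrix``/``design`` are aligned first (common samples, matrix column
    order). Regions are fit independently — optionally in parallel — and
    collected in region-map order, so results do not depend on ``threads``.
    """
    matrix, design = mio.align(matrix, design)
    cfg = config or FitConfig()
    jobs = [(rid, regions.cpgs(rid)) for rid in regions.region_ids]
    if threads and threads > 1:
        rows = Parallel(n_jobs=threads, batch_size=max(1, len(jobs) // (4 * threads)))(
            delayed(_fit_one)(rid, cpgs, matrix, design, cfg) for rid, cpgs in jobs
        )
    else:
        rows = [_fit_one(rid, cpgs, matrix, design, cfg) for rid, cpgs in jobs]
    res = pd.DataFrame(rows)
    T, p_joint = cauchy_combine(res["p_mean"].to_numpy(), res["p_var"].to_numpy())
    res["T_cauchy"] = T
    res["p_joint"] = p_joint
    res["fdr_mean"] = bh_adjust(res["p_mean"].to_numpy())
    res["fdr_var"] = bh_adjust(res["p_var"].to_numpy())
    res["fdr_joint"] = bh_adjust(res["p_joint"].to_numpy())
    res = classify_regions(res, alpha=alpha)
    order = mio.RESULT_COLUMNS + [c for c in res.columns if c not in mio.RESULT_COLUMNS]
    return res[order]
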