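"""Saturation-kinetics fitting for TPH2 variant comparison.

Velocities are 5-HTP formation rates normalized to enzyme amount (arbitrary
units); substrate is tryptophan in µM at fixed cofactor (300 µM 6MPH4 or BH4).
Two models are fitted:

* Michaelis-Menten: v = Vmax * S / (Km + S)
* single-site substrate inhibition (Haldane): v = Vmax * S / (Km + S + S^2/Ki)

The primary estimator is nonlinear least squares with multi-start; the
double-reciprocal Lineweaver-Burk line (1/v on 1/S; Km = slope/intercept,
Vmax = 1/intercept) is retained side by side because published Michaelis
constants in this assay family are traditionally read off LB plots.  Both
agree exactly on noiseless data; on noisy data LB is biased by the reciprocal
transform, which the recovery harness documents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .reference import ParameterError, Tph2Error


class FitError(Tph2Error):
    """A kinetic fit could not be carried out on the given data."""


def michaelis_menten(S, km: float, vmax: float):
    S = np.asarray(S, dtype=float)
    return vmax * S / (km + S)


def substrate_inhibition(S, km: float, vmax: float, ki: float):
    S = np.asarray(S, dtype=float)
    return vmax * S / (km + S + S * S / ki)


@dataclass(frozen=True)
class KineticDataset:
    """Substrate-velocity observations for one enzyme variant and cofactor."""

    variant: str
    cofactor: str
    S: np.ndarray
    v: np.ndarray
    replicate: np.ndarray
    cofactor_um: float = 300.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        object.__setattr__(self, "replicate", np.asarray(self.replicate))
        if self.S.shape != self.v.shape:
            raise ParameterError("S and v must have matching shapes")
        if (self.S <= 0).any():
            raise ParameterError("substrate concentrations must be positive")
        if (self.v < 0).any():
            raise ParameterError("velocities must be non-negative")

    def subset(self, replicate) -> "KineticDataset":
        m = self.replicate == replicate
        return KineticDataset(self.variant, self.cofactor, self.S[m], self.v[m],
                              self.replicate[m], self.cofactor_um)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant": self.variant, "cofactor": self.cofactor,
             "S_uM": self.S, "v": self.v, "replicate": self.replicate}
        )


@dataclass(frozen=True)
class KineticFit:
    """Fitted kinetic constants with standard errors and diagnostics."""

    model: str  # 'MM' | 'SI'
    km: float
    vmax: float
    ki: Optional[float] = None
    se: Mapping[str, float] = field(default_factory=dict)
    method: str = "nls"
    rss: float = float("nan")
    converged: bool = True
    flags: tuple[str, ...] = ()


def normalize_rates(raw_velocities, expression_signal: float) -> np.ndarray:
    """Normalize raw 5-HTP formation rates to the enzyme expression signal."""
    if expression_signal <= 0:
        raise ParameterError("expression signal must be positive")
    return np.asarray(raw_velocities, dtype=float) / expression_signal


def _lb_estimate(S: np.ndarray, v: np.ndarray) -> Optional[tuple[float, float]]:
    ok = v > 0
    if ok.sum() < 2:
        return None
    slope, intercept = np.polyfit(1.0 / S[ok], 1.0 / v[ok], 1)
    if intercept <= 0:
        return None
    return slope / intercept, 1.0 / intercept


def _nls(fun, S, v, starts, bounds) -> tuple[Optional[np.ndarray], Optional[np.ndarray], float]:
    best, best_cov, best_rss = None, None, np.inf
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                fun, S, v, p0=p0, bounds=bounds, maxfev=20000,
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((v - fun(S, *popt)) ** 2))
        if rss < best_rss:
            best, best_cov, best_rss = popt, pcov, rss
    return best, best_cov, best_rss


def _se_from_cov(pcov, names, n, k) -> tuple[dict[str, float], tuple[str, ...]]:
    flags: tuple[str, ...] = ()
    if pcov is None or not np.all(np.isfinite(pcov)):
        return {n_: float("inf") for n_ in names}, ("covariance_singular",)
    se = {n_: float(np.sqrt(max(pcov[i, i], 0.0))) for i, n_ in enumerate(names)}
    if n <= k:
        flags = ("too_few_points_for_se",)
    return se, flags


def fit_mm(dataset: KineticDataset) -> KineticFit:
    """Nonlinear least-squares Michaelis-Menten fit (multi-start)."""
    S, v = dataset.S, dataset.v
    if np.unique(S).size < 3:
        raise ParameterError("need >= 3 distinct substrate concentrations")
    vmax0 = float(v.max()) if v.max() > 0 else 1.0
    starts = [(s_km, s_vmax) for s_km in (np.median(S), S.min(), S.max(), 10 * S.max())
              for s_vmax in (vmax0, 2 * vmax0)][:6]
    lb = _lb_estimate(S, v)
    if lb is not None and lb[0] > 0 and lb[1] > 0:
        starts.insert(0, lb)
    popt, pcov, rss = _nls(
        lambda s, km, vm: michaelis_menten(s, km, vm), S, v, starts,
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
    )
    if popt is None:
        return KineticFit("MM", float("nan"), float("nan"), se={}, rss=float("nan"),
                          converged=False, flags=("no_convergence",))
    se, flags = _se_from_cov(pcov, ("km", "vmax"), S.size, 2)
    converged = np.isfinite(rss)
    # saturation-only data (no curvature information) drives Km to the boundary
    if (
        not np.isfinite(se.get("km", np.inf))
        or se["km"] > 1e6 * max(popt[0], 1.0)
        or popt[0] < 1e-6 * float(S.min())
    ):
        flags = flags + ("km_not_identifiable",)
        converged = False
    return KineticFit("MM", float(popt[0]), float(popt[1]), se=se, rss=rss,
                      converged=bool(converged), flags=flags)


def fit_lineweaver_burk(dataset: KineticDataset) -> KineticFit:
    """Double-reciprocal (Lineweaver-Burk) Michaelis-Menten estimate."""
    S, v = dataset.S, dataset.v
    if (v <= 0).any():
        raise FitError("Lineweaver-Burk requires strictly positive velocities")
    if np.unique(S).size < 2:
        raise ParameterError("need >= 2 distinct substrate concentrations")
    slope, intercept = np.polyfit(1.0 / S, 1.0 / v, 1)
    if intercept <= 0:
        return KineticFit("MM", float("nan"), float("nan"), method="lineweaver_burk",
                          converged=False, flags=("nonpositive_intercept",))
    km, vmax = slope / intercept, 1.0 / intercept
    resid = 1.0 / v - (slope / S + intercept)
    return KineticFit("MM", float(km), float(vmax), method="lineweaver_burk",
                      rss=float(np.sum(resid**2)), converged=True)


def fit_substrate_inhibition(dataset: KineticDataset) -> KineticFit:
    """Multi-start Haldane substrate-inhibition fit v = Vmax*S/(Km+S+S^2/Ki)."""
    S, v = dataset.S, dataset.v
    if np.unique(S).size < 4:
        raise ParameterError("need >= 4 distinct substrate concentrations")
    vmax0 = float(v.max()) if v.max() > 0 else 1.0
    km0 = float(np.median(S))
    smax = float(S.max())
    starts = [
        (km0, vmax0, smax), (km0, 2 * vmax0, 10 * smax), (S.min(), vmax0, smax**2 / km0),
        (smax, vmax0, smax), (km0 / 10, vmax0, 100 * smax),
    ]
    lb = _lb_estimate(S, v)
    if lb is not None and lb[0] > 0 and lb[1] > 0:
        starts.insert(0, (lb[0], lb[1], 10 * smax))
    popt, pcov, rss = _nls(
        lambda s, km, vm, ki: substrate_inhibition(s, km, vm, ki), S, v, starts,
        bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
    )
    if popt is None:
        return KineticFit("SI", float("nan"), float("nan"), ki=float("nan"), se={},
                          converged=False, flags=("no_convergence",))
    se, flags = _se_from_cov(pcov, ("km", "vmax", "ki"), S.size, 3)
    # no descending limb in the data => Ki runs away and is not identified
    if popt[2] > 1e3 * smax or not np.isfinite(se.get("ki", np.inf)):
        flags = flags + ("ki_unbounded",)
    return KineticFit("SI", float(popt[0]), float(popt[1]), ki=float(popt[2]), se=se,
                      rss=rss, converged=True, flags=flags)


def si_velocity_peak(km: float, ki: float) -> float:
    """Substrate concentration maximizing the Haldane velocity: sqrt(Km*Ki)."""
    return float(np.sqrt(km * ki))


def compare_variants(
    km_by_variant: Mapping[str, Sequence[float]],
    vmax_by_variant: Optional[Mapping[str, Sequence[float]]] = None,
    baseline: Optional[str] = None,
) -> pd.DataFrame:
    """Summarize replicate-level estimates per variant and test pairwise.

    Returns one row per variant with mean +/- SEM of Km (and Vmax), the Vmax
    ratio to the baseline variant (percent), and two-tailed Welch p-values
    against every other variant on the replicate Km estimates.
    """
    variants = list(km_by_variant)
    if baseline is None:
        baseline = variants[0]
    for name, vals in km_by_variant.items():
        if len(vals) < 2:
            raise ParameterError(f"variant {name!r} needs >= 2 replicates for SEM")
    pvals: dict[tuple[str, str], float] = {}
    for x, y in combinations(variants, 2):
        a, b = np.asarray(km_by_variant[x], float), np.asarray(km_by_variant[y], float)
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        pvals[(x, y)] = pvals[(y, x)] = p
    rows = []
    base_vmax = None
    if vmax_by_variant is not None:
        base_vmax = np.median(np.asarray(vmax_by_variant[baseline], float))
    for name in variants:
        km = np.asarray(km_by_variant[name], float)
        row: dict[str, object] = {
            "variant": name,
            "n": km.size,
            "km_mean": float(km.mean()),
            "km_sem": float(stats.sem(km)),
        }
        if vmax_by_variant is not None:
            vm = np.asarray(vmax_by_variant[name], float)
            row["vmax_mean"] = float(vm.mean())
            row["vmax_sem"] = float(stats.sem(vm))
            row["vmax_pct_of_baseline"] = float(100.0 * np.median(vm) / base_vmax)
        for other in variants:
            if other != name:
                row[f"p_vs_{other}"] = pvals[(name, other)]
        rows.append(row)
    return pd.DataFrame(rows)
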