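"""Multi-group twin maximum likelihood with direct (unbounded) variances.

The core model: twin-pair phenotypes are bivariate normal with expected
covariance matrices parameterized directly in the variance components,

    MZ: [[T, A + C], [A + C, T]]      DZ: [[T, A/2 + C], [A/2 + C, T]]

with T = A + C + E. A and C are estimated WITHOUT a lower bound of zero —
negative estimates are legitimate and keep likelihood-ratio error rates
regular; a negative C reads as a familial residual consistent with
non-additive genetic variance outweighing shared environment. Positive
definiteness of the expected matrices is enforced by an infinite objective
value rather than hard parameter bounds.

Incomplete pairs are retained by full-information maximum likelihood
(FIML): a pair with one member missing contributes the marginal univariate
normal log-density; both-missing pairs are dropped (counted). Internally
the likelihood is evaluated from per-group sufficient statistics (sums and
cross-products of complete pairs plus per-twin-order half-pair sums),
which is algebraically identical to summing :func:`pair_loglik` over pairs
and makes the thousands of refits behind power simulations and profile
confidence intervals affordable.

Model labels follow the five-model battery: ``sat2`` / ``ace2`` (sexes
pooled within MZ and DZ groups) and ``sat4`` / ``ace4_free`` /
``ace4_equal`` (groups split by zygosity x sex; the "equal" variant
constrains the A, C, E components, but not the means, across sex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .descriptives import levene, twin_correlations
from .reparam import ace_shares, ace_to_ade

LOG_2PI = math.log(2.0 * math.pi)
_TWO_GROUPS = ("MZ", "DZ")
_FOUR_GROUPS = ("MZ_M", "MZ_F", "DZ_M", "DZ_F")

N_FREE_PARAMS = {"sat2": 10, "ace2": 4, "sat4": 20, "ace4_free": 8, "ace4_equal": 5}


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------


def pair_loglik(y1: float, y2: float, mean, cov) -> float:
    """Log-likelihood contribution of a single (possibly incomplete) pair.

    Complete pairs contribute the bivariate normal log-density; pairs with
    one member missing contribute the marginal univariate normal density;
    both-missing pairs contribute 0. A non-positive-definite ``cov``
    returns -inf, which drives optimizers back into the feasible region.
    """
    m1, m2 = float(mean[0]), float(mean[1])
    v1, v2 = float(cov[0][0]), float(cov[1][1])
    c = float(cov[0][1])
    ok1 = y1 is not None and np.isfinite(y1)
    ok2 = y2 is not None and np.isfinite(y2)
    if not ok1 and not ok2:
        return 0.0
    if ok1 and ok2:
        det = v1 * v2 - c * c
        if det <= 0.0 or v1 <= 0.0 or v2 <= 0.0:
            return -np.inf
        d1, d2 = y1 - m1, y2 - m2
        quad = (v2 * d1 * d1 - 2.0 * c * d1 * d2 + v1 * d2 * d2) / det
        return -0.5 * (2.0 * LOG_2PI + math.log(det) + quad)
    if ok1:
        y, m, v = y1, m1, v1
    else:
        y, m, v = y2, m2, v2
    if v <= 0.0:
        return -np.inf
    d = y - m
    return -0.5 * (LOG_2PI + math.log(v) + d * d / v)


@dataclass(frozen=True)
class GroupStats:
    """Sufficient statistics of one twin group for the FIML likelihood."""

    n: int  # complete pairs
    s1: float
    s2: float
    q11: float
    q22: float
    q12: float
    n_half1: int  # pairs with only twin 1 observed
    hs1: float
    hq1: float
    n_half2: int  # pairs with only twin 2 observed
    hs2: float
    hq2: float
    n_dropped: int  # both members missing

    @property
    def n_effective(self) -> int:
        return self.n + self.n_half1 + self.n_half2


def group_stats(y1, y2) -> GroupStats:
    """Aggregate per-pair arrays into :class:`GroupStats`."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    ok1, ok2 = np.isfinite(y1), np.isfinite(y2)
    both = ok1 & ok2
    only1 = ok1 & ~ok2
    only2 = ok2 & ~ok1
    a, b = y1[both], y2[both]
    h1, h2 = y1[only1], y2[only2]
    return GroupStats(
        n=int(both.sum()),
        s1=float(a.sum()),
        s2=float(b.sum()),
        q11=float(a @ a),
        q22=float(b @ b),
        q12=float(a @ b),
        n_half1=int(only1.sum()),
        hs1=float(h1.sum()),
        hq1=float(h1 @ h1),
        n_half2=int(only2.sum()),
        hs2=float(h2.sum()),
        hq2=float(h2 @ h2),
        n_dropped=int((~ok1 & ~ok2).sum()),
    )


def neg2ll_group(
    g: GroupStats, m1: float, m2: float, v1: float, v2: float, c: float
) -> float:
    """-2 log-likelihood of one group; +inf when the covariance is not PD.

    Identical to ``-2 * sum(pair_loglik(...))`` over the group's pairs.
    """
    if v1 <= 0.0 or v2 <= 0.0:
        return np.inf
    det = v1 * v2 - c * c
    if det <= 0.0:
        return np.inf
    total = 0.0
    if g.n:
        s11 = g.q11 - 2.0 * m1 * g.s1 + g.n * m1 * m1
        s22 = g.q22 - 2.0 * m2 * g.s2 + g.n * m2 * m2
        s12 = g.q12 - m1 * g.s2 - m2 * g.s1 + g.n * m1 * m2
        total += g.n * (2.0 * LOG_2PI + math.log(det))
        total += (v2 * s11 - 2.0 * c * s12 + v1 * s22) / det
    if g.n_half1:
        ss = g.hq1 - 2.0 * m1 * g.hs1 + g.n_half1 * m1 * m1
        total += g.n_half1 * (LOG_2PI + math.log(v1)) + ss / v1
    if g.n_half2:
        ss = g.hq2 - 2.0 * m2 * g.hs2 + g.n_half2 * m2 * m2
        total += g.n_half2 * (LOG_2PI + math.log(v2)) + ss / v2
    return total


def split_groups(
    table: pd.DataFrame, phenotype: str, grouping: str
) -> dict[str, GroupStats]:
    """Group a pair table into MZ/DZ (2group) or zygosity x sex (4group)."""
    c1, c2 = f"{phenotype}_1", f"{phenotype}_2"
    if c1 not in table.columns or c2 not in table.columns:
        raise KeyError(f"phenotype columns {c1!r}/{c2!r} not in table")
    out: dict[str, GroupStats] = {}
    if grouping == "2group":
        for zyg in _TWO_GROUPS:
            sub = table[table["zygosity"] == zyg]
            out[zyg] = group_stats(sub[c1], sub[c2])
    elif grouping == "4group":
        for name in _FOUR_GROUPS:
            zyg, sex = name.split("_")
            sub = table[(table["zygosity"] == zyg) & (table["sex"] == sex)]
            out[name] = group_stats(sub[c1], sub[c2])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return out


def _moments(g: GroupStats) -> tuple[float, float, float, float, float]:
    """Complete-pair sample moments (n divisor) of one group."""
    if g.n == 0:
        raise FitError("group has no complete pairs")
    m1, m2 = g.s1 / g.n, g.s2 / g.n
    v1 = g.q11 / g.n - m1 * m1
    v2 = g.q22 / g.n - m2 * m2
    c = g.q12 / g.n - m1 * m2
    return m1, m2, v1, v2, c


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """One fitted model: labelled parameters, -2lnL and bookkeeping."""

    model_label: str
    parameters: dict[str, float]
    minus2LL: float
    n_free_params: int
    n_pairs_by_group: dict[str, int]
    converged: bool
    gradient_norm: float
    groups: dict[str, GroupStats] = field(repr=False, default_factory=dict)
    extra: dict = field(repr=False, default_factory=dict)


@dataclass
class VarianceComponentEstimate:
    """Raw and standardized ACE components with profile CIs."""

    A: float
    C: float
    E: float
    a2: float
    c2: float
    e2: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    note: str = ""


_NM_OPTS = dict(xatol=1e-9, fatol=1e-11, maxiter=4000, maxfev=8000)


def _minimize(
    obj: Callable, x0: np.ndarray, restarts: int = 3, safe: np.ndarray | None = None
):
    """Nelder-Mead with a convergence restart and jittered retries.

    Returns (x, fval, converged). The objective may return +inf outside the
    positive-definite region; the simplex handles the cliff gracefully.
    ``safe`` is an interior point to blend toward when the start is
    infeasible (e.g. a diagonal-dominant configuration).
    """
    x0 = np.asarray(x0, dtype=float)
    if not np.isfinite(obj(x0)):
        # pull the start into the feasible region
        anchors = [safe] if safe is not None else []
        anchors.append(np.zeros_like(x0))
        for anchor in anchors:
            for t in (0.5, 0.25, 0.1, 0.01, 0.0):
                trial = t * x0 + (1.0 - t) * anchor
                if np.isfinite(obj(trial)):
                    x0 = trial
                    break
            else:
                continue
            break
    best = optimize.minimize(obj, x0, method="Nelder-Mead", options=_NM_OPTS)
    polish = optimize.minimize(obj, best.x, method="Nelder-Mead", options=_NM_OPTS)
    if polish.fun <= best.fun:
        best = polish
    converged = bool(np.isfinite(best.fun))
    if not converged:
        rng = np.random.default_rng(0)
        for _ in range(restarts):
            trial_x0 = x0 * (1.0 + 0.1 * rng.standard_normal(len(x0)))
            trial = optimize.minimize(
                obj, trial_x0, method="Nelder-Mead", options=_NM_OPTS
            )
            if np.isfinite(trial.fun) and trial.fun < best.fun:
                best = trial
                converged = True
    return best.x, float(best.fun), converged


def _gradient_norm(obj: Callable, x: np.ndarray) -> float:
    h = 1e-6
    g = np.empty(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = h * max(1.0, abs(x[i]))
        fp, fm = obj(x + e), obj(x - e)
        if not (np.isfinite(fp) and np.isfinite(fm)):
            return np.nan
        g[i] = (fp - fm) / (2.0 * e[i])
    return float(np.linalg.norm(g))


# -- saturated models -------------------------------------------------------


def _fit_saturated_group(g: GroupStats, name: str) -> tuple[np.ndarray, float, bool]:
    if g.n < 3:
        raise FitError(f"group {name!r} has {g.n} complete pairs (< 3)")
    x0 = np.array(_moments(g))
    if x0[2] <= 0 or x0[3] <= 0:
        raise FitError(f"group {name!r} has degenerate complete-pair moments")

    def obj(x):
        return neg2ll_group(g, x[0], x[1], x[2], x[3], x[4])

    if g.n_half1 == 0 and g.n_half2 == 0:
        # complete data: ML solution is the sample moments exactly
        return x0, obj(x0), True
    x, f, ok = _minimize(obj, x0)
    return x, f, ok


def fit_saturated(
    table: pd.DataFrame, phenotype: str, grouping: str = "2group"
) -> FitResult:
    """Per-group free means, variances and covariance, ML-fitted.

    With complete data the solution equals the sample moments (n divisor);
    with half-pairs each group is optimized under FIML. Groups are
    independent, so each is fitted separately and the -2lnL values add.
    """
    groups = split_groups(table, phenotype, grouping)
    label = "sat2" if grouping == "2group" else "sat4"
    params: dict[str, float] = {}
    total = 0.0
    converged = True
    xs = []
    for name, g in groups.items():
        x, f, ok = _fit_saturated_group(g, name)
        total += f
        converged &= ok
        xs.append((name, g, x))
        for key, val in zip(("mean1", "mean2", "var1", "var2", "cov"), x):
            params[f"{name}.{key}"] = float(val)

    def full_obj(z):
        i, out = 0, 0.0
        for _, g, _x in xs:
            out += neg2ll_group(g, z[i], z[i + 1], z[i + 2], z[i + 3], z[i + 4])
            i += 5
        return out

    zhat = np.concatenate([x for _, _, x in xs])
    return FitResult(
        model_label=label,
        parameters=params,
        minus2LL=total,
        n_free_params=N_FREE_PARAMS[label],
        n_pairs_by_group={k: g.n_effective for k, g in groups.items()},
        converged=converged,
        gradient_norm=_gradient_norm(full_obj, zhat),
        groups=groups,
    )


# -- ACE models -------------------------------------------------------------


def _ace_group_neg2ll(
    g: GroupStats, zyg: str, mu: float, A: float, C: float, E: float
) -> float:
    T = A + C + E
    cov = A + C if zyg == "MZ" else 0.5 * A + C
    return neg2ll_group(g, mu, mu, T, T, cov)


def _ace_starts(
    groups: dict[str, GroupStats],
) -> tuple[float, float, float, float, float, float, float]:
    """Moment starting values A0=2(covMZ-covDZ), C0=2covDZ-covMZ,
    E0=var-covMZ, pooled over the supplied MZ*/DZ* groups; also returns the
    pooled covMZ, covDZ and variance for submodel-specific starts."""
    cov = {"MZ": [], "DZ": []}
    var: list[float] = []
    means: list[float] = []
    weights: list[float] = []
    for name, g in groups.items():
        if g.n < 2:
            continue
        m1, m2, v1, v2, c = _moments(g)
        zyg = name.split("_")[0]
        cov[zyg].append(c)
        var.extend([v1, v2])
        means.extend([m1, m2])
        weights.append(g.n)
    if not cov["MZ"] or not cov["DZ"]:
        raise FitError("both zygosity groups must contain complete pairs")
    c_mz = float(np.mean(cov["MZ"]))
    c_dz = float(np.mean(cov["DZ"]))
    v = float(np.mean(var))
    mu0 = float(np.average(means, weights=np.repeat(weights, 2)))
    A0 = 2.0 * (c_mz - c_dz)
    C0 = 2.0 * c_dz - c_mz
    E0 = max(v - c_mz, 0.05 * v)
    return mu0, A0, C0, E0, c_mz, c_dz, v


def _fit_ace_2group(
    groups: dict[str, GroupStats],
    fixed: dict[str, float] | None = None,
) -> tuple[dict[str, float], float, bool, float]:
    """Fit mu + unbounded A, C, E to an {MZ, DZ} pair of groups.

    ``fixed`` pins components (e.g. {"A": 0.0} for the CE submodel, used by
    power analysis and bounded refits)."""
    fixed = dict(fixed or {})
    mu0, A0, C0, E0, c_mz, c_dz, v = _ace_starts(groups)
    starts = {"A": A0, "C": C0, "E": E0}
    free = [k for k in ("A", "C", "E") if k not in fixed]
    # submodel-aware moment starts: match the pooled covariances under the
    # constrained expectation instead of the full ACE formula
    if "A" in fixed and "C" not in fixed:
        a = fixed["A"]
        starts["C"] = 0.5 * ((c_mz - a) + (c_dz - 0.5 * a))
    if "C" in fixed and "A" not in fixed:
        c = fixed["C"]
        starts["A"] = 0.5 * ((c_mz - c) + 2.0 * (c_dz - c))
    if fixed:
        used_a = fixed.get("A", starts["A"])
        used_c = fixed.get("C", starts["C"])
        starts["E"] = max(v - used_a - used_c, 0.05 * v)
    safe_vals = {"A": 0.0, "C": 0.0, "E": v}

    def unpack(x):
        comp = dict(fixed)
        for k, val in zip(free, x[1:]):
            comp[k] = val
        return comp

    def obj(x):
        comp = unpack(x)
        out = 0.0
        for name, g in groups.items():
            out += _ace_group_neg2ll(
                g, name.split("_")[0], x[0], comp["A"], comp["C"], comp["E"]
            )
        return out

    x0 = np.array([mu0] + [starts[k] for k in free])
    x_safe = np.array([mu0] + [safe_vals[k] for k in free])
    x, f, ok = _minimize(obj, x0, safe=x_safe)
    comp = unpack(x)
    params = {"mu": float(x[0]), **{k: float(v) for k, v in comp.items()}}
    return params, f, ok, _gradient_norm(obj, x)


def _estimate_from_components(A: float, C: float, E: float) -> VarianceComponentEstimate:
    T = A + C + E
    est = VarianceComponentEstimate(
        A=A, C=C, E=E, a2=A / T, c2=C / T, e2=E / T
    )
    if C < 0:
        est.note = (
            "negative C: familial residual consistent with non-additive "
            "genetic variance outweighing shared environment"
        )
    return est


def fit_ace(
    table: pd.DataFrame,
    phenotype: str,
    grouping: str = "2group",
    equate_sex: bool = True,
    fixed: dict[str, float] | None = None,
) -> tuple[FitResult, dict[str, VarianceComponentEstimate]]:
    """ACE model with direct, unbounded variance estimation.

    2group: one grand mean, one A/C/E set. 4group with ``equate_sex=False``
    (``ace4_free``): per-sex means and per-sex A/C/E (the sexes are
    likelihood-independent and fitted separately); with ``equate_sex=True``
    (``ace4_equal``): per-sex means, shared A/C/E. Returns the fit and the
    standardized estimates keyed by "overall" or sex.
    """
    groups = split_groups(table, phenotype, grouping)
    return fit_ace_stats(groups, grouping, equate_sex, fixed)


def fit_ace_stats(
    groups: dict[str, GroupStats],
    grouping: str = "2group",
    equate_sex: bool = True,
    fixed: dict[str, float] | None = None,
) -> tuple[FitResult, dict[str, VarianceComponentEstimate]]:
    """As :func:`fit_ace` but starting from precomputed group statistics."""
    estimates: dict[str, VarianceComponentEstimate] = {}
    if grouping == "2group":
        params, m2ll, ok, gnorm = _fit_ace_2group(groups, fixed)
        label = "ace2"
        n_free = N_FREE_PARAMS[label] - len(fixed or {})
        estimates["overall"] = _estimate_from_components(
            params["A"], params["C"], params["E"]
        )
        grad = gnorm
    elif grouping == "4group" and not equate_sex:
        label = "ace4_free"
        params = {}
        m2ll, ok, grad = 0.0, True, 0.0
        for sex in ("M", "F"):
            sub = {z: groups[f"{z}_{sex}"] for z in _TWO_GROUPS}
            p, f, k, gn = _fit_ace_2group(sub, fixed)
            m2ll += f
            ok &= k
            grad = math.hypot(grad, gn)
            for key, val in p.items():
                params[f"{key}_{sex}"] = val
            estimates[sex] = _estimate_from_components(p["A"], p["C"], p["E"])
        n_free = N_FREE_PARAMS[label] - 2 * len(fixed or {})
    elif grouping == "4group" and equate_sex:
        label = "ace4_equal"
        fixed = dict(fixed or {})
        free = [k for k in ("A", "C", "E") if k not in fixed]
        s_m = _ace_starts({z: groups[f"{z}_M"] for z in _TWO_GROUPS})
        s_f = _ace_starts({z: groups[f"{z}_F"] for z in _TWO_GROUPS})
        pooled = {
            "A": 0.5 * (s_m[1] + s_f[1]),
            "C": 0.5 * (s_m[2] + s_f[2]),
            "E": 0.5 * (s_m[3] + s_f[3]),
        }

        def unpack(x):
            comp = dict(fixed)
            for k, val in zip(free, x[2:]):
                comp[k] = val
            return comp

        def obj(x):
            comp = unpack(x)
            out = 0.0
            for name, g in groups.items():
                zyg, sex = name.split("_")
                mu = x[0] if sex == "M" else x[1]
                out += _ace_group_neg2ll(g, zyg, mu, comp["A"], comp["C"], comp["E"])
            return out

        v_pooled = 0.5 * (s_m[6] + s_f[6])
        safe_vals = {"A": 0.0, "C": 0.0, "E": v_pooled}
        x0 = np.array([s_m[0], s_f[0]] + [pooled[k] for k in free])
        x_safe = np.array([s_m[0], s_f[0]] + [safe_vals[k] for k in free])
        x, m2ll, ok = _minimize(obj, x0, safe=x_safe)
        grad = _gradient_norm(obj, x)
        comp = unpack(x)
        params = {"mu_M": float(x[0]), "mu_F": float(x[1])}
        params.update({k: float(v) for k, v in comp.items()})
        estimates["overall"] = _estimate_from_components(
            params["A"], params["C"], params["E"]
        )
        n_free = N_FREE_PARAMS[label] - len(fixed)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    fit = FitResult(
        model_label=label,
        parameters=params,
        minus2LL=float(m2ll),
        n_free_params=n_free,
        n_pairs_by_group={k: g.n_effective for k, g in groups.items()},
        converged=bool(ok),
        gradient_norm=grad,
        groups=groups,
        extra={"fixed": dict(fixed or {}), "grouping": grouping},
    )
    if not ok:
        fit.extra["warning"] = "optimizer did not converge after restarts"
    return fit, estimates


def fit_ace_bounded(
    groups: dict[str, GroupStats], grouping: str = "2group"
) -> tuple[FitResult, dict[str, VarianceComponentEstimate]]:
    """ACE fit constrained to A >= 0 and C >= 0 (path-coefficient analogue).

    Fits unbounded first; while the solution has a negative A or C, the most
    negative component is pinned to zero and the rest refitted — the active-
    set solution of the boundary-constrained ML problem. Provided for
    bias comparisons; the unbounded fit is the recommended estimator.
    """
    if grouping != "2group":
        raise NotImplementedError("bounded refit is provided for 2group fits")
    fixed: dict[str, float] = {}
    while True:
        fit, est = fit_ace_stats(groups, grouping, fixed=fixed)
        e = est["overall"]
        negs = {k: v for k, v in (("A", e.A), ("C", e.C)) if v < 0 and k not in fixed}
        if not negs:
            fit.model_label = "ace2_bounded"
            return fit, est
        worst = min(negs, key=negs.get)
        fixed[worst] = 0.0


# -- inference --------------------------------------------------------------


def lrt(nested: FitResult, full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a full model.

    Central chi-square reference with df = difference in free parameter
    counts; no boundary mixture, consistent with unbounded estimation.
    """
    df = nested.n_free_params * -1 + full.n_free_params
    if df < 0:
        raise ValueError("nested model must have fewer free parameters")
    stat = nested.minus2LL - full.minus2LL
    if stat < -1e-4:
        raise FitError(
            f"negative LRT statistic {stat:.3g}: optimization failure in the full model"
        )
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 and stat == 0.0 else float(stats.chi2.sf(stat, max(df, 1)))
    if df == 0:
        p = 1.0 if stat <= 1e-8 else 0.0
    return float(stat), df, p


_PROFILE_NM_OPTS = dict(xatol=1e-10, fatol=1e-12, maxiter=3000, maxfev=6000)


def _profile_obj_factory(fit: FitResult, component: str, sex: str | None):
    """Constrained -2lnL as a function of one standardized share.

    Free parameters are the mean(s), the total variance T and one other
    share; the third share is 1 minus the other two. For ace4_free the
    other sex's minimized -2lnL is an additive constant.
    """
    comp_order = {"a2": 0, "c2": 1, "e2": 2}
    if component not in comp_order:
        raise ValueError(f"component must be one of a2/c2/e2, got {component!r}")
    label = fit.model_label
    groups = fit.groups

    def shares_from(x_share: float, s_free: float) -> tuple[float, float, float]:
        vals = {"a2": 0.0, "c2": 0.0, "e2": 0.0}
        vals[component] = x_share
        free_name = "c2" if component == "a2" else "a2"
        vals[free_name] = s_free
        last = ({"a2", "c2", "e2"} - {component, free_name}).pop()
        vals[last] = 1.0 - x_share - s_free
        return vals["a2"], vals["c2"], vals["e2"]

    if label == "ace2":
        sub = {z: groups[z] for z in _TWO_GROUPS}
        p = fit.parameters
        A, C, E = p["A"], p["C"], p["E"]
        T_hat = A + C + E
        shares_hat = {"a2": A / T_hat, "c2": C / T_hat, "e2": E / T_hat}
        free_name = "c2" if component == "a2" else "a2"
        base_const = 0.0
        mu_start = [p["mu"]]

        def neg2ll_at(share_value, x):
            a2, c2, e2 = shares_from(share_value, x[-1])
            T = x[-2]
            if T <= 0:
                return np.inf
            out = 0.0
            for z in _TWO_GROUPS:
                out += _ace_group_neg2ll(sub[z], z, x[0], a2 * T, c2 * T, e2 * T)
            return out

    elif label == "ace4_free":
        if sex not in ("M", "F"):
            raise ValueError("ace4_free profiles are per sex; pass sex='M' or 'F'")
        sub = {z: groups[f"{z}_{sex}"] for z in _TWO_GROUPS}
        p = fit.parameters
        A, C, E = p[f"A_{sex}"], p[f"C_{sex}"], p[f"E_{sex}"]
        T_hat = A + C + E
        shares_hat = {"a2": A / T_hat, "c2": C / T_hat, "e2": E / T_hat}
        free_name = "c2" if component == "a2" else "a2"
        other = "F" if sex == "M" else "M"
        other_groups = {z: groups[f"{z}_{other}"] for z in _TWO_GROUPS}
        _, other_m2ll, _, _ = _fit_ace_2group(other_groups)
        base_const = other_m2ll
        mu_start = [p[f"mu_{sex}"]]

        def neg2ll_at(share_value, x):
            a2, c2, e2 = shares_from(share_value, x[-1])
            T = x[-2]
            if T <= 0:
                return np.inf
            out = 0.0
            for z in _TWO_GROUPS:
                out += _ace_group_neg2ll(sub[z], z, x[0], a2 * T, c2 * T, e2 * T)
            return out

    elif label == "ace4_equal":
        p = fit.parameters
        A, C, E = p["A"], p["C"], p["E"]
        T_hat = A + C + E
        shares_hat = {"a2": A / T_hat, "c2": C / T_hat, "e2": E / T_hat}
        free_name = "c2" if component == "a2" else "a2"
        base_const = 0.0
        mu_start = [p["mu_M"], p["mu_F"]]

        def neg2ll_at(share_value, x):
            a2, c2, e2 = shares_from(share_value, x[-1])
            T = x[-2]
            if T <= 0:
                return np.inf
            out = 0.0
            for name, g in groups.items():
                zyg, s = name.split("_")
                mu = x[0] if s == "M" else x[1]
                out += _ace_group_neg2ll(g, zyg, mu, a2 * T, c2 * T, e2 * T)
            return out

    else:
        raise ValueError(f"profile CIs are defined for ACE fits, not {label!r}")

    x_start = np.array(mu_start + [T_hat, shares_hat[free_name]])

    def profile(share_value: float, warm: np.ndarray | None = None) -> tuple[float, np.ndarray]:
        def obj(x):
            return neg2ll_at(share_value, x)

        # find a feasible start: warm solution, the unconstrained optimum,
        # then heuristic free-share values inside the PD region
        candidates = ([] if warm is None else [warm]) + [x_start]
        for s_free in np.linspace(-0.8, 1.5, 24):
            x = x_start.copy()
            x[-1] = s_free
            candidates.append(x)
        x0 = None
        for cand in candidates:
            if np.isfinite(obj(cand)):
                x0 = cand
                break
        if x0 is None:
            return np.inf, x_start
        res = optimize.minimize(obj, x0, method="Nelder-Mead", options=_PROFILE_NM_OPTS)
        return float(res.fun) + base_const, res.x

    return profile, shares_hat[component]


def profile_neg2ll(
    fit: FitResult, component: str, value: float, sex: str | None = None
) -> float:
    """Profile -2lnL with one standardized share constrained to ``value``."""
    profile, _ = _profile_obj_factory(fit, component, sex)
    f, _ = profile(value)
    return f


def profile_ci(
    fit: FitResult,
    component: str,
    level: float = 0.95,
    sex: str | None = None,
) -> tuple[float, float]:
    """Profile-likelihood CI for a standardized share (a2, c2 or e2).

    Each bound is where the profile -2lnL (all other parameters
    re-optimized) rises by the chi-square(1) quantile (3.841 at 95%) above
    the minimum, located by expanding brackets plus bisection. A bound that
    cannot be bracketed inside the positive-definite region is returned as
    NaN (one-sided interval) with a note in ``fit.extra``.
    """
    if not fit.converged:
        raise FitError("cannot profile a non-converged fit")
    profile, s_hat = _profile_obj_factory(fit, component, sex)
    crit = float(stats.chi2.ppf(level, 1))
    f_min, warm_hat = profile(s_hat)
    # the constrained fit at the estimate should equal the global minimum
    f_min = min(f_min, fit.minus2LL)
    target = f_min + crit

    def search(direction: float) -> float:
        step = 0.05
        prev_s, prev_f = s_hat, f_min
        warm = warm_hat
        for _ in range(60):
            s = prev_s + direction * step
            f, warm_new = profile(s, warm)
            if f >= target:
                # bisect between prev_s (below target) and s (at/above)
                lo_s, hi_s = prev_s, s
                warm_b = warm
                for _ in range(60):
                    mid = 0.5 * (lo_s + hi_s)
                    fm, warm_b = profile(mid, warm_b)
                    if fm >= target:
                        hi_s = mid
                    else:
                        lo_s = mid
                    if abs(hi_s - lo_s) < 1e-5:
                        break
                return 0.5 * (lo_s + hi_s)
            prev_s, prev_f, warm = s, f, warm_new
            step *= 1.5
            if abs(prev_s) > 25:
                break
        fit.extra.setdefault("ci_notes", []).append(
            f"{component}{'_' + sex if sex else ''}: "
            f"{'upper' if direction > 0 else 'lower'} bound not bracketable"
        )
        return np.nan

    lower = search(-1.0)
    upper = search(+1.0)
    return lower, upper


# -- the five-model battery -------------------------------------------------


def model_battery(
    table: pd.DataFrame,
    phenotype: str,
    ci_level: float = 0.95,
    by_sex_ci: bool = True,
) -> dict:
    """Fit the five-model battery to one (already preprocessed) phenotype.

    Returns one flat results row: stratified correlations, Levene p-values,
    the five -2lnL values, standardized ACE estimates with profile CIs
    overall and by sex, the assumption test (ace2 vs sat2) and the sex-
    heterogeneity test (ace4_equal vs ace4_free). Errors at any stage are
    captured in ``status`` rather than raised, so batch runs continue.
    """
    row: dict = {"phenotype": phenotype, "status": "ok"}
    try:
        corr = twin_correlations(table, phenotype, by_sex=True)
        row.update(
            r_mz=corr.r_mz,
            r_dz=corr.r_dz,
            r_mz_m=corr.r_mz_m,
            r_mz_f=corr.r_mz_f,
            r_dz_m=corr.r_dz_m,
            r_dz_f=corr.r_dz_f,
            n_mz=corr.n_pairs.get("MZ", 0),
            n_dz=corr.n_pairs.get("DZ", 0),
        )
        lev_z = levene(table, phenotype, "zygosity")
        lev_zs = levene(table, phenotype, "zygosity_sex")
        row.update(
            levene_zyg_stat=lev_z.statistic,
            levene_zyg_p=lev_z.p_value,
            levene_zygsex_stat=lev_zs.statistic,
            levene_zygsex_p=lev_zs.p_value,
        )
    except Exception as exc:  # noqa: BLE001 - battery isolates failures
        row["status"] = f"error:descriptives:{exc}"
        return row

    try:
        sat2 = fit_saturated(table, phenotype, "2group")
        ace2, est2 = fit_ace(table, phenotype, "2group")
        sat4 = fit_saturated(table, phenotype, "4group")
        ace4f, est4f = fit_ace(table, phenotype, "4group", equate_sex=False)
        ace4e, _ = fit_ace(table, phenotype, "4group", equate_sex=True)
        row.update(
            m2ll_sat2=sat2.minus2LL,
            m2ll_ace2=ace2.minus2LL,
            m2ll_sat4=sat4.minus2LL,
            m2ll_ace4_free=ace4f.minus2LL,
            m2ll_ace4_equal=ace4e.minus2LL,
        )
        _, _, p_assume = lrt(ace2, sat2)
        _, _, p_het = lrt(ace4e, ace4f)
        row.update(p_assumptions=p_assume, p_sex_het=p_het)

        e = est2["overall"]
        row.update(A=e.A, C=e.C, E=e.E, a2=e.a2, c2=e.c2, e2=e.e2, c_note=e.note)
        for comp in ("a2", "c2", "e2"):
            lo, hi = profile_ci(ace2, comp, level=ci_level)
            row[f"{comp}_lo"], row[f"{comp}_hi"] = lo, hi
        for sex in ("M", "F"):
            es = est4f[sex]
            tag = sex.lower()
            row.update(
                {f"a2_{tag}": es.a2, f"c2_{tag}": es.c2, f"e2_{tag}": es.e2}
            )
            if by_sex_ci:
                for comp in ("a2", "c2", "e2"):
                    lo, hi = profile_ci(ace4f, comp, level=ci_level, sex=sex)
                    row[f"{comp}_{tag}_lo"], row[f"{comp}_{tag}_hi"] = lo, hi
        ade = ace_to_ade(ace_shares(e.a2, e.c2, e.e2))
        row.update(ade_a2=ade.a2, ade_d2=ade.d2, ade_e2=ade.e2)
        row["converged_all"] = all(
            f.converged for f in (sat2, ace2, sat4, ace4f, ace4e)
        )
    except Exception as exc:  # noqa: BLE001
        row["status"] = f"error:biometric:{exc}"
    return row
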