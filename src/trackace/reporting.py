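"""Descriptives, decomposition tables, moderation curves, clustered crosstabs.

Twin correlations are double-entered (each pair contributes both
orderings), decomposition tables mirror the raw-path / raw-variance /
standardized-share layout of the main results, conditional-variance
curves evaluate the moderated components over a centered-performance
grid, and crosstabs of twin-level factors against tracking timing carry
a Rao-Scott second-order (Satterthwaite) correction for the dependence
of twins within a pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .ace_structure import ModeratedPathSet, standardize_components, variance_components
from .fiml_engine import FitResult
from .pair_data import PairTable

__all__ = [
    "CorrelationReport",
    "CrosstabReport",
    "twin_correlations",
    "decomposition_table",
    "conditional_variance_curves",
    "crosstab_with_raoscott",
    "crosstab_from_counts",
    "performance_bins",
    "CITO_BIN_EDGES",
    "homogeneity_checks",
]

#: default CITO performance bin edges (inclusive ranges, Table-4 style)
CITO_BIN_EDGES = (
    (500, 518), (519, 525), (526, 528), (529, 532),
    (533, 536), (537, 539), (540, 544), (545, 550),
)


# ---------------------------------------------------------------------------
# twin correlations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationReport:
    """Double-entry MZ and DZ twin correlations for one phenotype."""

    phenotype: str
    rho_mz: float | None
    rho_dz: float | None
    n_mz: int
    n_dz: int

    @property
    def available(self) -> bool:
        return self.rho_mz is not None and self.rho_dz is not None


def _double_entry(v1: np.ndarray, v2: np.ndarray) -> tuple[float | None, int]:
    ok = np.isfinite(v1) & np.isfinite(v2)
    n = int(ok.sum())
    if n < 2:
        return None, n
    u = np.concatenate([v1[ok], v2[ok]])
    w = np.concatenate([v2[ok], v1[ok]])
    if u.std() == 0:
        return 1.0, n
    return float(np.corrcoef(u, w)[0, 1]), n


def twin_correlations(table: PairTable, phenotype: str) -> CorrelationReport:
    """Double-entered Pearson twin correlation per zygosity.

    ``phenotype`` is "attainment" or "performance"; pairs with either
    twin missing are dropped, and with fewer than two complete pairs per
    zygosity the report is marked unavailable.
    """
    if phenotype not in ("attainment", "performance"):
        raise ValueError(f"unknown phenotype {phenotype!r}")
    df = table.df
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = df[df["zygosity"] == zyg]
        rho, n = _double_entry(
            sub[f"{phenotype}_1"].to_numpy(float), sub[f"{phenotype}_2"].to_numpy(float)
        )
        out[zyg] = (rho, n)
    return CorrelationReport(
        phenotype, out["MZ"][0], out["DZ"][0], out["MZ"][1], out["DZ"][1]
    )


# ---------------------------------------------------------------------------
# decomposition tables and moderation curves
# ---------------------------------------------------------------------------


def decomposition_table(fit: FitResult) -> pd.DataFrame:
    """Long-format results table mirroring the main decomposition layout.

    One row per (group, quantity): intercepts and paths with SEs, raw
    variance components at X = 0 (common, unique, and common + unique),
    totals, and standardized percentage shares.  A pure function of the
    fit: re-running yields identical output.
    """
    rows: list[tuple[str, str, float, float]] = []

    def se_of(status: str, role: str) -> float:
        v = fit.spec.status_map[(status, role)]
        return fit.se.get(v, np.nan) if isinstance(v, str) else np.nan

    for status in fit.spec.statuses:
        paths = fit.path_set(status)
        means = fit.means_model(status)
        vc = variance_components(paths, 0.0)
        std = standardize_components(vc)
        add = lambda q, val, se=np.nan: rows.append((status, q, float(val), se))
        add("intercept_performance", means.mu_x, se_of(status, "mu_x"))
        add("intercept_attainment", means.mu_y, se_of(status, "mu_y"))
        for role in ("a_xx", "c_xx", "e_xx", "a_yx", "c_yx", "e_yx",
                     "a_yy", "c_yy", "e_yy"):
            add(role, getattr(paths, role), se_of(status, role))
        if fit.spec.name == "2":
            for role in ("ap_yx", "cp_yx", "ep_yx", "ap_yy", "cp_yy", "ep_yy"):
                add(role, getattr(paths, role), se_of(status, role))
        add("V_x_A", vc.va_x); add("V_x_C", vc.vc_x); add("V_x_E", vc.ve_x)
        add("V_x_T", vc.vt_x)
        add("V_y_A_common", vc.va_common); add("V_y_C_common", vc.vc_common)
        add("V_y_E_common", vc.ve_common)
        add("V_y_A_unique", vc.va_unique); add("V_y_C_unique", vc.vc_unique)
        add("V_y_E_unique", vc.ve_unique)
        add("V_y_A", vc.va_y); add("V_y_C", vc.vc_y); add("V_y_E", vc.ve_y)
        add("V_y_T", vc.vt_y)
        for key in ("a_y", "c_y", "e_y", "a_x", "c_x", "e_x",
                    "a_common", "c_common", "e_common",
                    "a_unique", "c_unique", "e_unique"):
            if key in std:
                add(f"pct_{key}", 100.0 * std[key])
    return pd.DataFrame(rows, columns=["group", "quantity", "value", "se"])


def conditional_variance_curves(
    fit: FitResult | Mapping[str, ModeratedPathSet],
    x_grid: Sequence[float],
    statuses: Sequence[str] | None = None,
    x_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Raw and standardized variance components along a moderator grid.

    Evaluates the unique, common, and total A/C/E components of
    attainment at each centered-performance value per tracking status;
    standardized columns divide by the conditional total V_y|X.  Grid
    points outside ``x_range`` (when known) are flagged ``extrapolated``
    with a warning.
    """
    if isinstance(fit, FitResult):
        statuses = statuses or list(fit.spec.statuses)
        path_sets = {s: fit.path_set(s) for s in statuses}
    else:
        path_sets = dict(fit)
        statuses = statuses or list(path_sets)

    grid = np.asarray(list(x_grid), dtype=float)
    extrapolated = np.zeros(len(grid), dtype=bool)
    if x_range is not None:
        extrapolated = (grid < x_range[0]) | (grid > x_range[1])
        if extrapolated.any():
            warnings.warn("moderator grid extends outside the observed range")

    rows = []
    for status in statuses:
        ps = path_sets[status]
        for xv, extra in zip(grid, extrapolated):
            vc = variance_components(ps, float(xv))
            row = {
                "status": status, "x": float(xv), "extrapolated": bool(extra),
                "va_common": vc.va_common, "vc_common": vc.vc_common,
                "ve_common": vc.ve_common,
                "va_unique": vc.va_unique, "vc_unique": vc.vc_unique,
                "ve_unique": vc.ve_unique,
                "va_total": vc.va_y, "vc_total": vc.vc_y, "ve_total": vc.ve_y,
                "v_total": vc.vt_y,
            }
            for comp in ("a", "c", "e"):
                for part in ("common", "unique", "total"):
                    row[f"std_{comp}_{part}"] = row[f"v{comp}_{part}"] / row["v_total"]
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rao-Scott corrected crosstabs
# ---------------------------------------------------------------------------


@dataclass
class CrosstabReport:
    """Twin-level contingency table with a cluster-corrected test.

    ``rs_chi2`` is the second-order Rao-Scott corrected Pearson statistic
    (chi-square scale); ``f_stat`` the equivalent Satterthwaite F with
    fractional degrees of freedom (``df1``, ``df2``).  When built from
    printed counts alone, the correction fields are None.
    """

    counts: pd.DataFrame
    row_pct: pd.DataFrame
    n: int
    pearson_chi2: float | None = None
    df: int | None = None
    rs_chi2: float | None = None
    f_stat: float | None = None
    df1: float | None = None
    df2: float | None = None
    p_value: float | None = None


def crosstab_from_counts(counts: pd.DataFrame) -> CrosstabReport:
    """Counts-only report (row percentages and Pearson chi-square)."""
    counts = counts.astype(int)
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    chi2, _, df, _ = stats.chi2_contingency(counts.to_numpy(), correction=False)
    return CrosstabReport(
        counts=counts, row_pct=row_pct, n=int(counts.to_numpy().sum()),
        pearson_chi2=float(chi2), df=int(df),
    )


def crosstab_with_raoscott(
    rows: pd.Series | np.ndarray,
    cols: pd.Series | np.ndarray,
    clusters: pd.Series | np.ndarray,
) -> CrosstabReport:
    """Twin-level crosstab with Rao-Scott second-order correction.

    ``rows``/``cols`` are the twin-level factor values (e.g. performance
    bin by tracking timing) and ``clusters`` the pair identifiers.
    Records with either factor missing are excluded; empty rows/columns
    are dropped with a notice.  The Pearson chi-square is corrected by
    the generalized design effects of the independence contrasts
    (cluster linearization, equal weights) and referred to a
    Satterthwaite F with fractional degrees of freedom.
    """
    rows = pd.Series(np.asarray(rows, dtype=object))
    cols = pd.Series(np.asarray(cols, dtype=object))
    clusters = pd.Series(np.asarray(clusters, dtype=object))
    ok = rows.notna() & cols.notna()
    rows, cols, clusters = rows[ok], cols[ok], clusters[ok]

    counts = pd.crosstab(rows, cols)
    empty_rows = counts.index[(counts.sum(axis=1) == 0)].tolist()
    if empty_rows:
        warnings.warn(f"dropping empty rows: {empty_rows}")
        counts = counts.loc[counts.sum(axis=1) > 0]
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    R, C = counts.shape
    if R < 2 or C < 2:
        raise ValueError("crosstab needs at least 2 x 2 non-empty cells")

    n = int(counts.to_numpy().sum())
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    chi2 = float(stats.chi2_contingency(counts.to_numpy(), correction=False)[0])
    d = (R - 1) * (C - 1)

    # cell indicator matrix (n_twins, R*C), vectorized cell proportions p-hat
    ri = pd.Categorical(rows, categories=counts.index).codes
    ci = pd.Categorical(cols, categories=counts.columns).codes
    cell = ri * C + ci
    Y = np.zeros((len(rows), R * C))
    Y[np.arange(len(rows)), cell] = 1.0
    p = Y.mean(axis=0)

    # cluster linearization covariance of p-hat (equal weights)
    cl = pd.Categorical(clusters).codes
    M = int(cl.max()) + 1
    Z = np.zeros((M, R * C))
    np.add.at(Z, cl, Y - p)
    Z /= n
    factor = M / (M - 1.0)
    v_clust = factor * (Z.T @ Z)
    # multinomial covariance with the same finite-sample factor, so that
    # singleton clusters reproduce the Pearson statistic exactly
    v_mult = factor * (np.diag(p) - np.outer(p, p)) / n

    # Jacobian of the independence contrasts h_ij = p_ij - p_i. * p_.j
    pr = p.reshape(R, C).sum(axis=1)
    pc = p.reshape(R, C).sum(axis=0)
    J = np.zeros((d, R * C))
    k = 0
    for i in range(R - 1):
        for j in range(C - 1):
            for a in range(R):
                for b in range(C):
                    J[k, a * C + b] = (
                        (1.0 if (a == i and b == j) else 0.0)
                        - (pc[j] if a == i else 0.0)
                        - (pr[i] if b == j else 0.0)
                    )
            k += 1

    G0 = J @ v_mult @ J.T
    G1 = J @ v_clust @ J.T
    delta = np.real(linalg.eigvals(linalg.solve(G0, G1)))
    delta = np.clip(delta, 1e-12, None)
    dbar = float(delta.mean())
    a2 = float(((delta - dbar) ** 2).mean() / dbar**2)

    rs_chi2 = chi2 / (dbar * (1.0 + a2))
    df1 = d / (1.0 + a2)
    df2 = df1 * (M - 1.0)
    f_stat = chi2 / (d * dbar)
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return CrosstabReport(
        counts=counts, row_pct=row_pct, n=n,
        pearson_chi2=chi2, df=d, rs_chi2=float(rs_chi2),
        f_stat=float(f_stat), df1=float(df1), df2=float(df2), p_value=p_value,
    )


def performance_bins(
    values: np.ndarray | pd.Series,
    edges: Sequence[tuple[float, float]] = CITO_BIN_EDGES,
) -> pd.Series:
    """Bin raw performance scores into the CITO-style inclusive ranges."""
    values = pd.Series(np.asarray(values, dtype=float))
    out = pd.Series([None] * len(values), dtype=object)
    for lo, hi in edges:
        label = f"{int(lo)}-{int(hi)}"
        out[(values >= lo) & (values <= hi)] = label
    return out


# ---------------------------------------------------------------------------
# homogeneity (assumption) checks
# ---------------------------------------------------------------------------


def _bivariate_n2ll(
    params: np.ndarray, data: list[np.ndarray], male: list[np.ndarray], tie: list[dict]
) -> float:
    """-2LL of per-group bivariate normals with parameter tying.

    ``tie`` maps each group's roles (mu1, mu2, ls1, ls2, z, ds) to indices
    in the packed parameter vector; ls = log sd, z = atanh correlation,
    ds = mean shift for male twins (index -1 means fixed at zero).
    """
    total = 0.0
    for d, m, t in zip(data, male, tie):
        mu = np.array([params[t["mu1"]], params[t["mu2"]]])
        ds = params[t["ds"]] if t["ds"] >= 0 else 0.0
        sd = np.exp(np.array([params[t["ls1"]], params[t["ls2"]]]))
        rho = np.tanh(params[t["z"]])
        cov = np.array([
            [sd[0] ** 2, rho * sd[0] * sd[1]],
            [rho * sd[0] * sd[1], sd[1] ** 2],
        ])
        resid = d - mu - ds * m
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            return 1e10
        sol = np.linalg.solve(cov, resid.T).T
        quad = np.einsum("ij,ij->i", resid, sol)
        total += float(np.sum(2.0 * np.log(2.0 * np.pi) + logdet + quad))
    return total


def _fit_tied(
    data: list[np.ndarray], male: list[np.ndarray], tie: list[dict], n_par: int
) -> float:
    start = np.zeros(n_par)
    # initialize from pooled moments so convergence is quick
    pooled = np.vstack(data)
    for t in tie:
        start[t["mu1"]] = pooled[:, 0].mean()
        start[t["mu2"]] = pooled[:, 1].mean()
        start[t["ls1"]] = np.log(pooled[:, 0].std() + 1e-6)
        start[t["ls2"]] = np.log(pooled[:, 1].std() + 1e-6)
        start[t["z"]] = 0.3
    res = optimize.minimize(
        _bivariate_n2ll, start, args=(data, male, tie), method="L-BFGS-B",
        options={"maxiter": 1000, "gtol": 1e-7, "ftol": 1e-13},
    )
    return float(res.fun)


def homogeneity_checks(table: PairTable, phenotype: str = "attainment") -> pd.DataFrame:
    """Stepwise tests of mean/variance homogeneity by birth order, zygosity, sex.

    Starting from a saturated per-zygosity bivariate-normal model of
    (twin1, twin2) with a free male mean shift, variances are equated
    across birth order, then across zygosity, then means across birth
    order, then across zygosity, then the sex shift is set to zero; each
    step is an LRT against the previous model.  Twin correlations stay
    zygosity-specific throughout (MZ and DZ correlations genuinely differ
    under the ACE model).
    """
    df = table.df
    data, male = [], []
    for zyg in ("MZ", "DZ"):
        sub = df[df["zygosity"] == zyg]
        v = sub[[f"{phenotype}_1", f"{phenotype}_2"]].to_numpy(float)
        m = np.nan_to_num(sub[["male_1", "male_2"]].to_numpy(float))
        ok = np.isfinite(v).all(axis=1)
        if ok.sum() < 3:
            raise ValueError(f"not enough complete {zyg} pairs for {phenotype!r}")
        data.append(v[ok])
        male.append(m[ok])

    # parameter tying per step; indices allocated per constraint pattern
    def tie_for(equal_var_bo: bool, equal_var_zyg: bool, equal_mu_bo: bool,
                equal_mu_zyg: bool, no_sex: bool) -> tuple[list[dict], int]:
        names: dict[str, int] = {}

        def idx(name: str) -> int:
            return names.setdefault(name, len(names))

        ties = []
        for zyg in ("MZ", "DZ"):
            mz = "" if equal_mu_zyg else zyg
            vz = "" if equal_var_zyg else zyg
            ties.append({
                "mu1": idx(f"mu{mz}1" if not equal_mu_bo else f"mu{mz}"),
                "mu2": idx(f"mu{mz}2" if not equal_mu_bo else f"mu{mz}"),
                "ls1": idx(f"ls{vz}1" if not equal_var_bo else f"ls{vz}"),
                "ls2": idx(f"ls{vz}2" if not equal_var_bo else f"ls{vz}"),
                "z": idx(f"z{zyg}"),
                "ds": -1 if no_sex else idx("ds"),
            })
        return ties, len(names)

    steps = [
        ("saturated", (False, False, False, False, False)),
        ("variances equal across birth order", (True, False, False, False, False)),
        ("variances equal across zygosity", (True, True, False, False, False)),
        ("means equal across birth order", (True, True, True, False, False)),
        ("means equal across zygosity", (True, True, True, True, False)),
        ("no sex difference in means", (True, True, True, True, True)),
    ]
    rows = []
    prev: tuple[float, int] | None = None
    for label, pattern in steps:
        tie, n_par = tie_for(*pattern)
        n2ll = _fit_tied(data, male, tie, n_par)
        if prev is None:
            rows.append((label, n2ll, n_par, np.nan, np.nan, np.nan))
        else:
            chi2 = max(n2ll - prev[0], 0.0)
            ddf = prev[1] - n_par
            p = float(stats.chi2.sf(chi2, ddf)) if ddf > 0 else np.nan
            rows.append((label, n2ll, n_par, chi2, ddf, p))
        prev = (n2ll, n_par)
    return pd.DataFrame(
        rows, columns=["step", "neg2_loglik", "n_free", "lrt_chi2", "lrt_df", "p_value"]
    )
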