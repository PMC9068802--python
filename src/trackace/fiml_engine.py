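"""Multigroup FIML estimation of moderated Cholesky ACE models.

Each pair contributes the Gaussian log-likelihood of its *observed*
subvector of (x1, y1, x2, y2), where the model-implied mean and
covariance are built from each twin's own tracking status and centered
performance (definition variables).  Twins with a missing moderator
contribute no performance or attainment term, but their co-twin does.

Model specifications follow the study's progression:

* Model 1a — one parameter set shared by every tracking status;
* Model 1b — a full set (intercepts, x paths, common and unique y paths)
  per status, moderation fixed at zero;
* Model 2  — Model 1b plus six free moderation slopes per status.

Covariate slopes (sex, birth year) are shared across all groups in every
model.  The central estimator is :class:`CholeskyACE`, a scikit-learn
style estimator; :func:`fit_model` and friends are thin wrappers.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .ace_structure import MeansModel, ModeratedPathSet
from .pair_data import DELAYED, IMMEDIATE, MISSING, PairTable, RELATEDNESS

__all__ = [
    "STATUS_ORDER",
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "CholeskyACE",
    "neg2_loglik",
    "fit_model",
    "likelihood_ratio_test",
    "aic",
    "delta_ci",
]

STATUS_ORDER = (IMMEDIATE, DELAYED, MISSING)

#: per-status parameter roles, in reporting order
STATUS_ROLES = (
    "mu_x", "mu_y",
    "a_xx", "c_xx", "e_xx",
    "a_yx", "c_yx", "e_yx",
    "a_yy", "c_yy", "e_yy",
    "ap_yx", "cp_yx", "ep_yx",
    "ap_yy", "cp_yy", "ep_yy",
    "b_mod_y",
)
#: moderation slope roles (fixed at zero outside Model 2)
SLOPE_ROLES = ("ap_yx", "cp_yx", "ep_yx", "ap_yy", "cp_yy", "ep_yy")
#: covariate slopes shared across all groups
GLOBAL_ROLES = ("b_male_x", "b_male_y", "b_yob_x", "b_yob_y")

_LOG2PI = float(np.log(2.0 * np.pi))
_SINGULAR_PENALTY = 1.0e8


class EstimationError(RuntimeError):
    """All optimizer starts failed."""


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Map from (status, role) to a named free parameter or a fixed value.

    Equality constraints across tracking statuses are expressed by mapping
    several (status, role) cells to the same parameter name; entries that
    are floats are fixed.  ``global_map`` handles the covariate slopes
    shared by all groups.
    """

    name: str
    statuses: tuple[str, ...]
    status_map: Mapping[tuple[str, str], str | float]
    global_map: Mapping[str, str | float]
    moderator_mean: bool = False

    def __post_init__(self) -> None:
        for status in self.statuses:
            for role in STATUS_ROLES:
                if (status, role) not in self.status_map:
                    raise ValueError(f"spec {self.name!r}: no entry for {(status, role)}")
        for role in GLOBAL_ROLES:
            if role not in self.global_map:
                raise ValueError(f"spec {self.name!r}: no entry for global {role!r}")

    @property
    def free_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for role in GLOBAL_ROLES:
            v = self.global_map[role]
            if isinstance(v, str) and v not in names:
                names.append(v)
        for status in self.statuses:
            for role in STATUS_ROLES:
                v = self.status_map[(status, role)]
                if isinstance(v, str) and v not in names:
                    names.append(v)
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def value(self, params: Mapping[str, float], status: str, role: str) -> float:
        v = self.status_map[(status, role)]
        return params[v] if isinstance(v, str) else float(v)

    def global_value(self, params: Mapping[str, float], role: str) -> float:
        v = self.global_map[role]
        return params[v] if isinstance(v, str) else float(v)

    # -- constructors -------------------------------------------------------

    @classmethod
    def model_1a(cls, statuses: Sequence[str] = STATUS_ORDER) -> "ModelSpec":
        """All statuses share one parameter set; no moderation."""
        smap: dict[tuple[str, str], str | float] = {}
        for status in statuses:
            for role in STATUS_ROLES:
                if role in SLOPE_ROLES or role == "b_mod_y":
                    smap[(status, role)] = 0.0
                else:
                    smap[(status, role)] = role
        return cls("1a", tuple(statuses), smap, {r: r for r in GLOBAL_ROLES})

    @classmethod
    def model_1b(cls, statuses: Sequence[str] = STATUS_ORDER) -> "ModelSpec":
        """Status-specific parameter sets; no moderation."""
        smap: dict[tuple[str, str], str | float] = {}
        for status in statuses:
            for role in STATUS_ROLES:
                if role in SLOPE_ROLES or role == "b_mod_y":
                    smap[(status, role)] = 0.0
                else:
                    smap[(status, role)] = f"{role}@{status}"
        return cls("1b", tuple(statuses), smap, {r: r for r in GLOBAL_ROLES})

    @classmethod
    def model_2(
        cls, statuses: Sequence[str] = STATUS_ORDER, moderator_mean: bool = False
    ) -> "ModelSpec":
        """Status-specific sets plus free moderation slopes per status."""
        smap: dict[tuple[str, str], str | float] = {}
        for status in statuses:
            for role in STATUS_ROLES:
                if role == "b_mod_y":
                    smap[(status, role)] = f"{role}@{status}" if moderator_mean else 0.0
                else:
                    smap[(status, role)] = f"{role}@{status}"
        return cls("2", tuple(statuses), smap, {r: r for r in GLOBAL_ROLES},
                   moderator_mean=moderator_mean)

    @classmethod
    def from_name(cls, name: str, statuses: Sequence[str] = STATUS_ORDER) -> "ModelSpec":
        try:
            ctor = {"1a": cls.model_1a, "1b": cls.model_1b, "2": cls.model_2}[name]
        except KeyError:
            raise ValueError(f"unknown model name {name!r}; expected 1a, 1b or 2")
        return ctor(statuses)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statuses": list(self.statuses),
            "status_map": {f"{s}.{r}": v for (s, r), v in self.status_map.items()},
            "global_map": dict(self.global_map),
            "moderator_mean": self.moderator_mean,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        smap = {}
        for key, v in d["status_map"].items():
            s, r = key.split(".", 1)
            smap[(s, r)] = v
        return cls(d["name"], tuple(d["statuses"]), smap, dict(d["global_map"]),
                   d.get("moderator_mean", False))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# prepared data
# ---------------------------------------------------------------------------


@dataclass
class _Prepared:
    """Arrays extracted once per fit from a pair table."""

    y: np.ndarray          # (n, 4) data vector (x1, y1, x2, y2), NaN if missing
    mask: np.ndarray       # (n, 4) observed flags
    status_idx: np.ndarray  # (n, 2) index into spec.statuses
    x_mod: np.ndarray      # (n, 2) centered moderator, 0 where missing
    male: np.ndarray       # (n, 2)
    yob_c: np.ndarray      # (n, 2)
    r: np.ndarray          # (n,) relatedness
    pattern_groups: dict[tuple[int, ...], np.ndarray]
    n_obs_stats: int
    group_sizes: pd.Series

    @classmethod
    def from_table(cls, table: PairTable, statuses: Sequence[str]) -> "_Prepared":
        df = table.df
        n = len(df)
        status_lut = {s: i for i, s in enumerate(statuses)}

        x = df[["performance_centered_1", "performance_centered_2"]].to_numpy(float)
        att = df[["attainment_1", "attainment_2"]].to_numpy(float)
        male = np.nan_to_num(df[["male_1", "male_2"]].to_numpy(float))
        yob = df[["birth_year_1", "birth_year_2"]].to_numpy(float)
        yob_c = np.nan_to_num(yob - table.birth_year_mean)

        status_idx = np.zeros((n, 2), dtype=int)
        for i in (1, 2):
            col = table.tracking_status(i)
            unknown = sorted(set(col.unique()) - set(statuses))
            if unknown:
                raise ValueError(
                    f"data contain tracking statuses {unknown} absent from the spec"
                )
            status_idx[:, i - 1] = col.map(status_lut).to_numpy()

        x_obs = np.isfinite(x)
        # a twin with missing moderator contributes no likelihood term at all
        y_obs = np.isfinite(att) & x_obs
        mask = np.stack([x_obs[:, 0], y_obs[:, 0], x_obs[:, 1], y_obs[:, 1]], axis=1)
        data = np.stack([x[:, 0], att[:, 0], x[:, 1], att[:, 1]], axis=1)
        data = np.where(mask, data, 0.0)

        if not mask.any():
            raise ValueError("analysis sample is empty: no twin has an observed moderator")

        patterns: dict[tuple[int, ...], list[int]] = {}
        for idx in range(n):
            key = tuple(np.flatnonzero(mask[idx]))
            if key:
                patterns.setdefault(key, []).append(idx)
        pattern_groups = {k: np.asarray(v) for k, v in patterns.items()}

        from .pair_data import assign_pair_group  # local import avoids cycle at module load
        labels = [str(assign_pair_group(p)) for p in table.pairs()]
        group_sizes = pd.Series(labels, dtype="object").value_counts().sort_index()

        return cls(
            y=data,
            mask=mask,
            status_idx=status_idx,
            x_mod=np.where(x_obs, np.nan_to_num(x), 0.0),
            male=male,
            yob_c=yob_c,
            r=df["zygosity"].map(RELATEDNESS).to_numpy(float),
            pattern_groups=pattern_groups,
            n_obs_stats=int(mask.sum()),
            group_sizes=group_sizes,
        )


class _SpecIndex:
    """Cached mapping between a spec's (status, role) cells and theta entries."""

    def __init__(self, spec: ModelSpec):
        names = spec.free_names
        pos = {n: i for i, n in enumerate(names)}
        ns = len(spec.statuses)
        self.k = len(names)
        self.status_tgt: dict[str, np.ndarray] = {}
        self.status_fix: dict[str, np.ndarray] = {}
        for role in STATUS_ROLES:
            tgt = np.full(ns, -1, dtype=int)
            fix = np.zeros(ns)
            for si, s in enumerate(spec.statuses):
                v = spec.status_map[(s, role)]
                if isinstance(v, str):
                    tgt[si] = pos[v]
                else:
                    fix[si] = float(v)
            self.status_tgt[role] = tgt
            self.status_fix[role] = fix
        self.global_tgt: dict[str, int] = {}
        self.global_fix: dict[str, float] = {}
        for role in GLOBAL_ROLES:
            v = spec.global_map[role]
            self.global_tgt[role] = pos[v] if isinstance(v, str) else -1
            self.global_fix[role] = 0.0 if isinstance(v, str) else float(v)

    def role_values(self, theta: np.ndarray, role: str) -> np.ndarray:
        tgt = self.status_tgt[role]
        return np.where(tgt >= 0, theta[np.clip(tgt, 0, None)], self.status_fix[role])

    def global_value(self, theta: np.ndarray, role: str) -> float:
        tgt = self.global_tgt[role]
        return float(theta[tgt]) if tgt >= 0 else self.global_fix[role]

    def scatter_status(self, g: np.ndarray, role: str, by_status: np.ndarray) -> None:
        tgt = self.status_tgt[role]
        for si in range(len(tgt)):
            if tgt[si] >= 0:
                g[tgt[si]] += by_status[si]

    def scatter_global(self, g: np.ndarray, role: str, value: float) -> None:
        tgt = self.global_tgt[role]
        if tgt >= 0:
            g[tgt] += value


def _implied_moments(
    theta: np.ndarray, sx: _SpecIndex, prep: _Prepared
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Batched model-implied mean (n, 4), covariance (n, 4, 4), and the
    per-twin effective path arrays used by the analytic gradient."""
    si = prep.status_idx
    X = prep.x_mod

    def role(name: str) -> np.ndarray:
        return sx.role_values(theta, name)[si]  # (n, 2)

    P = {
        "a_xx": role("a_xx"), "c_xx": role("c_xx"), "e_xx": role("e_xx"),
        "a_yx": role("a_yx") + role("ap_yx") * X,
        "c_yx": role("c_yx") + role("cp_yx") * X,
        "e_yx": role("e_yx") + role("ep_yx") * X,
        "a_yy": role("a_yy") + role("ap_yy") * X,
        "c_yy": role("c_yy") + role("cp_yy") * X,
        "e_yy": role("e_yy") + role("ep_yy") * X,
    }
    axx, cxx, exx = P["a_xx"], P["c_xx"], P["e_xx"]
    ayx, cyx, eyx = P["a_yx"], P["c_yx"], P["e_yx"]
    ayy, cyy, eyy = P["a_yy"], P["c_yy"], P["e_yy"]
    r = prep.r

    n = si.shape[0]
    sigma = np.empty((n, 4, 4))
    for t in (0, 1):
        o = 2 * t
        sigma[:, o, o] = axx[:, t] ** 2 + cxx[:, t] ** 2 + exx[:, t] ** 2
        sigma[:, o + 1, o + 1] = (
            ayx[:, t] ** 2 + cyx[:, t] ** 2 + eyx[:, t] ** 2
            + ayy[:, t] ** 2 + cyy[:, t] ** 2 + eyy[:, t] ** 2
        )
        within = axx[:, t] * ayx[:, t] + cxx[:, t] * cyx[:, t] + exx[:, t] * eyx[:, t]
        sigma[:, o, o + 1] = sigma[:, o + 1, o] = within
    sigma[:, 0, 2] = sigma[:, 2, 0] = r * axx[:, 0] * axx[:, 1] + cxx[:, 0] * cxx[:, 1]
    sigma[:, 0, 3] = sigma[:, 3, 0] = r * axx[:, 0] * ayx[:, 1] + cxx[:, 0] * cyx[:, 1]
    sigma[:, 2, 1] = sigma[:, 1, 2] = r * axx[:, 1] * ayx[:, 0] + cxx[:, 1] * cyx[:, 0]
    sigma[:, 1, 3] = sigma[:, 3, 1] = (
        r * (ayx[:, 0] * ayx[:, 1] + ayy[:, 0] * ayy[:, 1])
        + cyx[:, 0] * cyx[:, 1] + cyy[:, 0] * cyy[:, 1]
    )

    mu = np.empty((n, 4))
    mu_x, mu_y = role("mu_x"), role("mu_y")
    b_mod_y = role("b_mod_y")
    b_male_x = sx.global_value(theta, "b_male_x")
    b_male_y = sx.global_value(theta, "b_male_y")
    b_yob_x = sx.global_value(theta, "b_yob_x")
    b_yob_y = sx.global_value(theta, "b_yob_y")
    for t in (0, 1):
        mu[:, 2 * t] = mu_x[:, t] + b_male_x * prep.male[:, t] + b_yob_x * prep.yob_c[:, t]
        mu[:, 2 * t + 1] = (
            mu_y[:, t]
            + b_male_y * prep.male[:, t]
            + b_yob_y * prep.yob_c[:, t]
            + b_mod_y[:, t] * X[:, t]
        )
    return mu, sigma, P


def _n2ll_and_grad(
    theta: np.ndarray,
    spec: ModelSpec,
    prep: _Prepared,
    sx: _SpecIndex | None = None,
    want_grad: bool = False,
):
    """FIML -2 log-likelihood and, optionally, its analytic gradient.

    The gradient uses the Gaussian score W = S^-1 - S^-1 r r^T S^-1 per
    observed block, chained through the bilinear path structure of the
    implied covariance and through the spec's parameter tying.
    """
    sx = sx or _SpecIndex(spec)
    mu, sigma, P = _implied_moments(theta, sx, prep)
    resid = prep.y - mu
    n = len(resid)
    total = 0.0
    penalized = False
    if want_grad:
        W = np.zeros((n, 4, 4))
        gmu = np.zeros((n, 4))
    for obs, idx in prep.pattern_groups.items():
        k = len(obs)
        sub = sigma[np.ix_(idx, obs, obs)]
        rs = resid[np.ix_(idx, obs)]
        sign, logdet = np.linalg.slogdet(sub)
        good = sign > 0
        if not good.all():
            penalized = True
            total += float(np.sum(~good)) * _SINGULAR_PENALTY
            idx, sub, rs, logdet = idx[good], sub[good], rs[good], logdet[good]
            if len(idx) == 0:
                continue
        sinv = np.linalg.inv(sub)
        sol = np.einsum("nij,nj->ni", sinv, rs)
        quad = np.einsum("ni,ni->n", rs, sol)
        total += float(np.sum(k * _LOG2PI + logdet + quad))
        if want_grad:
            w = sinv - sol[:, :, None] * sol[:, None, :]
            W[np.ix_(idx, obs, obs)] = w
            gmu[np.ix_(idx, obs)] = -2.0 * sol
    if penalized:
        warnings.warn(
            "singular model-implied covariance encountered; penalizing",
            RuntimeWarning,
            stacklevel=3,
        )
    if not np.isfinite(total):
        total = _SINGULAR_PENALTY * n
    if not want_grad:
        return total

    r = prep.r
    axx, cxx, exx = P["a_xx"], P["c_xx"], P["e_xx"]
    ayx, cyx, eyx = P["a_yx"], P["c_yx"], P["e_yx"]
    ayy, cyy, eyy = P["a_yy"], P["c_yy"], P["e_yy"]
    dP = {name: np.zeros_like(axx) for name in P}
    for t in (0, 1):
        o, u = 2 * t, 1 - t
        ou = 2 * u
        woo = W[:, o, o]
        woy = W[:, o, o + 1]
        wyy = W[:, o + 1, o + 1]
        wxx_c = W[:, o, ou]          # cov(x_t, x_u)
        wxy_c = W[:, o, ou + 1]      # cov(x_t, y_u)
        wyx_c = W[:, ou, o + 1]      # cov(x_u, y_t)
        wyy_c = W[:, o + 1, ou + 1]  # cov(y_t, y_u)
        dP["a_xx"][:, t] = 2 * (woo * axx[:, t] + woy * ayx[:, t]
                                + wxx_c * r * axx[:, u] + wxy_c * r * ayx[:, u])
        dP["c_xx"][:, t] = 2 * (woo * cxx[:, t] + woy * cyx[:, t]
                                + wxx_c * cxx[:, u] + wxy_c * cyx[:, u])
        dP["e_xx"][:, t] = 2 * (woo * exx[:, t] + woy * eyx[:, t])
        dP["a_yx"][:, t] = 2 * (wyy * ayx[:, t] + woy * axx[:, t]
                                + wyx_c * r * axx[:, u] + wyy_c * r * ayx[:, u])
        dP["c_yx"][:, t] = 2 * (wyy * cyx[:, t] + woy * cxx[:, t]
                                + wyx_c * cxx[:, u] + wyy_c * cyx[:, u])
        dP["e_yx"][:, t] = 2 * (wyy * eyx[:, t] + woy * exx[:, t])
        dP["a_yy"][:, t] = 2 * (wyy * ayy[:, t] + wyy_c * r * ayy[:, u])
        dP["c_yy"][:, t] = 2 * (wyy * cyy[:, t] + wyy_c * cyy[:, u])
        dP["e_yy"][:, t] = 2 * (wyy * eyy[:, t])

    g = np.zeros(sx.k)
    ns = len(spec.statuses)
    st_flat = prep.status_idx.ravel()
    X = prep.x_mod

    def by_status(weights: np.ndarray) -> np.ndarray:
        return np.bincount(st_flat, weights=weights.ravel(), minlength=ns)

    slope_of = {"a_yx": "ap_yx", "c_yx": "cp_yx", "e_yx": "ep_yx",
                "a_yy": "ap_yy", "c_yy": "cp_yy", "e_yy": "ep_yy"}
    for name, d in dP.items():
        sx.scatter_status(g, name, by_status(d))
        if name in slope_of:
            sx.scatter_status(g, slope_of[name], by_status(d * X))
    dmu_x = gmu[:, (0, 2)]
    dmu_y = gmu[:, (1, 3)]
    sx.scatter_status(g, "mu_x", by_status(dmu_x))
    sx.scatter_status(g, "mu_y", by_status(dmu_y))
    sx.scatter_status(g, "b_mod_y", by_status(dmu_y * X))
    sx.scatter_global(g, "b_male_x", float(np.sum(dmu_x * prep.male)))
    sx.scatter_global(g, "b_male_y", float(np.sum(dmu_y * prep.male)))
    sx.scatter_global(g, "b_yob_x", float(np.sum(dmu_x * prep.yob_c)))
    sx.scatter_global(g, "b_yob_y", float(np.sum(dmu_y * prep.yob_c)))
    return total, g


def _neg2_loglik_prepared(theta: np.ndarray, spec: ModelSpec, prep: _Prepared) -> float:
    return _n2ll_and_grad(theta, spec, prep, want_grad=False)


def neg2_loglik(
    params: Mapping[str, float] | Sequence[float],
    spec: ModelSpec,
    pairs: PairTable,
) -> float:
    """-2 log-likelihood of a pair table under ``spec`` at ``params``.

    ``params`` may be a mapping from free-parameter names to values or a
    vector ordered as ``spec.free_names``.
    """
    theta = _as_theta(params, spec)
    prep = _Prepared.from_table(pairs, spec.statuses)
    return _neg2_loglik_prepared(theta, spec, prep)


def _as_theta(params, spec: ModelSpec) -> np.ndarray:
    if isinstance(params, Mapping):
        missing = [n for n in spec.free_names if n not in params]
        if missing:
            raise ValueError(f"missing values for parameters {missing}")
        return np.array([float(params[n]) for n in spec.free_names])
    theta = np.asarray(params, dtype=float)
    if theta.shape != (spec.n_free,):
        raise ValueError(f"expected {spec.n_free} parameters, got shape {theta.shape}")
    return theta


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, uncertainty, and diagnostics of one model fit."""

    spec: ModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    cov: np.ndarray | None
    neg2_loglik: float
    n_free: int
    n_obs_stats: int
    n_pairs: int
    group_sizes: dict[str, int]
    converged: bool
    grad_norm: float
    n_restarts: int
    seed: int
    moderator_mean_used: bool = False

    @property
    def aic(self) -> float:
        """Standard convention: -2LL + 2k."""
        return self.neg2_loglik + 2.0 * self.n_free

    @property
    def aic_mx(self) -> float:
        """Mx convention: -2LL - 2 * (observed statistics - k)."""
        return self.neg2_loglik - 2.0 * (self.n_obs_stats - self.n_free)

    def path_set(self, status: str) -> ModeratedPathSet:
        v = lambda role: self.spec.value(self.estimates, status, role)
        return ModeratedPathSet(
            a_xx=v("a_xx"), c_xx=v("c_xx"), e_xx=v("e_xx"),
            a_yx=v("a_yx"), c_yx=v("c_yx"), e_yx=v("e_yx"),
            a_yy=v("a_yy"), c_yy=v("c_yy"), e_yy=v("e_yy"),
            ap_yx=v("ap_yx"), cp_yx=v("cp_yx"), ep_yx=v("ep_yx"),
            ap_yy=v("ap_yy"), cp_yy=v("cp_yy"), ep_yy=v("ep_yy"),
        )

    def means_model(self, status: str) -> MeansModel:
        v = lambda role: self.spec.value(self.estimates, status, role)
        g = lambda role: self.spec.global_value(self.estimates, role)
        return MeansModel(
            mu_x=v("mu_x"), mu_y=v("mu_y"),
            b_male_x=g("b_male_x"), b_male_y=g("b_male_y"),
            b_yob_x=g("b_yob_x"), b_yob_y=g("b_yob_y"),
            b_mod_y=v("b_mod_y"),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "spec": self.spec.to_dict(),
            "estimates": self.estimates,
            "se": self.se,
            "neg2_loglik": self.neg2_loglik,
            "n_free": self.n_free,
            "n_obs_stats": self.n_obs_stats,
            "n_pairs": self.n_pairs,
            "group_sizes": self.group_sizes,
            "aic": self.aic,
            "aic_mx": self.aic_mx,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "moderator_mean_used": self.moderator_mean_used,
        }
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FitResult":
        p = Path(source)
        d = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            estimates=d["estimates"],
            se=d["se"],
            cov=None,
            neg2_loglik=d["neg2_loglik"],
            n_free=d["n_free"],
            n_obs_stats=d["n_obs_stats"],
            n_pairs=d["n_pairs"],
            group_sizes=d["group_sizes"],
            converged=d["converged"],
            grad_norm=d["grad_norm"],
            n_restarts=d["n_restarts"],
            seed=d["seed"],
            moderator_mean_used=d.get("moderator_mean_used", False),
        )

    def to_tsv(self, path: str | Path | None = None) -> pd.DataFrame:
        """Long-format parameter table (one row per status x role)."""
        rows = []
        for role in GLOBAL_ROLES:
            name = self.spec.global_map[role]
            if isinstance(name, str):
                rows.append(("all", role, self.estimates[name], self.se.get(name, np.nan)))
        for status in self.spec.statuses:
            for role in STATUS_ROLES:
                v = self.spec.status_map[(status, role)]
                if isinstance(v, str):
                    rows.append((status, role, self.estimates[v], self.se.get(v, np.nan)))
                else:
                    rows.append((status, role, float(v), np.nan))
        df = pd.DataFrame(rows, columns=["group", "parameter", "estimate", "se"])
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of two nested fits."""

    statistic: float
    df: int
    p_value: float
    nested_name: str
    full_name: str


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def _double_entry_corr(a1: np.ndarray, a2: np.ndarray) -> float:
    ok = np.isfinite(a1) & np.isfinite(a2)
    if ok.sum() < 2:
        return 0.0
    u = np.concatenate([a1[ok], a2[ok]])
    v = np.concatenate([a2[ok], a1[ok]])
    if u.std() == 0 or v.std() == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def _falconer_paths(
    values1: np.ndarray, values2: np.ndarray, zyg: np.ndarray
) -> tuple[float, float, float]:
    """Method-of-moments ACE paths from double-entry twin correlations."""
    mz, dz = zyg == "MZ", zyg == "DZ"
    r_mz = _double_entry_corr(values1[mz], values2[mz])
    r_dz = _double_entry_corr(values1[dz], values2[dz])
    var = float(np.nanvar(np.concatenate([values1, values2])))
    if var <= 0:
        var = 1.0
    a2 = np.clip(2.0 * (r_mz - r_dz), 0.05, 0.85)
    c2 = np.clip(2.0 * r_dz - r_mz, 0.02, 0.85)
    e2 = max(1.0 - a2 - c2, 0.1)
    total = a2 + c2 + e2
    return tuple(np.sqrt(np.array([a2, c2, e2]) / total * var))  # type: ignore[return-value]


def moment_start(spec: ModelSpec, table: PairTable) -> dict[str, float]:
    """Falconer-style method-of-moments starting values.

    Performance paths come from the twin correlations of x; the common
    attainment paths from the within-twin regression of y on x scaled
    onto the x paths; the unique paths from the residual decomposition.
    Moderation slopes and covariate slopes start at zero.
    """
    df = table.df
    zyg = df["zygosity"].to_numpy()
    x1 = df["performance_centered_1"].to_numpy(float)
    x2 = df["performance_centered_2"].to_numpy(float)
    y1 = df["attainment_1"].to_numpy(float)
    y2 = df["attainment_2"].to_numpy(float)

    ax, cx, ex = _falconer_paths(x1, x2, zyg)
    xs = np.concatenate([x1, x2])
    ys = np.concatenate([y1, y2])
    ok = np.isfinite(xs) & np.isfinite(ys)
    b = float(np.cov(xs[ok], ys[ok])[0, 1] / np.var(xs[ok])) if ok.sum() > 2 else 0.0
    res1, res2 = y1 - b * x1, y2 - b * x2
    au, cu, eu = _falconer_paths(res1, res2, zyg)
    mu_x = float(np.nanmean(xs))
    mu_y = float(np.nanmean(ys)) if np.isfinite(ys).any() else 0.0

    base = {
        "mu_x": mu_x, "mu_y": mu_y,
        "a_xx": ax, "c_xx": cx, "e_xx": ex,
        "a_yx": b * ax, "c_yx": b * cx, "e_yx": b * ex,
        "a_yy": au, "c_yy": cu, "e_yy": eu,
    }
    start: dict[str, float] = {}
    for role in GLOBAL_ROLES:
        v = spec.global_map[role]
        if isinstance(v, str):
            start[v] = 0.0
    for status in spec.statuses:
        for role in STATUS_ROLES:
            v = spec.status_map[(status, role)]
            if isinstance(v, str):
                start[v] = base.get(role, 0.0)
    return start


# factor groups whose loadings may be negated together without changing
# the likelihood.  A and C factors appear in cross-twin products, which mix
# tracking statuses in discordant pairs, so they may only be flipped
# globally (all statuses at once); E factors are twin-specific and can be
# flipped per status.
_GLOBAL_FLIPS = (
    ("a_xx", ("a_xx", "a_yx", "ap_yx")),
    ("c_xx", ("c_xx", "c_yx", "cp_yx")),
    ("a_yy", ("a_yy", "ap_yy")),
)
_PER_STATUS_FLIPS = (
    ("e_xx", ("e_xx", "e_yx", "ep_yx")),
    ("e_yy", ("e_yy", "ep_yy")),
)


def _canonicalize_signs(spec: ModelSpec, estimates: dict[str, float]) -> dict[str, float]:
    """Likelihood-preserving sign convention: a_xx, c_xx, e_xx, a_yy, e_yy >= 0.

    The >= 0 convention for the global factors is anchored at the first
    status; c_yy keeps its estimated sign (reported as estimated, variance
    components use squares).
    """
    out = dict(estimates)
    flips: set[str] = set()
    first = spec.statuses[0]
    for lead, group in _GLOBAL_FLIPS:
        v = spec.status_map[(first, lead)]
        if isinstance(v, str) and out[v] < 0:
            for status in spec.statuses:
                for role in group:
                    name = spec.status_map[(status, role)]
                    if isinstance(name, str):
                        flips.add(name)
    for status in spec.statuses:
        for lead, group in _PER_STATUS_FLIPS:
            v = spec.status_map[(status, lead)]
            if isinstance(v, str) and out[v] < 0:
                for role in group:
                    name = spec.status_map[(status, role)]
                    if isinstance(name, str):
                        flips.add(name)
    for name in flips:
        out[name] = -out[name]
    return out


def _hessian_covariance(hess: np.ndarray) -> tuple[np.ndarray | None, bool]:
    """Parameter covariance 2*H^-1 from the -2LL Hessian.

    Near-zero or negative curvature directions (a path estimated at zero
    has locally flat likelihood in its sign) are clipped in the
    eigendecomposition, which yields large/inf variances there instead of
    corrupting every standard error.
    """
    hess = 0.5 * (hess + hess.T)
    vals, vecs = np.linalg.eigh(hess)
    if not np.isfinite(vals).all():
        return None, True
    tol = 1e-10 * max(float(vals.max()), 1.0)
    ill = bool((vals <= tol).any())
    if (vals <= tol).all():
        return None, True
    inv_vals = np.where(vals > tol, 1.0 / np.clip(vals, tol, None), 1.0 / tol)
    cov = 2.0 * (vecs * inv_vals) @ vecs.T
    return cov, ill


def _fd_hessian(
    f: Callable[[np.ndarray], float],
    theta: np.ndarray,
    grad: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Central finite-difference Hessian with step 1e-4 * max(1, |theta|).

    When an analytic gradient is supplied the Hessian rows are central
    differences of the gradient (then symmetrized); otherwise a pure
    function-value stencil is used.
    """
    k = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    hess = np.empty((k, k))
    if grad is not None:
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            hess[i] = (grad(theta + ei) - grad(theta - ei)) / (2.0 * h[i])
        return 0.5 * (hess + hess.T)
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = f(theta + ei)
        fmm = f(theta - ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            fij = f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            hess[i, j] = hess[j, i] = fij / (4.0 * h[i] * h[j])
    return hess


class CholeskyACE(BaseEstimator):
    """Moderated bivariate Cholesky ACE twin model fitted by FIML.

    A scikit-learn style estimator over wide twin-pair tables.  ``fit``
    minimizes the FIML -2 log-likelihood by bounded quasi-Newton iteration
    (L-BFGS-B on the raw, unconstrained paths) from a method-of-moments
    start plus jittered restarts, and computes standard errors from the
    inverse of a central finite-difference Hessian at the optimum.

    Parameters
    ----------
    model : str or ModelSpec, default "1a"
        "1a" (one shared parameter set), "1b" (per-status sets), "2"
        (per-status sets plus moderation), or an explicit spec.  When a
        name is given, the statuses present in the data define the groups.
    n_restarts : int, default 5
        Total optimizer starts: the moment start plus jittered copies.
    seed : int, default 0
        Seed for the restart jitter.
    gtol, maxiter : optimizer settings (projected-gradient tolerance).
    compute_se : bool, default True
        Whether to compute the finite-difference Hessian and SEs.
    starts : mapping, optional
        Values overriding the moment start (e.g. a warm start from a
        nested fit).

    Attributes
    ----------
    params_ : dict mapping free-parameter names to estimates
    se_ : dict of standard errors
    result_ : the full :class:`FitResult`
    neg2_loglik_, aic_, aic_mx_, converged_, n_free_ : fit summaries
    """

    def __init__(
        self,
        model: str | ModelSpec = "1a",
        n_restarts: int = 5,
        seed: int = 0,
        gtol: float = 1e-5,
        maxiter: int = 2000,
        compute_se: bool = True,
        starts: Mapping[str, float] | None = None,
        jitter: float = 0.1,
    ):
        self.model = model
        self.n_restarts = n_restarts
        self.seed = seed
        self.gtol = gtol
        self.maxiter = maxiter
        self.compute_se = compute_se
        self.starts = starts
        self.jitter = jitter

    def _resolve_spec(self, table: PairTable) -> ModelSpec:
        if isinstance(self.model, ModelSpec):
            return self.model
        present = set(table.tracking_status(1)) | set(table.tracking_status(2))
        statuses = tuple(s for s in STATUS_ORDER if s in present)
        return ModelSpec.from_name(self.model, statuses)

    def fit(self, X: PairTable | pd.DataFrame, y=None) -> "CholeskyACE":
        table = X if isinstance(X, PairTable) else PairTable(X.copy())
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        spec = self._resolve_spec(table)
        prep = _Prepared.from_table(table, spec.statuses)
        rng = np.random.default_rng(self.seed)

        start = moment_start(spec, table)
        if self.starts:
            start.update({k: float(v) for k, v in self.starts.items() if k in start})
        theta0 = np.array([start[n] for n in spec.free_names])

        sx = _SpecIndex(spec)
        fun = lambda th: _neg2_loglik_prepared(th, spec, prep)
        fun_grad = lambda th: _n2ll_and_grad(th, spec, prep, sx=sx, want_grad=True)
        best = None
        failures = []
        for i in range(self.n_restarts):
            th = theta0 if i == 0 else theta0 * (1.0 + self.jitter * rng.standard_normal(len(theta0))) + 0.01 * self.jitter * rng.standard_normal(len(theta0))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = optimize.minimize(
                        fun_grad, th, jac=True, method="L-BFGS-B",
                        options={"maxiter": self.maxiter, "gtol": self.gtol,
                                 "ftol": 1e-12, "maxfun": 10 * self.maxiter},
                    )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(repr(exc))
                continue
            if not np.isfinite(res.fun):
                failures.append("non-finite objective")
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise EstimationError(f"all optimizer starts failed: {failures}")

        theta_hat = best.x
        grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
        estimates = _canonicalize_signs(spec, dict(zip(spec.free_names, theta_hat)))
        theta_hat = np.array([estimates[n] for n in spec.free_names])

        se: dict[str, float] = {}
        cov = None
        if self.compute_se:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                hess = _fd_hessian(fun, theta_hat, grad=lambda th: fun_grad(th)[1])
            cov, ill = _hessian_covariance(hess)
            if cov is None:
                warnings.warn("singular Hessian; standard errors unavailable")
                se = {n: float("nan") for n in spec.free_names}
            else:
                if ill:
                    warnings.warn(
                        "Hessian nearly singular (flat direction, e.g. a path at zero); "
                        "covariance uses a clipped eigendecomposition"
                    )
                diag = np.diag(cov).copy()
                diag[diag < 0] = np.nan
                se = dict(zip(spec.free_names, np.sqrt(diag)))

        self.spec_ = spec
        self.params_ = estimates
        self.se_ = se
        self.cov_ = cov
        self.neg2_loglik_ = float(best.fun)
        self.n_free_ = spec.n_free
        self.converged_ = bool(best.success)
        self.grad_norm_ = grad_norm
        self.result_ = FitResult(
            spec=spec,
            estimates=estimates,
            se=se,
            cov=cov,
            neg2_loglik=float(best.fun),
            n_free=spec.n_free,
            n_obs_stats=prep.n_obs_stats,
            n_pairs=len(table.df),
            group_sizes={str(k): int(v) for k, v in prep.group_sizes.items()},
            converged=bool(best.success),
            grad_norm=grad_norm,
            n_restarts=self.n_restarts,
            seed=self.seed,
            moderator_mean_used=spec.moderator_mean,
        )
        self.aic_ = self.result_.aic
        self.aic_mx_ = self.result_.aic_mx
        return self

    def score(self, X: PairTable | pd.DataFrame, y=None) -> float:
        """Mean log-likelihood per pair (sklearn convention: higher is better)."""
        table = X if isinstance(X, PairTable) else PairTable(X.copy())
        n2ll = neg2_loglik(self.params_, self.spec_, table)
        return -0.5 * n2ll / len(table.df)


def fit_model(
    spec: ModelSpec | str,
    pairs: PairTable,
    starts: Mapping[str, float] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    compute_se: bool = True,
    gtol: float = 1e-5,
) -> FitResult:
    """Functional wrapper over :class:`CholeskyACE`. Returns the FitResult."""
    est = CholeskyACE(
        model=spec, n_restarts=n_restarts, seed=seed,
        compute_se=compute_se, starts=starts, gtol=gtol,
    ).fit(pairs)
    return est.result_


def likelihood_ratio_test(nested: FitResult, full: FitResult) -> LRTResult:
    """Chi-square LRT of a constrained model against the full model."""
    statistic = nested.neg2_loglik - full.neg2_loglik
    df = full.n_free - nested.n_free
    if df <= 0:
        raise ValueError("full model must have more free parameters than the nested model")
    if statistic < -1e-3:
        warnings.warn(
            f"negative LRT statistic ({statistic:.4g}): the full model fit worse; "
            "consider refitting with more restarts"
        )
    p = float(stats.chi2.sf(max(statistic, 0.0), df))
    return LRTResult(float(statistic), int(df), p, nested.spec.name, full.spec.name)


def aic(fit: FitResult) -> dict[str, float]:
    """Both AIC conventions, labeled: standard -2LL + 2k and Mx -2LL - 2(stats - k)."""
    return {"aic": fit.aic, "aic_mx": fit.aic_mx}


def delta_ci(
    fit: FitResult,
    transform: Callable[[Mapping[str, float]], float],
    level: float = 0.95,
) -> tuple[float, float, float, float]:
    """Delta-method confidence interval for a scalar function of the parameters.

    Returns (lower, upper, estimate, se).  Raises if the parameter
    covariance is unavailable (non-invertible Hessian).
    """
    if fit.cov is None:
        raise ValueError("parameter covariance unavailable; interval cannot be computed")
    names = fit.spec.free_names
    theta = np.array([fit.estimates[n] for n in names])
    est = float(transform(dict(zip(names, theta))))
    grad = np.empty(len(theta))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for i in range(len(theta)):
        up, dn = theta.copy(), theta.copy()
        up[i] += h[i]
        dn[i] -= h[i]
        grad[i] = (
            transform(dict(zip(names, up))) - transform(dict(zip(names, dn)))
        ) / (2.0 * h[i])
    var = float(grad @ fit.cov @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return est - z * se, est + z * se, est, se
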