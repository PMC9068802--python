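"""Model-implied moments for moderated bivariate Cholesky ACE twin models.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C), and non-shared environmental (E)
components by contrasting monozygotic pairs (genetic relatedness r = 1)
with dizygotic pairs (r = 0.5).  For a single trait with path
coefficients a, c, e on unit-variance latent factors,

    V       = a^2 + c^2 + e^2
    Cov_MZ  = a^2 + c^2
    Cov_DZ  = 0.5 a^2 + c^2

The bivariate extension orders educational performance (x) before
attainment (y) in a Cholesky structure: the A/C/E influences on y are
split into a part *common* with x (paths a_yx, c_yx, e_yx, loading on the
x factors) and a part *unique* to y (paths a_yy, c_yy, e_yy).  Each
attainment path may additionally be moderated linearly by the twin's own
mean-centered performance X (a definition variable), e.g.
``a_yx -> a_yx + a'_yx * X``.  Performance paths carry no moderation.

All functions here are pure; estimation lives in :mod:`trackace.fiml_engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "PathSet",
    "ModeratedPathSet",
    "MeansModel",
    "VarianceComponents",
    "moderated_path",
    "pair_covariance",
    "mean_vector",
    "variance_components",
    "standardize_components",
]


@dataclass(frozen=True)
class PathSet:
    """Univariate ACE path coefficients (phenotype units per latent unit)."""

    a: float
    c: float
    e: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"path {f.name!r} must be finite, got {v!r}")


@dataclass(frozen=True)
class ModeratedPathSet:
    """Bivariate Cholesky paths with optional moderation of the y paths.

    ``*_xx`` are the performance paths, ``*_yx`` the paths from the
    performance factors to attainment (common part), ``*_yy`` the
    attainment-specific paths (unique part).  The primed slopes
    (``ap_yx`` for a'_yx, etc.) moderate the corresponding base path
    linearly in the centered moderator X and default to zero.
    """

    a_xx: float
    c_xx: float
    e_xx: float
    a_yx: float
    c_yx: float
    e_yx: float
    a_yy: float
    c_yy: float
    e_yy: float
    ap_yx: float = 0.0
    cp_yx: float = 0.0
    ep_yx: float = 0.0
    ap_yy: float = 0.0
    cp_yy: float = 0.0
    ep_yy: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"path {f.name!r} must be finite, got {v!r}")

    def effective(self, x: float) -> dict[str, float]:
        """Moderated attainment paths (and raw x paths) evaluated at X = x."""
        return {
            "a_xx": self.a_xx,
            "c_xx": self.c_xx,
            "e_xx": self.e_xx,
            "a_yx": moderated_path(self.a_yx, self.ap_yx, x),
            "c_yx": moderated_path(self.c_yx, self.cp_yx, x),
            "e_yx": moderated_path(self.e_yx, self.ep_yx, x),
            "a_yy": moderated_path(self.a_yy, self.ap_yy, x),
            "c_yy": moderated_path(self.c_yy, self.cp_yy, x),
            "e_yy": moderated_path(self.e_yy, self.ep_yy, x),
        }

    def scaled(self, k: float) -> "ModeratedPathSet":
        return replace(self, **{f.name: getattr(self, f.name) * k for f in fields(self)})


@dataclass(frozen=True)
class MeansModel:
    """Linear means: intercepts plus fixed effects of sex and birth year.

    ``b_mod_y`` is an optional main effect of the centered moderator on the
    attainment mean (off by default; recorded in every fit that uses it).
    """

    mu_x: float
    mu_y: float
    b_male_x: float = 0.0
    b_male_y: float = 0.0
    b_yob_x: float = 0.0
    b_yob_y: float = 0.0
    b_mod_y: float = 0.0


def moderated_path(base: float, slope: float, x: float) -> float:
    """Effective path coefficient ``base + slope * x`` at moderator value x."""
    return base + slope * x


def _check_r(r: float) -> None:
    if r not in (1.0, 0.5):
        raise ValueError(f"relatedness r must be 1.0 (MZ) or 0.5 (DZ), got {r!r}")


def pair_covariance(
    paths_twin1: ModeratedPathSet,
    paths_twin2: ModeratedPathSet,
    r: float,
    x1: float = 0.0,
    x2: float = 0.0,
) -> np.ndarray:
    """Model-implied 4x4 covariance of (x1, y1, x2, y2) for one twin pair.

    The A factors correlate r across twins, the C factors are shared, and
    the E factors are twin-specific.  Each twin's attainment paths are the
    moderated values at that twin's own centered moderator, and in pairs
    discordant for tracking status the two twins' own path sets enter the
    cross products (the standard definition-variable treatment).
    """
    _check_r(r)
    p1 = paths_twin1.effective(x1)
    p2 = paths_twin2.effective(x2)

    sigma = np.empty((4, 4))
    for i, (pi, pj) in enumerate([(p1, p1), (p2, p2)]):
        o = 2 * i
        sigma[o, o] = pi["a_xx"] ** 2 + pi["c_xx"] ** 2 + pi["e_xx"] ** 2
        sigma[o + 1, o + 1] = (
            pi["a_yx"] ** 2 + pi["c_yx"] ** 2 + pi["e_yx"] ** 2
            + pi["a_yy"] ** 2 + pi["c_yy"] ** 2 + pi["e_yy"] ** 2
        )
        sigma[o, o + 1] = sigma[o + 1, o] = (
            pi["a_xx"] * pi["a_yx"] + pi["c_xx"] * pi["c_yx"] + pi["e_xx"] * pi["e_yx"]
        )
    # cross-twin blocks: no E terms
    cxx = r * p1["a_xx"] * p2["a_xx"] + p1["c_xx"] * p2["c_xx"]
    cx1y2 = r * p1["a_xx"] * p2["a_yx"] + p1["c_xx"] * p2["c_yx"]
    cx2y1 = r * p2["a_xx"] * p1["a_yx"] + p2["c_xx"] * p1["c_yx"]
    cyy = (
        r * (p1["a_yx"] * p2["a_yx"] + p1["a_yy"] * p2["a_yy"])
        + p1["c_yx"] * p2["c_yx"] + p1["c_yy"] * p2["c_yy"]
    )
    sigma[0, 2] = sigma[2, 0] = cxx
    sigma[0, 3] = sigma[3, 0] = cx1y2
    sigma[1, 2] = sigma[2, 1] = cx2y1
    sigma[1, 3] = sigma[3, 1] = cyy
    return sigma


def mean_vector(
    means_twin1: MeansModel,
    means_twin2: MeansModel,
    male1: float = 0.0,
    male2: float = 0.0,
    yob_c1: float = 0.0,
    yob_c2: float = 0.0,
    x1: float = 0.0,
    x2: float = 0.0,
) -> np.ndarray:
    """Model-implied mean of (x1, y1, x2, y2) given each twin's covariates."""
    out = np.empty(4)
    for i, (m, male, yob, x) in enumerate(
        [(means_twin1, male1, yob_c1, x1), (means_twin2, male2, yob_c2, x2)]
    ):
        out[2 * i] = m.mu_x + m.b_male_x * male + m.b_yob_x * yob
        out[2 * i + 1] = m.mu_y + m.b_male_y * male + m.b_yob_y * yob + m.b_mod_y * x
    return out


@dataclass(frozen=True)
class VarianceComponents:
    """Raw A/C/E variances (squares of effective paths) at a moderator value.

    Attainment components are split into the part common with performance
    (``va_common`` etc.) and the part unique to attainment; ``va_y`` is
    their sum ("Common + Unique").  Performance components come from the
    x paths, which are never moderated.
    """

    x: float
    va_x: float
    vc_x: float
    ve_x: float
    va_common: float
    vc_common: float
    ve_common: float
    va_unique: float
    vc_unique: float
    ve_unique: float

    @property
    def vt_x(self) -> float:
        return self.va_x + self.vc_x + self.ve_x

    @property
    def va_y(self) -> float:
        return self.va_common + self.va_unique

    @property
    def vc_y(self) -> float:
        return self.vc_common + self.vc_unique

    @property
    def ve_y(self) -> float:
        return self.ve_common + self.ve_unique

    @property
    def vt_y(self) -> float:
        return self.va_y + self.vc_y + self.ve_y

    @property
    def vt_common(self) -> float:
        return self.va_common + self.vc_common + self.ve_common

    @property
    def vt_unique(self) -> float:
        return self.va_unique + self.vc_unique + self.ve_unique


def variance_components(paths: ModeratedPathSet, x: float = 0.0) -> VarianceComponents:
    """Raw variance components: squares of the (moderated) path coefficients."""
    p = paths.effective(x)
    return VarianceComponents(
        x=x,
        va_x=p["a_xx"] ** 2,
        vc_x=p["c_xx"] ** 2,
        ve_x=p["e_xx"] ** 2,
        va_common=p["a_yx"] ** 2,
        vc_common=p["c_yx"] ** 2,
        ve_common=p["e_yx"] ** 2,
        va_unique=p["a_yy"] ** 2,
        vc_unique=p["c_yy"] ** 2,
        ve_unique=p["e_yy"] ** 2,
    )


def standardize_components(vc: VarianceComponents) -> dict[str, float]:
    """Standardized variance proportions.

    Returns attainment and performance A/C/E shares of the respective
    totals, plus the within-common and within-unique shares of the
    attainment decomposition (each block sums to 1 where its total is
    positive).
    """
    if vc.vt_y <= 0 or vc.vt_x <= 0:
        raise ValueError("total variance must be positive to standardize")
    out = {
        "a_y": vc.va_y / vc.vt_y,
        "c_y": vc.vc_y / vc.vt_y,
        "e_y": vc.ve_y / vc.vt_y,
        "a_x": vc.va_x / vc.vt_x,
        "c_x": vc.vc_x / vc.vt_x,
        "e_x": vc.ve_x / vc.vt_x,
    }
    if vc.vt_common > 0:
        out["a_common"] = vc.va_common / vc.vt_common
        out["c_common"] = vc.vc_common / vc.vt_common
        out["e_common"] = vc.ve_common / vc.vt_common
    if vc.vt_unique > 0:
        out["a_unique"] = vc.va_unique / vc.vt_unique
        out["c_unique"] = vc.vc_unique / vc.vt_unique
        out["e_unique"] = vc.ve_unique / vc.vt_unique
    return out
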