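"""Synthetic twin-pair tables drawn from the moderated Cholesky ACE model.

The generator is the exact generative counterpart of the model that
:mod:`trackace.fiml_engine` fits: unit-variance latent A factors correlate
r across twins (1 for MZ, 0.5 for DZ, via the shared-factor construction
sqrt(r)*A_common + sqrt(1-r)*A_unique), C factors are fully shared within
a pair, E factors are twin-specific, and each twin's attainment is built
from path coefficients moderated by that twin's own realized centered
performance (the definition-variable convention).

Tracking status is drawn per twin from explicit pattern probabilities, so
pair concordance (including the discordant and status-missing groups)
emerges from the configuration.  A separate logistic assignment op exists
for emulating performance-dependent selection into delayed tracking.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ace_structure import MeansModel, ModeratedPathSet
from .pair_data import DELAYED, DZ, IMMEDIATE, MISSING, MZ, PairTable, RELATEDNESS

__all__ = [
    "GenerativeConfig",
    "simulate_pairs",
    "assign_tracking_by_performance",
    "impose_missingness",
    "expected_status_weights",
    "analysis_truth",
]

#: statuses a twin can carry during generation
GEN_STATUSES = (IMMEDIATE, DELAYED, MISSING)


@dataclass
class GenerativeConfig:
    """Generating parameters for a synthetic twin sample.

    ``paths`` and ``means`` map tracking status to the status-specific
    path set and means model.  Status patterns are drawn per pair: with
    probability ``p_status_missing`` both twins carry the missing status
    (their own parameter set, mirroring the separate model group); the
    rest are discordant with the zygosity-specific probability and
    otherwise concordant such that the marginal delayed share equals
    ``p_delayed``.
    """

    paths: dict[str, ModeratedPathSet]
    means: dict[str, MeansModel]
    n_mz: int
    n_dz: int
    p_delayed: float = 0.26
    p_status_missing: float = 0.0
    p_discordant_mz: float = 0.04
    p_discordant_dz: float = 0.13
    missing_rates: dict[str, float] = field(default_factory=dict)
    performance_offset: float = 538.0
    birth_year_range: tuple[int, int] = (1986, 1999)
    p_male: float = 0.46
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")
        for p in (self.p_delayed, self.p_status_missing, self.p_discordant_mz,
                  self.p_discordant_dz, self.p_male, *self.missing_rates.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p!r} outside [0, 1]")
        for status, ps in self.paths.items():
            if status not in GEN_STATUSES:
                raise ValueError(f"unknown status {status!r}")
            if not all(np.isfinite(dataclasses.astuple(ps))):
                raise ValueError(f"non-finite paths for status {status!r}")
        for zyg, p_disc in ((MZ, self.p_discordant_mz), (DZ, self.p_discordant_dz)):
            q_dd = self.p_delayed - p_disc / 2.0
            if q_dd < 0 or q_dd + p_disc > 1:
                raise ValueError(
                    f"inconsistent status probabilities for {zyg}: "
                    f"p_delayed={self.p_delayed}, p_discordant={p_disc}"
                )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["paths"] = {s: dataclasses.asdict(p) for s, p in self.paths.items()}
        d["means"] = {s: dataclasses.asdict(m) for s, m in self.means.items()}
        d["birth_year_range"] = list(self.birth_year_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeConfig":
        d = dict(d)
        d["paths"] = {s: ModeratedPathSet(**p) for s, p in d["paths"].items()}
        d["means"] = {s: MeansModel(**m) for s, m in d["means"].items()}
        if "birth_year_range" in d:
            d["birth_year_range"] = tuple(d["birth_year_range"])
        if "missing_rates" in d and d["missing_rates"] is None:
            d["missing_rates"] = {}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerativeConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- reference configuration -------------------------------------------

    @classmethod
    def default(cls, n_mz: int = 1650, n_dz: int = 1350, seed: int = 0) -> "GenerativeConfig":
        """Study-condition defaults for the demo and recovery runs.

        Path and mean values mirror the fitted immediate/delayed contrast
        of the tracking-split model (large shared-environment influence
        under immediate tracking, nearly none under delayed tracking; a
        smaller performance variance in the delayed group), with the
        status-missing group at the pooled values.  Counts default to
        3000 pairs, 55% MZ.
        """
        immediate = ModeratedPathSet(
            a_xx=7.11, c_xx=3.64, e_xx=3.81,
            a_yx=0.66, c_yx=0.57, e_yx=0.22,
            a_yy=0.53, c_yy=-0.16, e_yy=0.44,
        )
        delayed = ModeratedPathSet(
            a_xx=5.40, c_xx=0.98, e_xx=3.25,
            a_yx=0.53, c_yx=0.04, e_yx=0.19,
            a_yy=0.64, c_yy=-0.13, e_yy=0.43,
        )
        pooled = ModeratedPathSet(
            a_xx=7.08, c_xx=2.74, e_xx=3.69,
            a_yx=0.65, c_yx=0.53, e_yx=0.20,
            a_yy=0.56, c_yy=0.00, e_yy=0.45,
        )
        covs = dict(b_male_x=0.6, b_male_y=0.06, b_yob_x=0.05, b_yob_y=0.005)
        return cls(
            paths={IMMEDIATE: immediate, DELAYED: delayed, MISSING: pooled},
            means={
                IMMEDIATE: MeansModel(mu_x=-1.33, mu_y=2.61, **covs),
                DELAYED: MeansModel(mu_x=1.79, mu_y=2.94, **covs),
                MISSING: MeansModel(mu_x=-0.70, mu_y=2.67, **covs),
            },
            n_mz=n_mz,
            n_dz=n_dz,
            p_delayed=0.26,
            p_status_missing=0.33,
            p_discordant_mz=0.04,
            p_discordant_dz=0.13,
            missing_rates={"attainment": 0.35, "performance": 0.0},
            seed=seed,
        )


def expected_status_weights(cfg: GenerativeConfig) -> dict[str, float]:
    """Expected per-twin status shares implied by the pattern model."""
    w_missing = cfg.p_status_missing
    w_delayed = (1.0 - w_missing) * cfg.p_delayed
    return {
        MISSING: w_missing,
        DELAYED: w_delayed,
        IMMEDIATE: 1.0 - w_missing - w_delayed,
    }


def analysis_truth(cfg: GenerativeConfig, statuses: tuple[str, ...] | None = None) -> dict[str, float]:
    """Generating parameter values on the scale the analysis estimates them.

    Parameter names follow the per-status model convention
    (``role@status`` plus the shared covariate slopes).  Performance
    intercepts are shifted by the expected overall performance mean,
    because the analysis centers performance on the loaded sample while
    the generator specifies status-specific means directly.
    """
    statuses = statuses or tuple(cfg.paths)
    w = expected_status_weights(cfg)
    # expected overall mean of the centered-performance variable's parent
    shift = sum(w[s] * cfg.means[s].mu_x for s in statuses if s in w)
    shift += cfg.means[statuses[0]].b_male_x * cfg.p_male  # yob is centered, mean 0
    truth: dict[str, float] = {}
    m0 = cfg.means[statuses[0]]
    truth["b_male_x"] = m0.b_male_x
    truth["b_male_y"] = m0.b_male_y
    truth["b_yob_x"] = m0.b_yob_x
    truth["b_yob_y"] = m0.b_yob_y
    for s in statuses:
        ps, ms = cfg.paths[s], cfg.means[s]
        truth[f"mu_x@{s}"] = ms.mu_x - shift
        truth[f"mu_y@{s}"] = ms.mu_y
        for f in dataclasses.fields(ps):
            truth[f"{f.name}@{s}"] = getattr(ps, f.name)
    return truth


def _draw_status_patterns(
    rng: np.random.Generator, zygosity: np.ndarray, cfg: GenerativeConfig
) -> np.ndarray:
    """(n, 2) array of per-twin statuses drawn from the pattern model."""
    n = len(zygosity)
    out = np.empty((n, 2), dtype=object)
    u_missing = rng.random(n)
    u_pattern = rng.random(n)
    u_order = rng.random(n)
    for zyg, p_disc in ((MZ, cfg.p_discordant_mz), (DZ, cfg.p_discordant_dz)):
        mask = zygosity == zyg
        q_dd = cfg.p_delayed - p_disc / 2.0
        miss = mask & (u_missing < cfg.p_status_missing)
        rest = mask & ~miss
        disc = rest & (u_pattern < p_disc)
        dd = rest & ~disc & (u_pattern < p_disc + q_dd)
        ii = rest & ~disc & ~dd
        out[miss] = [MISSING, MISSING]
        out[dd] = [DELAYED, DELAYED]
        out[ii] = [IMMEDIATE, IMMEDIATE]
        first_delayed = disc & (u_order < 0.5)
        out[first_delayed] = [DELAYED, IMMEDIATE]
        out[disc & ~first_delayed] = [IMMEDIATE, DELAYED]
    return out


def _status_values(attr: str, source: dict, statuses: np.ndarray) -> np.ndarray:
    """Per-twin (n, 2) array of a path/mean attribute looked up by status."""
    lut = {s: getattr(v, attr) for s, v in source.items()}
    return np.vectorize(lut.__getitem__, otypes=[float])(statuses)


def simulate_pairs(config: GenerativeConfig) -> PairTable:
    """Simulate a pair table; reproducible given ``config.seed``.

    Sample moments of each zygosity x status cell converge to the
    model-implied moments of :func:`trackace.ace_structure.pair_covariance`
    evaluated at the generating parameters.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_mz + config.n_dz
    if n == 0:
        raise ValueError("no pairs requested")
    zygosity = np.array([MZ] * config.n_mz + [DZ] * config.n_dz, dtype=object)
    r = np.array([RELATEDNESS[z] for z in zygosity])[:, None]

    statuses = _draw_status_patterns(rng, zygosity, config)
    used = set(np.unique(statuses))
    for s in used:
        if s not in config.paths or s not in config.means:
            raise ValueError(f"config lacks paths/means for generated status {s!r}")

    # covariates: MZ twins share sex, DZ sexes are independent
    male = (rng.random((n, 2)) < config.p_male).astype(float)
    male[zygosity == MZ, 1] = male[zygosity == MZ, 0]
    lo, hi = config.birth_year_range
    birth_year = rng.integers(lo, hi + 1, size=n).astype(float)
    birth_year = np.repeat(birth_year[:, None], 2, axis=1)  # twins share a birth year
    yob_c = birth_year - (lo + hi) / 2.0

    def correlated_pair_factor() -> np.ndarray:
        shared = rng.standard_normal((n, 1))
        unique = rng.standard_normal((n, 2))
        return np.sqrt(r) * shared + np.sqrt(1.0 - r) * unique

    a_x = correlated_pair_factor()
    a_y = correlated_pair_factor()
    c_x = np.repeat(rng.standard_normal((n, 1)), 2, axis=1)
    c_y = np.repeat(rng.standard_normal((n, 1)), 2, axis=1)
    e_x = rng.standard_normal((n, 2))
    e_y = rng.standard_normal((n, 2))

    path = lambda name: _status_values(name, config.paths, statuses)
    mean = lambda name: _status_values(name, config.means, statuses)

    x = (
        mean("mu_x")
        + mean("b_male_x") * male
        + mean("b_yob_x") * yob_c
        + path("a_xx") * a_x
        + path("c_xx") * c_x
        + path("e_xx") * e_x
    )
    performance = config.performance_offset + x
    x_centered = performance - performance.mean()

    eff = lambda base, slope: path(base) + path(slope) * x_centered
    y = (
        mean("mu_y")
        + mean("b_male_y") * male
        + mean("b_yob_y") * yob_c
        + mean("b_mod_y") * x_centered
        + eff("a_yx", "ap_yx") * a_x
        + eff("c_yx", "cp_yx") * c_x
        + eff("e_yx", "ep_yx") * e_x
        + eff("a_yy", "ap_yy") * a_y
        + eff("c_yy", "cp_yy") * c_y
        + eff("e_yy", "ep_yy") * e_y
    )

    df = pd.DataFrame({"pair_id": [f"p{idx:06d}" for idx in range(n)], "zygosity": zygosity})
    for i in (1, 2):
        df[f"attainment_{i}"] = y[:, i - 1]
        df[f"performance_{i}"] = performance[:, i - 1]
        df[f"tracking_{i}"] = statuses[:, i - 1]
        df[f"male_{i}"] = male[:, i - 1]
        df[f"birth_year_{i}"] = birth_year[:, i - 1]
    table = PairTable(df[[c for c in df.columns]])

    if any(rate > 0 for rate in config.missing_rates.values()):
        table = impose_missingness(table, config.missing_rates, seed=config.seed + 1)
    return table


def assign_tracking_by_performance(
    table: PairTable, intercept: float, slope: float, seed: int = 0
) -> PairTable:
    """Fill tracking by a logistic selection model on centered performance.

    P(delayed | X) = expit(intercept + slope * X) applied per twin
    independently; slope = 0 reproduces assignment independent of
    performance.  Twins with missing performance keep a missing status.
    """
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    df = table.df.copy()
    for i in (1, 2):
        x = df[f"performance_centered_{i}"].to_numpy()
        p = expit(intercept + slope * x)
        delayed = rng.random(len(df)) < p
        status = np.where(delayed, DELAYED, IMMEDIATE).astype(object)
        status[np.isnan(x)] = MISSING
        df[f"tracking_{i}"] = status
    return PairTable(df, performance_mean=table.performance_mean,
                     birth_year_mean=table.birth_year_mean)


def impose_missingness(
    table: PairTable, rates: dict[str, float], seed: int = 0
) -> PairTable:
    """Blank fields independently at the given per-field rates.

    Supported fields: ``attainment``, ``performance``, ``tracking``.
    Blanking performance removes the twin's moderator, which flags that
    twin for record-level exclusion downstream while the co-twin is
    retained.  Centering constants are recomputed from the remaining
    non-missing values.
    """
    for fieldname, rate in rates.items():
        if fieldname not in ("attainment", "performance", "tracking"):
            raise ValueError(f"unknown field {fieldname!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {fieldname!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    for fieldname, rate in rates.items():
        if rate == 0:
            continue
        for i in (1, 2):
            blank = rng.random(len(df)) < rate
            col = f"{fieldname}_{i}"
            if fieldname == "tracking":
                df.loc[blank, col] = MISSING
            else:
                df.loc[blank, col] = np.nan
    return PairTable(df)
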