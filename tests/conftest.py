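import numpy as np
import pytest

from trackace import GenerativeConfig, MeansModel, ModeratedPathSet, simulate_pairs


def univariate_config(
    a2: float = 0.5,
    c2: float = 0.3,
    e2: float = 0.2,
    n_mz: int = 2000,
    n_dz: int = 2000,
    seed: int = 0,
    var: float = 1.0,
) -> GenerativeConfig:
    """Single-status generator whose x phenotype is a plain ACE trait."""
    s = np.sqrt(np.array([a2, c2, e2]) * var)
    paths = ModeratedPathSet(
        a_xx=s[0], c_xx=s[1], e_xx=s[2],
        a_yx=0.0, c_yx=0.0, e_yx=0.0, a_yy=0.0, c_yy=0.0, e_yy=1.0,
    )
    return GenerativeConfig(
        paths={"immediate": paths},
        means={"immediate": MeansModel(mu_x=0.0, mu_y=0.0)},
        n_mz=n_mz, n_dz=n_dz,
        p_delayed=0.0, p_discordant_mz=0.0, p_discordant_dz=0.0,
        p_status_missing=0.0, performance_offset=0.0, seed=seed,
    )


def two_status_config(n_mz: int, n_dz: int, seed: int) -> GenerativeConfig:
    """Immediate/delayed generator with shared parameters (Model-1a truth)."""
    pooled = ModeratedPathSet(
        a_xx=7.08, c_xx=2.74, e_xx=3.69,
        a_yx=0.65, c_yx=0.53, e_yx=0.20,
        a_yy=0.56, c_yy=0.0, e_yy=0.45,
    )
    means = MeansModel(mu_x=0.0, mu_y=2.67, b_male_x=0.6, b_male_y=0.06,
                       b_yob_x=0.05, b_yob_y=0.005)
    return GenerativeConfig(
        paths={"immediate": pooled, "delayed": pooled},
        means={"immediate": means, "delayed": means},
        n_mz=n_mz, n_dz=n_dz,
        p_delayed=0.26, p_discordant_mz=0.04, p_discordant_dz=0.13,
        p_status_missing=0.0, seed=seed,
    )


@pytest.fixture(scope="session")
def study_table():
    """A moderately sized sample under the full study-condition generator."""
    return simulate_pairs(GenerativeConfig.default(n_mz=450, n_dz=350, seed=42))


@pytest.fixture(scope="session")
def complete_table():
    """Complete-data two-status sample (no missingness of any kind)."""
    return simulate_pairs(two_status_config(n_mz=180, n_dz=150, seed=11))


TINY_CSV = """pair_id,zygosity,attainment_1,performance_1,tracking_1,male_1,birth_year_1,attainment_2,performance_2,tracking_2,male_2,birth_year_2
p1,MZ,3.0,541.0,immediate,1,1992,3.5,543.0,immediate,1,1992
p2,DZ,1.5,528.0,delayed,0,1995,2.0,,,1,1995
p3,DZ,4.0,549.5,immediate,0,1988,,532.0,delayed,0,1988
"""


@pytest.fixture()
def tiny_csv(tmp_path):
    path = tmp_path / "pairs.csv"
    path.write_text(TINY_CSV)
    return path
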