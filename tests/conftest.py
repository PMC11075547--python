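import numpy as np
import pandas as pd
import pytest

from fruitgwas.contours import PolarContour, FruitImageKey

DEG = np.arange(360)
RAD = np.deg2rad(DEG)


def circle(r=100.0, view="Side1"):
    return PolarContour(np.full(360, float(r)), view=view)


def ellipse(a=120.0, b=80.0, view="Side1"):
    """Axis-aligned ellipse with semi-axis a along x and b along y."""
    r = a * b / np.sqrt((b * np.cos(RAD)) ** 2 + (a * np.sin(RAD)) ** 2)
    return PolarContour(r, view=view)


@pytest.fixture
def circle100():
    return circle(100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240305)


def random_contour(rng, base=100.0, n_harmonics=4, amp=0.05, view="Side1"):
    r = np.full(360, base)
    for k in range(1, n_harmonics + 1):
        r *= 1.0 + amp * rng.normal() * np.cos(k * RAD + rng.uniform(0, 2 * np.pi))
    return PolarContour(np.abs(r) + 1.0, view=view)


def mirror_symmetric_contour(rng, axis="vertical", base=100.0):
    """Random contour symmetric about the vertical (left-right) or
    horizontal (top-bottom) axis."""
    r = np.full(360, base)
    for k in range(1, 5):
        a = 0.05 * rng.normal()
        if axis == "vertical":
            r *= 1.0 + a * np.sin(k * RAD)   # sin(k d) symmetric under d -> 180-d for odd k
        else:
            r *= 1.0 + a * np.cos(k * RAD)   # cos symmetric under d -> -d
    if axis == "vertical":
        # enforce exactly: average with the mirrored contour
        m = r[(180 - DEG) % 360]
    else:
        m = r[(360 - DEG) % 360]
    return PolarContour((r + m) / 2.0, view="Side1")


def tree_records(rng, n_geno=50, years=(2019, 2020), reps=("1", "2"),
                 sg2=2.0, se2=1.0, year_effects=None, rep_effect=0.3,
                 n_features=1):
    """Balanced tree-level records from the genotype + year + rep model."""
    year_effects = year_effects or {y: 0.5 * i for i, y in enumerate(years)}
    genos = [f"G{i:03d}" for i in range(n_geno)]
    idx = pd.MultiIndex.from_product([genos, list(years), list(reps)],
                                     names=["genotype_id", "year", "tree_id"])
    g = rng.normal(0, np.sqrt(sg2), (n_geno, n_features))
    g_rows = np.repeat(g, len(years) * len(reps), axis=0)
    ye = np.array([year_effects[y] for y in idx.get_level_values("year")])[:, None]
    re = np.array([rep_effect * (r == "2") for r in idx.get_level_values("tree_id")])[:, None]
    Y = g_rows + ye + re + rng.normal(0, np.sqrt(se2), (len(idx), n_features))
    df = pd.DataFrame(Y, index=idx,
                      columns=[f"feat{j}" for j in range(n_features)])
    return df, pd.Series(g[:, 0], index=genos)


@pytest.fixture(scope="session")
def small_simdata():
    """Session-scoped small synthetic trial used by several suites."""
    from fruitgwas.synthetic_data import SimConfig, simulate_dataset

    cfg = SimConfig(seed=11, n_genotypes=40, markers_per_chromosome=10,
                    fruits_per_tree=3)
    return simulate_dataset(cfg)
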