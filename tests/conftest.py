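import numpy as np
import pandas as pd
import pytest

from tspforage.geometry import ArenaConfig, Strategy, bundled_configurations, distance_matrix
from tspforage.measures import EventKind, TrialLog
from tspforage.routes import optimal_route


@pytest.fixture(scope="session")
def configs():
    return bundled_configurations()


@pytest.fixture(scope="session")
def configs_by_id(configs):
    return {c.config_id: c for c in configs}


@pytest.fixture(scope="session")
def opts_by_id(configs):
    return {
        c.config_id: optimal_route(distance_matrix(c)) for c in configs
    }


@pytest.fixture
def unit_square():
    return ArenaConfig(
        1,
        ((0, 0.0, 0.0), (1, 1.0, 0.0), (2, 1.0, 1.0), (3, 0.0, 1.0)),
        Strategy.BASELINE,
    )


@pytest.fixture
def collinear4():
    """Four collinear targets at x = 0, 1, 2, 3 cm."""
    return ArenaConfig(
        3,
        ((0, 0.0, 0.0), (1, 1.0, 0.0), (2, 2.0, 0.0), (3, 3.0, 0.0)),
        Strategy.L_P,
    )


@pytest.fixture
def worked_trial(collinear4):
    """Hand-traced trial: contacts A,B,C,B,D, retrieval at first contact of
    each target; the second B contact is a revisit."""
    C, R = EventKind.CONTACT, EventKind.RETRIEVAL
    events = (
        (0.0, 0, C), (0.0, 0, R),
        (1.0, 1, C), (1.0, 1, R),
        (2.0, 2, C), (2.0, 2, R),
        (3.0, 1, C),
        (4.0, 3, C), (4.0, 3, R),
    )
    return TrialLog("r1", "SHR", "F", 3, events)


def random_config(rng: np.random.Generator, n: int, config_id: int = 99) -> ArenaConfig:
    """Uniform random targets inside the arena (min separation enforced)."""
    while True:
        r = 45.0 * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.c_[r * np.cos(th), r * np.sin(th)]
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        if d[~np.eye(n, dtype=bool)].min() > 1.0:
            return ArenaConfig(
                config_id,
                tuple((i, float(x), float(y)) for i, (x, y) in enumerate(pts)),
                Strategy.GLOBAL,
            )


@pytest.fixture(scope="session")
def anova_fixture():
    """Balanced 2x2x3 split-plot dataset with known-seed effects; the
    expected F table was computed independently with R's aov
    (Error(rat/strategy) stratification)."""
    rng = np.random.default_rng(12345)
    rows = []
    i = 0
    for strain in ("SHR", "WKY"):
        for sex in ("F", "M"):
            for _ in range(4):
                i += 1
                rid = f"r{i:02d}"
                subj = rng.normal(0, 0.5)
                for k, strat in enumerate(("GLOBAL", "L_NN", "L_P")):
                    y = (
                        1.0
                        + (0.4 if strain == "SHR" else 0)
                        + (0.2 if sex == "M" else 0)
                        + 0.3 * k + subj + rng.normal(0, 0.3)
                    )
                    rows.append((rid, strain, sex, strat, round(y, 6)))
    return pd.DataFrame(
        rows, columns=["rat_id", "strain", "sex", "strategy", "value"]
    )
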