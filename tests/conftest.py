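import numpy as np
import pandas as pd
import pytest

import traitpart as tp


@pytest.fixture(scope="session")
def sim_default():
    """One full synthetic experiment (27 plots, mixed effects, seed 1)."""
    return tp.generate(tp.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def species_filter():
    return tp.CommonSpeciesFilter(0.90)


@pytest.fixture(scope="session")
def cwms_default(sim_default, species_filter):
    design, ab, traits, _ = sim_default
    return tp.cwm_table(design, ab, traits, species_filter=species_filter)


# ---------------------------------------------------------------------------
# independent oracles used across test modules


def naive_balanced_type1_ss(df: pd.DataFrame, value: str = "value") -> dict:
    """Sequential SS for a balanced two-way layout from raw group means."""
    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    ss = {}
    ss["climate"] = sum(
        len(g) * (g[value].mean() - grand) ** 2
        for _, g in df.groupby("climate", observed=True)
    )
    ss["treatment"] = sum(
        len(g) * (g[value].mean() - grand) ** 2
        for _, g in df.groupby("treatment", observed=True)
    )
    cell_means = df.groupby(["climate", "treatment"], observed=True)[value].transform("mean")
    clim_means = df.groupby("climate", observed=True)[value].transform("mean")
    treat_means = df.groupby("treatment", observed=True)[value].transform("mean")
    ss["climate:treatment"] = float(
        ((cell_means - clim_means - treat_means + grand) ** 2).sum()
    )
    ss["residuals"] = float(((df[value] - cell_means) ** 2).sum())
    ss["total"] = float(((y - grand) ** 2).sum())
    return ss


def convex_hull_area_oracle(points: np.ndarray) -> float:
    """2-D hull area via Jarvis march + shoelace (independent of Qhull)."""
    pts = np.unique(points, axis=0)
    n = len(pts)
    start = min(range(n), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % n
        for j in range(n):
            if j == cur:
                continue
            u = pts[cand] - pts[cur]
            v = pts[j] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[j] - pts[cur]) >
                             np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
        if len(hull) > n:  # degenerate safety
            break
    v = pts[hull]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def feve_oracle(coords: np.ndarray, weights: np.ndarray) -> float:
    """FEve via networkx MST, independently of the scipy csgraph route."""
    import itertools

    import networkx as nx

    S = len(weights)
    G = nx.Graph()
    for i, j in itertools.combinations(range(S), 2):
        G.add_edge(i, j, weight=float(np.linalg.norm(coords[i] - coords[j])))
    tree = nx.minimum_spanning_tree(G)
    ew = np.array(
        [d["weight"] / (weights[i] + weights[j]) for i, j, d in tree.edges(data=True)]
    )
    pew = ew / ew.sum()
    thresh = 1.0 / (S - 1)
    return (np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh)


def fdiv_oracle(coords: np.ndarray, weights: np.ndarray, vertices: list[int]) -> float:
    G = coords[vertices].mean(axis=0)
    dG = np.array([np.linalg.norm(x - G) for x in coords])
    dbar = dG.mean()
    delta_d = sum(w * (d - dbar) for w, d in zip(weights, dG))
    delta_abs = sum(w * abs(d - dbar) for w, d in zip(weights, dG))
    return (delta_d + dbar) / (delta_abs + dbar)


def fdis_oracle(coords: np.ndarray, weights: np.ndarray) -> float:
    c = sum(w * x for w, x in zip(weights, coords))
    return sum(w * np.linalg.norm(x - c) for w, x in zip(weights, coords))
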