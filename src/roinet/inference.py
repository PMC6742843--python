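"""Two-sample group inference with Benjamini-Hochberg FDR.

Edge-wise: for every tested ROI-ROI connection, a pooled-variance two-sample
t-test (the GLM [1 -1] group contrast) compares the subjects' Fisher-z
values between groups; p-values are BH-adjusted across the tested set and a
connection is retained iff its adjusted p ("p-FDR") is below q (default
0.05). The sign convention is group1 - group2, i.e. patients minus controls
when called with the default group order.

Node-wise: the same machinery applied per node to any of the seven topology
metrics, BH-adjusted across nodes within the metric. Undefined values
(e.g. average path length of an isolated node) are dropped per row with a
logged count; a row with fewer than two defined values in a group is
excluded as undefined.

Which connections are tested is set by :class:`SeedRestriction` — by
default every pair with at least one endpoint in the seed set, each
unordered pair once for symmetric (FUN) matrices and both directions for
asymmetric (EFF) matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConnectivityMatrix

logger = logging.getLogger(__name__)


@dataclass
class SeedRestriction:
    """Restrict edge-wise testing to seed-to-other connections.

    seeds : ROI labels whose connectivity is under investigation.
    targets : labels a seed may connect to; defaults to every other ROI
        (including the other seeds — a seed-seed pair is tested once).
    fdr_scope : "all_tested_pairs" corrects across the whole tested set
        jointly (default); "per_seed" corrects within each seed's rows.
    """

    seeds: list[str]
    targets: list[str] | None = None
    fdr_scope: str = "all_tested_pairs"

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seed set is empty")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seed labels must be unique")
        if self.fdr_scope not in ("all_tested_pairs", "per_seed"):
            raise ValueError("fdr_scope must be all_tested_pairs or per_seed")

    def tested_pairs(self, roi_labels: list[str], kind: str) -> list[tuple[str, str]]:
        """The (seed, target) connections to test.

        FUN: unordered pairs with >=1 seed endpoint, each once (seed listed
        first; a seed-seed pair appears once, lower atlas index first).
        EFF: ordered pairs — both directions of every such pair.
        """
        labset = set(roi_labels)
        missing = set(self.seeds) - labset
        if missing:
            raise ValueError(f"seed labels not in matrix: {sorted(missing)}")
        targets = self.targets if self.targets is not None else roi_labels
        missing = set(targets) - labset
        if missing:
            raise ValueError(f"target labels not in matrix: {sorted(missing)}")
        seedset = set(self.seeds)
        order = {lab: i for i, lab in enumerate(roi_labels)}
        pairs: list[tuple[str, str]] = []
        seen: set[frozenset[str]] = set()
        for s in self.seeds:
            for t in targets:
                if t == s:
                    continue
                key = frozenset((s, t))
                if key in seen:
                    continue
                seen.add(key)
                if t in seedset and order[t] < order[s]:
                    pairs.append((t, s))  # canonical order for seed-seed pairs
                else:
                    pairs.append((s, t))
        if kind == "EFF":
            pairs = [p for pair in pairs for p in (pair, pair[::-1])]
        return pairs


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Vectorised pooled-variance two-sample t over the last-axis columns.

    x : n1 x m, y : n2 x m. Degenerate zero-variance columns follow the
    stated convention: equal means -> t=0, p=1; unequal means -> t=+-inf,
    p=0 (logged).
    """
    n1, n2 = x.shape[0], y.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    mx, my = x.mean(axis=0), y.mean(axis=0)
    sp2 = ((n1 - 1) * x.var(axis=0, ddof=1) + (n2 - 1) * y.var(axis=0, ddof=1)) / df
    diff = mx - my
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = se == 0
    if np.any(degenerate):
        eq = degenerate & (diff == 0)
        ne = degenerate & (diff != 0)
        t[eq] = 0.0
        t[ne] = np.where(diff[ne] > 0, np.inf, -np.inf)
        if np.any(ne):
            logger.warning(
                "%d comparisons have zero pooled variance with unequal "
                "means; reporting infinite t / p -> 0",
                int(ne.sum()),
            )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isinf(t)] = 0.0
    return t, df, p


def two_sample_t(x, y) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test (the [1 -1] contrast), two-sided.

    Sign convention: t > 0 means mean(x) > mean(y). Non-finite values are
    dropped before testing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    t, df, p = _pooled_t(x[:, None], y[:, None])
    return float(t[0]), int(df), float(p[0])


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def _split_groups(
    groups: list[str], group1: str, group2: str
) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(groups)
    i1 = np.flatnonzero(g == group1)
    i2 = np.flatnonzero(g == group2)
    if len(i1) < 2 or len(i2) < 2:
        raise ValueError(
            f"need >=2 subjects per group, got {len(i1)} {group1!r} and "
            f"{len(i2)} {group2!r}"
        )
    return i1, i2


def edgewise_group_comparison(
    matrices: list[ConnectivityMatrix],
    groups: list[str],
    restriction: SeedRestriction,
    q: float = 0.05,
    group1: str = "patient",
    group2: str = "control",
) -> pd.DataFrame:
    """Per-connection group comparison of Fisher-z values.

    Returns one row per tested connection with columns seed, target,
    mean_group1, mean_group2, t, df, p, p_fdr, significant
    (significant <=> p_fdr < q).
    """
    if not matrices:
        raise ValueError("no matrices given")
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0, 1)")
    labels = matrices[0].roi_labels
    kind = matrices[0].kind
    for m in matrices:
        if m.roi_labels != labels or m.kind != kind:
            raise ValueError("all matrices must share ROI labels and kind")
    if len(matrices) != len(groups):
        raise ValueError("matrices and groups must align")
    pairs = restriction.tested_pairs(labels, kind)
    index = {lab: i for i, lab in enumerate(labels)}
    rows = np.array([index[s] for s, _ in pairs])
    cols = np.array([index[t] for _, t in pairs])
    data = np.stack([m.values[rows, cols] for m in matrices])  # subjects x edges
    i1, i2 = _split_groups(groups, group1, group2)
    x, y = data[i1], data[i2]
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        bad = int((~np.isfinite(data)).any(axis=0).sum())
        logger.warning("%d tested connections contain undefined values", bad)
    t, df, p = _pooled_t(x, y)
    table = pd.DataFrame(
        {
            "seed": [s for s, _ in pairs],
            "target": [t_ for _, t_ in pairs],
            "mean_group1": x.mean(axis=0),
            "mean_group2": y.mean(axis=0),
            "t": t,
            "df": df,
            "p": p,
        }
    )
    if restriction.fdr_scope == "per_seed":
        table["p_fdr"] = np.nan
        for s, sub in table.groupby("seed", sort=False):
            table.loc[sub.index, "p_fdr"] = bh_fdr(sub["p"].to_numpy())
    else:
        table["p_fdr"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["p_fdr"] < q
    return table


def nodewise_metric_comparison(
    metric_tables: list[pd.DataFrame],
    groups: list[str],
    metric: str,
    q: float = 0.05,
    group1: str = "patient",
    group2: str = "control",
) -> pd.DataFrame:
    """Per-node group comparison of one topology metric.

    Undefined (NaN) values — e.g. path length of an isolated node — are
    dropped per node with a logged count; nodes left with fewer than two
    defined values in either group are reported as undefined rows and
    excluded from the BH correction.
    """
    if not metric_tables:
        raise ValueError("no metric tables given")
    if metric not in metric_tables[0].columns:
        raise ValueError(f"unknown metric {metric!r}")
    nodes = list(metric_tables[0].index)
    for tab in metric_tables:
        if list(tab.index) != nodes:
            raise ValueError("all metric tables must share the node index")
    values = np.stack([tab[metric].to_numpy(dtype=float) for tab in metric_tables])
    i1, i2 = _split_groups(groups, group1, group2)
    records = []
    n_dropped = 0
    for j, node in enumerate(nodes):
        x = values[i1, j]
        y = values[i2, j]
        xf, yf = x[np.isfinite(x)], y[np.isfinite(y)]
        n_dropped += (len(x) - len(xf)) + (len(y) - len(yf))
        if len(xf) < 2 or len(yf) < 2:
            records.append((node, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        t, df, p = _pooled_t(xf[:, None], yf[:, None])
        records.append((node, xf.mean(), yf.mean(), float(t[0]), df, float(p[0])))
    if n_dropped:
        logger.info("dropped %d undefined %s values", n_dropped, metric)
    table = pd.DataFrame(
        records,
        columns=["node", "mean_group1", "mean_group2", "t", "df", "p"],
    )
    table["metric"] = metric
    defined = table["p"].notna()
    table["p_fdr"] = np.nan
    if defined.any():
        table.loc[defined, "p_fdr"] = bh_fdr(table.loc[defined, "p"].to_numpy())
    table["significant"] = table["p_fdr"] < q
    return table[
        [
            "node",
            "metric",
            "mean_group1",
            "mean_group2",
            "t",
            "df",
            "p",
            "p_fdr",
            "significant",
        ]
    ]
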