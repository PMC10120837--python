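"""Per-trait summary statistics and the thresholded trait-correlation network.

The summary table mirrors the classical descriptive panel for a mapping
population: mean, median, sample standard deviation (n−1 divisor), variance,
max, min, range, coefficient of variation (percent), standard error, moment
skewness (g1 = m3 / m2^1.5) and excess kurtosis (m4 / m2² − 3). The
correlation network keeps a trait pair as an edge when the two-sided Pearson
test passes both a correlation floor and a p-value ceiling (|r| >= 0.10 and
p <= 0.05 by default), and tags each edge with its module pair.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import NetworkEdge, PhenotypeTable, ValidationError, get_logger

__all__ = ["summarize_traits", "correlation_network", "pearson_with_p", "plot_network"]

SUMMARY_ROWS = [
    "Mean", "Median", "Std_dev", "Variance", "Max", "Min", "Range",
    "C.V.", "SE", "Skewness", "Kurtosis",
]


def summarize_traits(pheno: PhenotypeTable) -> pd.DataFrame:
    """Descriptive statistics per trait, one column per trait.

    Missing values are dropped per trait. Each trait needs at least three
    observations; an all-missing trait raises. A constant trait is degenerate:
    its skewness and kurtosis are reported as 0 and the trait is listed in
    ``result.attrs["degenerate_traits"]``.
    """
    out = pd.DataFrame(index=SUMMARY_ROWS, columns=pheno.traits, dtype=float)
    degenerate: list[str] = []
    for trait in pheno.traits:
        x = pheno.values[trait].dropna().to_numpy(dtype=float)
        if x.size == 0:
            raise ValidationError(f"trait {trait!r} has no non-missing values")
        if x.size < 3:
            raise ValidationError(
                f"trait {trait!r} has only {x.size} non-missing values (need >= 3)"
            )
        sd = float(np.std(x, ddof=1))
        mean = float(np.mean(x))
        if sd == 0.0:
            degenerate.append(trait)
            skew = kurt = cv = 0.0
        else:
            skew = float(sps.skew(x, bias=True))
            kurt = float(sps.kurtosis(x, fisher=True, bias=True))
            cv = 100.0 * sd / mean
        out[trait] = [
            mean, float(np.median(x)), sd, sd**2, float(x.max()), float(x.min()),
            float(x.max() - x.min()), cv, sd / np.sqrt(x.size), skew, kurt,
        ]
    out.attrs["degenerate_traits"] = degenerate
    return out


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value from the exact t transform.

    ``t = r sqrt(n-2) / sqrt(1-r²)`` with n−2 degrees of freedom; |r| = 1
    yields p = 0.
    """
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(p)


def _module_pair(mod_a: str, mod_b: str) -> str:
    if mod_a == mod_b:
        return f"within-{mod_a}"
    return "-".join(sorted((mod_a, mod_b)))


def correlation_network(
    pheno: PhenotypeTable,
    r_min: float = 0.10,
    p_max: float = 0.05,
    min_pairs: int = 4,
) -> tuple[list[NetworkEdge], pd.DataFrame]:
    """Thresholded Pearson network over trait pairs.

    Correlations use pairwise-complete observations; an edge is kept iff
    |r| >= ``r_min`` and p <= ``p_max``. Zero-variance traits have their pairs
    skipped with a warning. Returns the edge list (node_a < node_b) and a
    per-module-pair edge count summary.
    """
    if not 0.0 <= r_min <= 1.0:
        raise ValidationError("r_min must be in [0, 1]")
    edges: list[NetworkEdge] = []
    counts: dict[str, int] = {}
    logger = get_logger()
    for a, b in combinations(pheno.traits, 2):
        sub = pheno.values[[a, b]].dropna()
        if len(sub) < min_pairs:
            raise ValidationError(
                f"trait pair ({a}, {b}) has {len(sub)} complete pairs (need >= {min_pairs})"
            )
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            warnings.warn(f"zero-variance trait in pair ({a}, {b}); pair skipped")
            logger.warning("correlation_network: pair (%s, %s) skipped (zero variance)", a, b)
            continue
        r, p = pearson_with_p(x, y)
        if abs(r) >= r_min and p <= p_max:
            mp = _module_pair(pheno.modules[a], pheno.modules[b])
            edges.append(NetworkEdge(*sorted((a, b)), r=r, p=p, module_pair=mp))
            counts[mp] = counts.get(mp, 0) + 1
    summary = pd.DataFrame(
        sorted(counts.items()), columns=["module_pair", "n_edges"]
    )
    return edges, summary


def plot_network(edges, modules: dict[str, str], path) -> None:
    """Static spring-layout plot of the trait network, colored by module."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    g = nx.Graph()
    for t, m in modules.items():
        g.add_node(t, module=m)
    for e in edges:
        g.add_edge(e.node_a, e.node_b, weight=abs(e.r), r=e.r)
    pos = nx.spring_layout(g, seed=0)
    palette = {"size": "#e6b422", "shape": "#888888", "color": "#4a90d9"}
    node_colors = [palette.get(modules.get(n, ""), "#cccccc") for n in g.nodes]
    edge_colors = ["#2d6cb5" if g.edges[e]["r"] > 0 else "#d97b29" for e in g.edges]
    widths = [4.0 * g.edges[e]["weight"] for e in g.edges]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx(g, pos, ax=ax, node_color=node_colors, edge_color=edge_colors,
                     width=widths, font_size=9)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
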