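"""Marker-based likelihood-ratio QTL scan with permutation thresholds.

Model
-----
At each marker the phenotype of an individual in genotype class ``j`` is
modelled as Normal(μ_j, σ²) with a common residual variance, so the
likelihood factorizes over genotype classes. Maximum-likelihood estimates are
the class means and the pooled residual variance with divisor n; under the
null (no QTL, H0: μ_j = μ) they are the grand mean and total variance with
divisor n. The test statistic is the log-likelihood ratio

    LR = 2 (ℓ1 − ℓ0) = n · ln(RSS0 / RSS1),

where RSS0 and RSS1 are null and alternative residual sums of squares.
Phenotypic variance explained is PVE = 100 · (1 − RSS1/RSS0). Genetic
effects: two classes (pseudo-testcross) → Δ = μ2 − μ1; three classes
(inter-cross, ordered AA/Aa/aa) → additive a = (μ_aa − μ_AA)/2 and dominance
d = μ_Aa − (μ_AA + μ_aa)/2.

QTLs are assumed to sit at marker positions — the scan evaluates markers
only, with no interval imputation between them. The genome-wide significance
threshold is the (1−α) order statistic of the maximum LR over the genome
under permutations of the phenotype vector against whole individuals, which
preserves the linkage-disequilibrium structure among markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    GenotypeMatrix,
    LinkageMap,
    PhenotypeTable,
    ValidationError,
    stage_rng,
)

__all__ = [
    "MarkerFit",
    "MarkerSkipped",
    "ScanResult",
    "fit_marker_model",
    "genome_scan",
    "permutation_threshold",
    "threshold_from_maxima",
    "scan_trait",
    "call_and_colocate",
    "plot_scan",
]

DEFAULT_MIN_CLASS_N = 5


class MarkerSkipped(Exception):
    """Raised when a marker is ineligible for the likelihood fit."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class MarkerFit:
    """Maximum-likelihood fit of the genotype-class model at one marker."""

    n: int
    class_labels: tuple[str, ...]
    n_j: tuple[int, ...]
    mu_j: tuple[float, ...]
    sigma2: float  # pooled ML residual variance (divisor n)
    mu0: float
    sigma2_0: float  # null ML variance (divisor n)
    lr: float
    pve_percent: float
    effects: dict[str, float] = field(default_factory=dict)
    zero_residual: bool = False

    @property
    def rss1(self) -> float:
        return self.n * self.sigma2

    @property
    def rss0(self) -> float:
        return self.n * self.sigma2_0


def _effects(labels: tuple[str, ...], mu: tuple[float, ...]) -> dict[str, float]:
    if len(mu) == 2:
        return {"delta": mu[1] - mu[0]}
    return {
        "additive": (mu[2] - mu[0]) / 2.0,
        "dominance": mu[1] - (mu[0] + mu[2]) / 2.0,
    }


def fit_marker_model(
    y,
    classes,
    min_class_n: int = DEFAULT_MIN_CLASS_N,
    class_labels: tuple[str, ...] | None = None,
) -> MarkerFit:
    """Fit the genotype-class normal model at a single marker.

    ``y`` and ``classes`` are aligned vectors; pairs with a missing phenotype
    or missing genotype (None/NaN) are dropped. Classes follow the declared
    ``class_labels`` order when given, otherwise sorted label order.
    Raises :class:`MarkerSkipped` when fewer than two classes remain or any
    observed class falls below ``min_class_n``.
    """
    y = np.asarray(y, dtype=float)
    cls = np.asarray(classes, dtype=object)
    keep = np.isfinite(y) & np.array([isinstance(c, str) for c in cls])
    y, cls = y[keep], cls[keep]
    observed = sorted(set(cls))
    if class_labels is None:
        labels = tuple(observed)
    else:
        labels = tuple(lab for lab in class_labels if lab in observed)
    if len(labels) < 2:
        raise MarkerSkipped("monomorphic")
    n = len(y)
    n_j, mu_j, rss1 = [], [], 0.0
    for lab in labels:
        yj = y[cls == lab]
        if len(yj) < min_class_n:
            raise MarkerSkipped("sparse_class")
        n_j.append(len(yj))
        mu_j.append(float(yj.mean()))
        rss1 += float(((yj - yj.mean()) ** 2).sum())
    mu0 = float(y.mean())
    rss0 = float(((y - mu0) ** 2).sum())
    zero_resid = rss1 <= 0.0
    if rss0 <= 0.0:
        lr, pve = 0.0, 0.0
    elif zero_resid:
        lr, pve = math.inf, 100.0 * (1.0 - rss1 / rss0)
    else:
        lr = n * math.log(rss0 / rss1)
        pve = 100.0 * (1.0 - rss1 / rss0)
    return MarkerFit(
        n=n, class_labels=labels, n_j=tuple(n_j), mu_j=tuple(mu_j),
        sigma2=rss1 / n, mu0=mu0, sigma2_0=rss0 / n, lr=lr, pve_percent=pve,
        effects=_effects(labels, tuple(mu_j)), zero_residual=zero_resid,
    )


# ---------------------------------------------------------------------------
# Vectorized scan kernel
# ---------------------------------------------------------------------------
def _class_masks(codes: np.ndarray, max_classes: int = 3):
    valid = codes >= 0
    masks = [(codes == k) for k in range(max_classes)]
    return valid, masks


def _eligibility(valid, masks, min_class_n):
    """Per-marker eligibility and skip reasons from class counts."""
    counts = np.stack([m.sum(axis=0) for m in masks])  # K x m
    present = counts > 0
    n_present = present.sum(axis=0)
    min_present = np.where(present, counts, np.iinfo(np.int64).max).min(axis=0)
    eligible = (n_present >= 2) & (min_present >= min_class_n)
    reasons = np.where(n_present < 2, "monomorphic",
                       np.where(min_present < min_class_n, "sparse_class", ""))
    return eligible, reasons, counts


def _lr_pve_matrix(y_mat: np.ndarray, valid, masks):
    """LR and PVE for every marker x phenotype-column pair.

    ``y_mat`` is n x P with no NaNs; missing genotypes are handled through the
    validity mask. Returns (lr, pve, rss0, rss1) each of shape (m, P) and the
    per-class sums/counts needed for class means.
    """
    y2 = y_mat**2
    vf = valid.astype(float)
    n_valid = vf.sum(axis=0)  # (m,)
    tot_y = vf.T @ y_mat  # m x P
    tot_y2 = vf.T @ y2
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = tot_y2 - tot_y**2 / n_valid[:, None]
        between = np.zeros_like(rss0)
        class_sums, class_counts = [], []
        for mk in masks:
            mf = mk.astype(float)
            nk = mf.sum(axis=0)  # (m,)
            sk = mf.T @ y_mat  # m x P
            class_sums.append(sk)
            class_counts.append(nk)
            between += np.where(nk[:, None] > 0, sk**2 / np.where(nk == 0, 1, nk)[:, None], 0.0)
        rss1 = tot_y2 - between
        rss1 = np.maximum(rss1, 0.0)
        lr = np.where(
            rss1 > 0,
            n_valid[:, None] * np.log(np.maximum(rss0, 1e-300) / np.where(rss1 > 0, rss1, 1.0)),
            np.inf,
        )
        lr = np.where(rss0 > 0, lr, 0.0)
        pve = np.where(rss0 > 0, 100.0 * (1.0 - rss1 / np.maximum(rss0, 1e-300)), 0.0)
    return lr, pve, rss0, rss1, class_sums, class_counts


# ---------------------------------------------------------------------------
# Scan orchestration
# ---------------------------------------------------------------------------
@dataclass
class ScanResult:
    """Per-marker LR profile for one trait, with optional permutation threshold."""

    trait: str
    table: pd.DataFrame  # per eligible marker: map position, LR, PVE, means, effects
    skipped: pd.DataFrame  # marker_id, reason
    n_individuals: int
    alpha: float | None = None
    threshold: float | None = None
    permutation_max_lrs: np.ndarray | None = None

    def qtl_calls(self) -> pd.DataFrame:
        """Markers whose LR meets or exceeds the genome-wide threshold."""
        if self.threshold is None:
            raise ValidationError("scan has no permutation threshold; run permutation_threshold")
        calls = self.table[self.table["lr"] >= self.threshold].copy()
        calls.insert(0, "trait", self.trait)
        calls["threshold"] = self.threshold
        return calls.reset_index(drop=True)

    def to_frame_full(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "trait", self.trait)
        if self.threshold is not None:
            out["threshold"] = self.threshold
        return out


def _prepare(pheno: PhenotypeTable, geno: GenotypeMatrix, lmap: LinkageMap, trait: str):
    """Align individuals, drop missing phenotypes, order markers along the map."""
    if trait not in pheno.traits:
        raise ValidationError(f"unknown trait {trait!r}")
    common = [i for i in geno.individuals if i in set(pheno.individuals)]
    if not common:
        raise ValidationError("no overlapping individuals between phenotypes and genotypes")
    y_all = pheno.values.loc[common, trait]
    kept_ids = y_all.dropna().index.tolist()
    y = y_all.dropna().to_numpy(dtype=float)

    in_map = set(lmap.marker_ids)
    geno_markers = geno.marker_ids
    mapped = [m for m in geno_markers if m in in_map]
    unmapped = [m for m in geno_markers if m not in in_map]
    meta = (
        lmap.positions_of(mapped)
        .reset_index()
        .sort_values(["linkage_group", "position"], kind="stable")
        .reset_index(drop=True)
    )
    mapped_sorted = meta["marker_id"].tolist()

    codes_all, _ = geno.class_codes()
    ind_pos = {ind: i for i, ind in enumerate(geno.individuals)}
    mkr_pos = {m: j for j, m in enumerate(geno_markers)}
    row_idx = [ind_pos[i] for i in kept_ids]
    col_idx = [mkr_pos[m] for m in mapped_sorted]
    codes = codes_all[np.ix_(row_idx, col_idx)]
    meta["seg_type"] = geno.marker_info.loc[mapped_sorted, "seg_type"].to_numpy()
    meta["class_labels"] = list(geno.marker_info.loc[mapped_sorted, "class_labels"])
    return y, codes, meta, unmapped


def genome_scan(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    lmap: LinkageMap,
    trait: str,
    min_class_n: int = DEFAULT_MIN_CLASS_N,
) -> ScanResult:
    """One LR fit per eligible marker, ordered along the linkage map."""
    y, codes, meta, unmapped = _prepare(pheno, geno, lmap, trait)
    if len(y) == 0:
        raise ValidationError(f"trait {trait!r} has no non-missing phenotypes")
    valid, masks = _class_masks(codes)
    eligible, reasons, _ = _eligibility(valid, masks, min_class_n)
    lr, pve, rss0, rss1, csums, ccounts = _lr_pve_matrix(y[:, None], valid, masks)
    lr, pve = lr[:, 0], pve[:, 0]

    with np.errstate(divide="ignore", invalid="ignore"):
        means = [
            np.where(ccounts[k] > 0, csums[k][:, 0] / np.where(ccounts[k] == 0, 1, ccounts[k]), np.nan)
            for k in range(len(masks))
        ]
    rows = []
    skipped = [{"marker_id": m, "reason": "not_in_map"} for m in unmapped]
    for j in range(len(meta)):
        if not eligible[j]:
            skipped.append({"marker_id": meta.loc[j, "marker_id"], "reason": reasons[j]})
            continue
        labels = tuple(meta.loc[j, "class_labels"])
        mu = tuple(float(means[k][j]) for k in range(len(labels)))
        eff = _effects(labels, mu)
        row = {
            "marker_id": meta.loc[j, "marker_id"],
            "linkage_group": meta.loc[j, "linkage_group"],
            "position": float(meta.loc[j, "position"]),
            "seg_type": meta.loc[j, "seg_type"],
            "n": int(valid[:, j].sum()),
            "lr": float(lr[j]),
            "pve_percent": float(pve[j]),
        }
        for k, lab in enumerate(labels):
            row[f"mean_{lab}"] = mu[k]
            row[f"n_{lab}"] = int(ccounts[k][j])
        row.update(eff)
        rows.append(row)
    table = pd.DataFrame(rows)
    return ScanResult(
        trait=trait,
        table=table,
        skipped=pd.DataFrame(skipped, columns=["marker_id", "reason"]),
        n_individuals=len(y),
    )


def threshold_from_maxima(maxima, alpha: float) -> float:
    """Genome-wide cutoff: the ceil((1−α)·N)-th order statistic of N permutation maxima.

    α = 1 degenerates to the minimum of the maxima.
    """
    maxima = np.asarray(maxima, dtype=float)
    if maxima.size == 0:
        raise ValidationError("no permutation maxima")
    if not 0.0 < alpha <= 1.0:
        raise ValidationError("alpha must be in (0, 1]")
    k = max(1, math.ceil((1.0 - alpha) * maxima.size))
    return float(np.sort(maxima)[k - 1])


def permutation_threshold(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    lmap: LinkageMap,
    trait: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_class_n: int = DEFAULT_MIN_CLASS_N,
) -> tuple[float, np.ndarray]:
    """Genome-wide LR threshold from phenotype permutations.

    The phenotype vector is shuffled against individuals ``n_perm`` times; the
    genome-wide maximum LR of each permutation is recorded and the threshold is
    the ceil((1−α)·n_perm)-th order statistic of those maxima. Markers with a
    zero residual variance (infinite LR) are excluded from the maxima.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if not 0.0 < alpha <= 1.0:
        raise ValidationError("alpha must be in (0, 1]")
    y, codes, meta, _ = _prepare(pheno, geno, lmap, trait)
    valid, masks = _class_masks(codes)
    eligible, _, _ = _eligibility(valid, masks, min_class_n)
    if not eligible.any():
        raise ValidationError("no eligible markers for permutation threshold")
    rng = stage_rng(seed, f"permutation_threshold:{trait}")
    perm = np.empty((len(y), n_perm))
    for p in range(n_perm):
        perm[:, p] = y[rng.permutation(len(y))]
    lr, _, _, _, _, _ = _lr_pve_matrix(perm, valid, masks)
    lr = lr[eligible]
    lr = np.where(np.isfinite(lr), lr, -np.inf)  # zero-residual markers excluded
    maxima = lr.max(axis=0)
    return threshold_from_maxima(maxima, alpha), maxima


def scan_trait(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    lmap: LinkageMap,
    trait: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_class_n: int = DEFAULT_MIN_CLASS_N,
) -> ScanResult:
    """Genome scan plus permutation threshold, ready for QTL calling."""
    result = genome_scan(pheno, geno, lmap, trait, min_class_n=min_class_n)
    thr, maxima = permutation_threshold(
        pheno, geno, lmap, trait, n_perm=n_perm, alpha=alpha, seed=seed,
        min_class_n=min_class_n,
    )
    result.alpha = alpha
    result.threshold = thr
    result.permutation_max_lrs = maxima
    return result


# ---------------------------------------------------------------------------
# QTL calling and cross-module co-location
# ---------------------------------------------------------------------------
def _merge_clusters(calls: pd.DataFrame, window_cm: float) -> dict[str, int]:
    """Union-find clustering of called markers; markers within ``window_cm`` on
    the same linkage group share a cluster (window 0 → identical markers only)."""
    markers = calls[["marker_id", "linkage_group", "position"]].drop_duplicates("marker_id")
    markers = markers.sort_values(["linkage_group", "position"]).reset_index(drop=True)
    parent = list(range(len(markers)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    if window_cm > 0:
        for i in range(1, len(markers)):
            if (
                markers.loc[i, "linkage_group"] == markers.loc[i - 1, "linkage_group"]
                and markers.loc[i, "position"] - markers.loc[i - 1, "position"] <= window_cm
            ):
                union(i, i - 1)
    return {markers.loc[i, "marker_id"]: find(i) for i in range(len(markers))}


def call_and_colocate(
    scans: Mapping[str, ScanResult],
    modules: Mapping[str, str],
    coloc_window_cm: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Collect QTL calls across traits and count module-level co-location.

    Every scan must already carry a permutation threshold. Two traits share a
    QTL when their called markers fall in the same co-location cluster — the
    identical marker at window 0, or within ``coloc_window_cm`` on one linkage
    group otherwise. The Venn counts report distinct QTL clusters per trait
    module and their pairwise/triple intersections.
    """
    missing = [t for t in scans if t not in modules]
    if missing:
        raise ValidationError(f"traits missing module tags: {missing}")
    frames = []
    for trait, scan in scans.items():
        calls = scan.qtl_calls()  # raises if unthresholded
        calls.insert(1, "module", modules[trait])
        frames.append(calls)
    qtl_table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["trait", "module", "marker_id"])
    )
    if len(qtl_table) == 0:
        venn = {"per_module": {}, "intersections": {}, "n_qtl_calls": 0}
        return qtl_table, venn

    cluster_of = _merge_clusters(qtl_table, coloc_window_cm)
    qtl_table["coloc_cluster"] = qtl_table["marker_id"].map(cluster_of)

    mod_sets: dict[str, set] = {}
    for _, row in qtl_table.iterrows():
        mod_sets.setdefault(row["module"], set()).add(row["coloc_cluster"])
    mods = sorted(mod_sets)
    venn = {
        "per_module": {m: len(mod_sets[m]) for m in mods},
        "intersections": {},
        "n_qtl_calls": int(len(qtl_table)),
    }
    from itertools import combinations

    for r in (2, 3):
        for combo in combinations(mods, r):
            inter = set.intersection(*(mod_sets[m] for m in combo))
            venn["intersections"]["&".join(combo)] = len(inter)
    return qtl_table, venn


def plot_scan(result: ScanResult, path) -> None:
    """Manhattan-style LR profile with the permutation threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table
    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset, ticks, labels = 0.0, [], []
    for lg, sub in tab.groupby("linkage_group", sort=True):
        x = sub["position"].to_numpy() + offset
        ax.plot(x, sub["lr"], ".", ms=3)
        ticks.append(offset + sub["position"].max() / 2)
        labels.append(str(lg))
        offset += sub["position"].max() + 10
    if result.threshold is not None:
        ax.axhline(result.threshold, ls="--", color="tab:blue",
                   label=f"genome-wide {100 * (1 - (result.alpha or 0.05)):.0f}% threshold")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xticks(ticks, labels, fontsize=7, rotation=90)
    ax.set_ylabel("LR")
    ax.set_title(result.trait)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
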