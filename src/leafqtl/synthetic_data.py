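"""Synthetic inputs: an outbred F1 cross with planted QTLs, parametric lobed
leaf images with ground-truth traits, and a block-structured FPKM matrix.

The cross generator emulates a full-sib mapping population of a heterozygous
tree cross: markers segregate either as pseudo-testcross loci (heterozygous in
one parent, two genotype classes expected 1:1) or as inter-cross loci
(heterozygous in both parents, three classes expected 1:2:1). Gametes
recombine between adjacent markers with the Haldane map function
``r = (1 - exp(-2 d / 100)) / 2`` for a spacing of ``d`` centimorgans — no
crossover interference is modelled.

Defaults mirror the study system the package targets: 179 progeny and a map
of 20 linkage groups; the desk-scale default density is 100 markers per group
at 1 cM spacing (denser maps, up to the ~9 600 markers of a full RAD-seq map,
are supported but not default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon

from .core_io import (
    CANONICAL_TRAITS,
    GenotypeMatrix,
    LinkageMap,
    PhenotypeTable,
    ExpressionMatrix,
    SEGREGATION_LABELS,
    ValidationError,
    stage_rng,
)
from .morphometrics import derive_shape

__all__ = [
    "CrossSpec",
    "QTLEffect",
    "QTLSpec",
    "LeafShapeSpec",
    "simulate_cross",
    "simulate_phenotypes",
    "generate_leaf_image",
    "simulate_expression",
    "haldane_r",
]


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


# ---------------------------------------------------------------------------
# Cross simulation
# ---------------------------------------------------------------------------
@dataclass
class CrossSpec:
    """Parameters of the simulated full-sib F1 cross."""

    n_progeny: int = 179
    linkage_groups: int = 20
    markers_per_group: int = 100
    marker_spacing: float = 1.0  # cM between adjacent markers
    testcross_fraction: float = 0.5
    maternal_testcross_fraction: float = 0.5  # informative parent of testcross loci
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny <= 0 or self.linkage_groups <= 0:
            raise ValidationError("counts must be positive")
        if self.markers_per_group <= 0:
            raise ValidationError("markers_per_group must be positive")
        if self.marker_spacing < 0:
            raise ValidationError("marker_spacing must be >= 0 cM")
        if not 0.0 <= self.testcross_fraction <= 1.0:
            raise ValidationError("testcross_fraction must be in [0, 1]")
        if not 0.0 <= self.maternal_testcross_fraction <= 1.0:
            raise ValidationError("maternal_testcross_fraction must be in [0, 1]")


def _gametes(rng: np.random.Generator, n: int, rec: np.ndarray) -> np.ndarray:
    """n haplotype-indicator vectors along one linkage group.

    ``rec[j]`` is the recombination fraction between markers j and j+1; the
    indicator starts at either parental haplotype with probability 1/2 and
    switches between adjacent markers with probability ``rec[j]``.
    """
    m = len(rec) + 1
    h = np.empty((n, m), dtype=np.int32)
    h[:, 0] = rng.integers(0, 2, size=n)
    if m > 1:
        h[:, 1:] = rng.random((n, m - 1)) < rec[None, :]
        np.cumsum(h, axis=1, out=h)  # start state + cumulative switch count
        h %= 2
    return h.astype(np.int8)


def simulate_cross(spec: CrossSpec) -> tuple[LinkageMap, GenotypeMatrix]:
    """Simulate a linkage map and F1 genotype matrix under the Haldane model.

    Testcross loci are phase-coupled within the informative parent (haplotype 0
    always carries the ``a`` allele), so genotype dependence between linked loci
    decays as 1 − 2r with map distance; loci informative in different parents
    are independent, as in a real pseudo-testcross design.
    """
    rng = stage_rng(spec.seed, "simulate_cross")
    n = spec.n_progeny
    m_lg = spec.markers_per_group

    map_rows = []
    call_cols: dict[str, np.ndarray] = {}
    seg_types: list[str] = []
    marker_ids: list[str] = []

    rec = np.full(m_lg - 1, haldane_r(spec.marker_spacing)) if m_lg > 1 else np.empty(0)
    for lg in range(1, spec.linkage_groups + 1):
        hm = _gametes(rng, n, rec)  # maternal gametes
        hf = _gametes(rng, n, rec)  # paternal gametes
        is_test = rng.random(m_lg) < spec.testcross_fraction
        maternal = rng.random(m_lg) < spec.maternal_testcross_fraction
        for j in range(m_lg):
            mid = f"m{lg:02d}_{j + 1:04d}"
            marker_ids.append(mid)
            map_rows.append((mid, f"LG{lg:02d}", j * spec.marker_spacing))
            if is_test[j]:
                seg_types.append("testcross2")
                h = hm[:, j] if maternal[j] else hf[:, j]
                labels = np.array(SEGREGATION_LABELS["testcross2"])
                call_cols[mid] = labels[h]
            else:
                seg_types.append("intercross3")
                n_ref = (hm[:, j] == 0).astype(np.int8) + (hf[:, j] == 0).astype(np.int8)
                labels = np.array(["aa", "Aa", "AA"])
                call_cols[mid] = labels[n_ref]

    individuals = [f"F1_{i + 1:03d}" for i in range(n)]
    lmap = LinkageMap(pd.DataFrame(map_rows, columns=["marker_id", "linkage_group", "position"]))
    calls = pd.DataFrame(call_cols, index=individuals, columns=marker_ids)
    marker_info = pd.DataFrame(
        {"seg_type": seg_types, "class_labels": [SEGREGATION_LABELS[s] for s in seg_types]},
        index=pd.Index(marker_ids, name="marker_id"),
    )
    return lmap, GenotypeMatrix(individuals, marker_info, calls)


# ---------------------------------------------------------------------------
# Phenotype simulation with planted QTLs
# ---------------------------------------------------------------------------
#: expected genotype-class frequencies under Mendelian segregation
_EXPECTED_FREQ = {"testcross2": (0.5, 0.5), "intercross3": (0.25, 0.5, 0.25)}


@dataclass(frozen=True)
class QTLEffect:
    """One planted effect: genotype-class means of ``marker_id`` for ``trait``."""

    trait: str
    marker_id: str
    class_means: tuple[float, ...]


@dataclass
class QTLSpec:
    """Planted genetic architecture for simulated traits.

    ``residual_sd`` may be one value for all traits or a per-trait mapping;
    ``modules`` tags traits not in the canonical leaf-trait table.
    """

    effects: list[QTLEffect] = field(default_factory=list)
    residual_sd: float | Mapping[str, float] = 1.0
    modules: Mapping[str, str] = field(default_factory=dict)

    def sd_for(self, trait: str) -> float:
        sd = self.residual_sd[trait] if isinstance(self.residual_sd, Mapping) else self.residual_sd
        if sd <= 0:
            raise ValidationError(f"residual_sd for {trait!r} must be > 0")
        return float(sd)


def _between_class_variance(freqs: Sequence[float], means: Sequence[float]) -> float:
    f = np.asarray(freqs, dtype=float)
    mu = np.asarray(means, dtype=float)
    grand = float(f @ mu)
    return float(f @ (mu - grand) ** 2)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, qtls: QTLSpec, seed: int = 0
) -> tuple[PhenotypeTable, dict]:
    """Draw trait values as the sum of planted class means plus Normal noise.

    Each individual's value for a trait is the class mean at its genotype of
    every planted QTL for that trait (summed), plus Normal(0, residual_sd²)
    noise. The truth record stores, per trait and planted marker, the class
    means and the theoretical PVE — the between-class variance under expected
    Mendelian class frequencies divided by the total trait variance.
    """
    rng = stage_rng(seed, "simulate_phenotypes")
    traits = sorted({e.trait for e in qtls.effects})
    if not traits:
        raise ValidationError("QTLSpec plants no effects")
    n = genotypes.n_individuals()
    values = pd.DataFrame(0.0, index=genotypes.individuals, columns=traits)
    truth: dict = {"traits": {}}

    for trait in traits:
        sd = qtls.sd_for(trait)
        genetic_var = 0.0
        planted = []
        for eff in (e for e in qtls.effects if e.trait == trait):
            if eff.marker_id not in genotypes.calls.columns:
                raise ValidationError(f"QTL references unknown marker {eff.marker_id!r}")
            info = genotypes.marker_info.loc[eff.marker_id]
            labels = tuple(info["class_labels"])
            if len(eff.class_means) != len(labels):
                raise ValidationError(
                    f"{eff.marker_id}: {len(labels)} classes but "
                    f"{len(eff.class_means)} class means"
                )
            freqs = _EXPECTED_FREQ[info["seg_type"]]
            lut = dict(zip(labels, eff.class_means))
            expected = float(np.dot(freqs, eff.class_means))
            col = genotypes.calls[eff.marker_id]
            contrib = np.array([lut.get(v, expected) if isinstance(v, str) else expected
                                for v in col])
            values[trait] += contrib
            bvar = _between_class_variance(freqs, eff.class_means)
            genetic_var += bvar
            planted.append(
                {"marker_id": eff.marker_id, "class_labels": labels,
                 "class_means": list(eff.class_means), "between_class_variance": bvar}
            )
        values[trait] += rng.normal(0.0, sd, size=n)
        total_var = genetic_var + sd**2
        for rec in planted:
            rec["theoretical_pve_percent"] = 100.0 * rec["between_class_variance"] / total_var
        truth["traits"][trait] = {
            "residual_sd": sd,
            "total_variance": total_var,
            "qtls": planted,
        }

    modules = {
        t: qtls.modules.get(t, CANONICAL_TRAITS.get(t, ("size",))[0]) for t in traits
    }
    return PhenotypeTable(values, modules), truth


# ---------------------------------------------------------------------------
# Parametric lobed-leaf images
# ---------------------------------------------------------------------------
@dataclass
class LeafShapeSpec:
    """Parametric leaf: an ellipse modulated by a lobe term in polar form.

    The outline is ``rho(theta) = E(theta) * (1 + alpha * |cos(k theta / 2)|^p)``
    where ``E`` is the ellipse with semi-axes L/2 and W/2. ``k`` equals the
    visible lobe count on [0, 2pi), so it maps directly onto the manually
    counted lobe trait.
    """

    length_cm: float = 15.5
    width_cm: float = 13.5
    lobe_count: int = 0
    lobe_depth: float = 0.0  # alpha, fraction of local radius
    lobe_sharpness: float = 2.0  # p
    color: tuple[float, float, float] = (57.0, 74.0, 36.0)  # mean leaf RGB
    pixel_scale: float = 0.02  # cm per pixel
    noise_sd: float = 8.0  # color noise, 0-255 units

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ValidationError("leaf length and width must be > 0")
        if self.lobe_count < 0:
            raise ValidationError("lobe_count must be >= 0")
        if not 0.0 <= self.lobe_depth < 0.6:
            raise ValidationError("lobe_depth must be in [0, 0.6) (self-intersection risk)")
        if self.lobe_count == 0 and self.lobe_depth != 0.0:
            raise ValidationError("lobe_depth must be 0 when lobe_count is 0")
        if self.lobe_sharpness <= 0:
            raise ValidationError("lobe_sharpness must be > 0")
        if self.pixel_scale <= 0:
            raise ValidationError("pixel_scale must be > 0")


def _leaf_polygon(spec: LeafShapeSpec, n_vertices: int = 4096) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a, b = spec.length_cm / 2.0, spec.width_cm / 2.0
    ellipse = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    lobes = 1.0 + spec.lobe_depth * np.abs(np.cos(spec.lobe_count * theta / 2.0)) ** spec.lobe_sharpness
    rho = ellipse * lobes
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])  # (x, y) in cm


def _polygon_area_perimeter(xy: np.ndarray) -> tuple[float, float]:
    x, y = xy[:, 0], xy[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * y2 - x2 * y))
    perim = float(np.sum(np.hypot(x2 - x, y2 - y)))
    return float(area), perim


def generate_leaf_image(
    spec: LeafShapeSpec, seed: int = 0, n_vertices: int = 4096
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Rasterize a parametric leaf on a white background.

    Returns the RGB uint8 image, the boolean foreground mask, and a
    ground-truth trait record computed analytically from an ``n_vertices``-gon
    of the same outline (area and perimeter by the shoelace formula and
    polyline length; length and width as axis extents, the outline being
    generated with its major axis horizontal).
    """
    rng = stage_rng(seed, "generate_leaf_image")
    long_axis_px = spec.length_cm * (1 + spec.lobe_depth) / spec.pixel_scale
    if long_axis_px < 200:
        raise ValidationError(
            f"raster resolution too low: long axis spans {long_axis_px:.0f} px < 200; "
            "decrease pixel_scale"
        )
    xy = _leaf_polygon(spec, n_vertices)
    area, perim = _polygon_area_perimeter(xy)
    ll = float(xy[:, 0].max() - xy[:, 0].min())
    lw = float(xy[:, 1].max() - xy[:, 1].min())
    if lw > ll:
        ll, lw = lw, ll
    ar, p_l, p_lw, rect, cir = derive_shape(area, perim, ll, lw)
    r, g, b = spec.color
    truth = {
        "LA": area, "LP": perim, "LL": ll, "LW": lw, "LLo": spec.lobe_count,
        "AR": ar, "P_L": p_l, "P_LW": p_lw, "Rect": rect, "Cir": cir,
        "R": r, "G": g, "B": b, "CV": 65536.0 * r + 256.0 * g + b,
    }

    margin = 4  # px of background around the blade
    scale = spec.pixel_scale
    x0, y0 = xy[:, 0].min(), xy[:, 1].min()
    width = int(np.ceil((xy[:, 0].max() - x0) / scale)) + 2 * margin
    height = int(np.ceil((xy[:, 1].max() - y0) / scale)) + 2 * margin
    rows = (xy[:, 1] - y0) / scale + margin
    cols = (xy[:, 0] - x0) / scale + margin
    rr, cc = _draw_polygon(rows, cols, shape=(height, width))
    mask = np.zeros((height, width), dtype=bool)
    mask[rr, cc] = True

    image = np.full((height, width, 3), 255, dtype=np.uint8)
    n_fg = int(mask.sum())
    for ch, mean in enumerate(spec.color):
        vals = mean + (rng.normal(0.0, spec.noise_sd, size=n_fg) if spec.noise_sd > 0 else 0.0)
        image[mask, ch] = np.clip(np.round(vals), 0, 255).astype(np.uint8)
    return image, mask, truth


# ---------------------------------------------------------------------------
# Block-structured expression matrix
# ---------------------------------------------------------------------------
def simulate_expression(
    n_genes: int,
    samples: Sequence[str],
    cluster_spec: Sequence[tuple[int, Sequence[str], Sequence[str]]],
    noise_sd: float = 0.5,
    seed: int = 0,
    base_log2: float = 5.0,
    contrast_log2: float = 3.0,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Genes x tissues FPKM with block-correlated clusters.

    Each cluster of ``(size, up_tissues, down_tissues)`` shares a log2 template
    — ``base + contrast`` in up tissues, ``base - contrast`` in down tissues,
    ``base`` elsewhere — with additive Gaussian noise on the log2 scale (i.e.
    multiplicative log-normal noise on FPKM). Genes not claimed by any cluster
    get independent random profiles. Returns the matrix and the true
    gene-to-cluster assignment (background genes labelled ``"bg"``).
    """
    rng = stage_rng(seed, "simulate_expression")
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample labels")
    sizes = [int(s) for s, _, _ in cluster_spec]
    if any(s <= 0 for s in sizes):
        raise ValidationError("cluster sizes must be positive")
    if sum(sizes) > n_genes:
        raise ValidationError(f"cluster sizes sum to {sum(sizes)} > n_genes = {n_genes}")

    log2x = np.empty((n_genes, len(samples)))
    labels: dict[str, str] = {}
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    row = 0
    for ci, (size, up, down) in enumerate(cluster_spec, start=1):
        unknown = (set(up) | set(down)) - set(samples)
        if unknown:
            raise ValidationError(f"cluster {ci}: unknown tissue(s) {sorted(unknown)}")
        template = np.full(len(samples), base_log2)
        template[[samples.index(t) for t in up]] = base_log2 + contrast_log2
        template[[samples.index(t) for t in down]] = base_log2 - contrast_log2
        block = template[None, :] + (
            rng.normal(0.0, noise_sd, size=(size, len(samples))) if noise_sd > 0 else 0.0
        )
        log2x[row : row + size] = block
        for g in genes[row : row + size]:
            labels[g] = f"C{ci}"
        row += size
    n_bg = n_genes - row
    if n_bg:
        log2x[row:] = rng.normal(base_log2, 1.5, size=(n_bg, len(samples)))
        for g in genes[row:]:
            labels[g] = "bg"
    fpkm = pd.DataFrame(np.exp2(log2x), index=genes, columns=samples)
    return ExpressionMatrix(fpkm), labels
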