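"""Domain types, file I/O, configuration and logging shared by all pipeline stages.

The pipeline works with four tabular objects: a linkage map (markers ordered
in centimorgans on linkage groups), a genotype matrix for an outbred F1
population (markers segregate either 1:1 with two genotype classes, the
pseudo-testcross configuration, or 1:2:1 with three classes when both parents
are heterozygous), a phenotype table of leaf traits grouped into size / shape /
color modules, and a genes-by-tissues FPKM expression matrix.

File dialects
-------------
* linkage map — CSV with columns ``marker_id, linkage_group, position``.
* genotypes — CSV with a two-row header: row 1 holds ``individual`` followed by
  marker ids, row 2 holds the segregation type of each marker (``testcross2``
  or ``intercross3``). Cells are class labels (``aa``/``ab`` for testcross,
  ``AA``/``Aa``/``aa`` for intercross); missing calls are empty or ``NA``.
* phenotypes — CSV, one row per individual; trait columns may be tagged
  ``name:module`` or left bare, in which case the module is inferred from the
  canonical leaf-trait table.
* expression — TSV, genes in rows, tissue samples in columns, FPKM values.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from zlib import crc32

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "LinkageMap",
    "GenotypeMatrix",
    "PhenotypeTable",
    "ExpressionMatrix",
    "NetworkEdge",
    "CANONICAL_TRAITS",
    "SEGREGATION_LABELS",
    "read_linkage_map",
    "read_genotypes",
    "read_phenotypes",
    "read_expression",
    "read_dataset",
    "write_results",
    "write_linkage_map",
    "write_genotypes",
    "write_phenotypes",
    "write_expression",
    "edges_to_frame",
    "get_logger",
    "stage_rng",
    "write_manifest",
]


class SchemaError(ValueError):
    """A file is missing a required column or header."""


class ValidationError(ValueError):
    """A parsed object violates a declared invariant."""


# ---------------------------------------------------------------------------
# Canonical leaf-trait table: name -> (module, units)
# ---------------------------------------------------------------------------
# Four size traits, six shape traits (lobe count included), and the four
# quantitative color traits. CV is the composite 65536*R + 256*G + B.
CANONICAL_TRAITS: dict[str, tuple[str, str]] = {
    "LA": ("size", "cm^2"),
    "LP": ("size", "cm"),
    "LL": ("size", "cm"),
    "LW": ("size", "cm"),
    "LLo": ("shape", "count"),
    "AR": ("shape", "ratio"),
    "P_L": ("shape", "ratio"),
    "P_LW": ("shape", "ratio"),
    "Rect": ("shape", "ratio"),
    "Cir": ("shape", "ratio"),
    "R": ("color", "0-255"),
    "G": ("color", "0-255"),
    "B": ("color", "0-255"),
    "CV": ("color", "composite"),
}

#: genotype class labels by segregation type, in fixed (ordered) convention
SEGREGATION_LABELS: dict[str, tuple[str, ...]] = {
    "testcross2": ("aa", "ab"),
    "intercross3": ("AA", "Aa", "aa"),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------
@dataclass
class LinkageMap:
    """Ordered markers with linkage group and centimorgan position.

    ``table`` has columns ``marker_id``, ``linkage_group``, ``position``;
    rows are kept sorted by (linkage group, position).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "linkage_group", "position"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"linkage map missing column(s): {sorted(missing)}")
        if self.table["marker_id"].duplicated().any():
            dups = self.table.loc[self.table["marker_id"].duplicated(), "marker_id"]
            raise ValidationError(f"duplicate marker ids in map: {list(dups)[:5]}")
        if (self.table["position"] < 0).any():
            raise ValidationError("linkage positions must be >= 0 cM")
        self.table = (
            self.table.sort_values(["linkage_group", "position"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker_id"])

    def positions_of(self, marker_ids: Sequence[str]) -> pd.DataFrame:
        tab = self.table.set_index("marker_id")
        return tab.loc[list(marker_ids)]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Genotype class calls for an outbred F1 population.

    ``marker_info`` is indexed by marker id with columns ``seg_type`` and
    ``class_labels`` (a tuple); ``calls`` is individuals x markers with class
    labels as strings and NaN for missing.
    """

    individuals: list[str]
    marker_info: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual ids")
        if list(self.calls.index) != list(self.individuals):
            raise ValidationError("calls rows must align with individual ids")
        if list(self.calls.columns) != list(self.marker_info.index):
            raise ValidationError("calls columns must align with marker_info")
        for mid, row in self.marker_info.iterrows():
            seg, labels = row["seg_type"], tuple(row["class_labels"])
            if seg not in SEGREGATION_LABELS:
                raise ValidationError(f"marker {mid}: unknown segregation type {seg!r}")
            want = 2 if seg == "testcross2" else 3
            if len(labels) != want:
                raise ValidationError(
                    f"marker {mid}: {seg} requires {want} class labels, got {labels}"
                )
            col = self.calls[mid]
            bad = col.dropna()[~col.dropna().isin(labels)]
            if len(bad):
                raise ValidationError(
                    f"marker {mid}: undeclared call(s) {sorted(set(bad))[:5]}"
                )

    @property
    def marker_ids(self) -> list[str]:
        return list(self.marker_info.index)

    def n_individuals(self) -> int:
        return len(self.individuals)

    def class_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer-coded calls (n x m, -1 = missing) and per-marker class counts.

        Codes index into each marker's declared ``class_labels`` order.
        """
        n, m = self.calls.shape
        codes = np.full((n, m), -1, dtype=np.int8)
        n_classes = np.empty(m, dtype=np.int8)
        raw = self.calls.to_numpy(dtype=object)
        label_sets = self.marker_info["class_labels"].tolist()
        for j, labels in enumerate(label_sets):
            n_classes[j] = len(labels)
            col = raw[:, j]
            for k, lab in enumerate(labels):
                codes[col == lab, j] = k
        return codes, n_classes


@dataclass
class PhenotypeTable:
    """Leaf trait values per individual, each trait tagged with its module."""

    values: pd.DataFrame  # individuals x traits
    modules: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.values.columns)) != len(self.values.columns):
            raise ValidationError("duplicate trait names")
        for trait in self.values.columns:
            if trait not in self.modules:
                if trait not in CANONICAL_TRAITS:
                    raise SchemaError(
                        f"trait {trait!r} has no module tag and is not a canonical "
                        "leaf trait; tag it as 'name:module'"
                    )
                self.modules[trait] = CANONICAL_TRAITS[trait][0]
                self.units.setdefault(trait, CANONICAL_TRAITS[trait][1])
            elif self.modules[trait] not in {"size", "shape", "color"}:
                raise ValidationError(
                    f"trait {trait!r}: unknown module {self.modules[trait]!r}"
                )

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait_vector(self, trait: str) -> pd.Series:
        return self.values[trait]


@dataclass
class ExpressionMatrix:
    """Genes x tissue-samples FPKM matrix (non-negative)."""

    fpkm: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.fpkm.columns)) != len(self.fpkm.columns):
            raise ValidationError("duplicate sample labels")
        if len(set(self.fpkm.index)) != len(self.fpkm.index):
            raise ValidationError("duplicate gene ids")
        if (self.fpkm.values < 0).any():
            bad = self.fpkm.index[(self.fpkm.values < 0).any(axis=1)]
            raise ValidationError(f"negative FPKM for gene(s): {list(bad)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.fpkm.columns)


@dataclass(frozen=True)
class NetworkEdge:
    """Undirected correlation-network edge; node_a < node_b by construction."""

    node_a: str
    node_b: str
    r: float
    p: float
    module_pair: str | None = None

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValidationError("self-loop edge")
        if self.node_a > self.node_b:
            object.__setattr__(self, "node_a", self.node_b)
            object.__setattr__(self, "node_b", self.node_a)
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"correlation out of range: {self.r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------
def _check_ids(ids: Iterable, what: str) -> list[str]:
    """Validate row ids; report 1-based line numbers of unparseable ones."""
    out, bad = [], []
    for lineno, raw in enumerate(ids, start=2):  # header is line 1
        s = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
        if not s:
            bad.append(lineno)
        else:
            out.append(s)
    if bad:
        raise ValidationError(f"{what}: unparseable ids at line(s) {bad}")
    if len(set(out)) != len(out):
        dups = sorted({x for x in out if out.count(x) > 1})
        raise ValidationError(f"{what}: duplicate ids {dups[:5]}")
    return out


def read_linkage_map(path: str | Path) -> LinkageMap:
    df = pd.read_csv(path)
    return LinkageMap(df)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    head = pd.read_csv(path, header=None, nrows=2)
    if str(head.iloc[0, 0]).strip().lower() != "individual":
        raise SchemaError("genotype CSV: first header cell must be 'individual'")
    marker_ids = [str(x) for x in head.iloc[0, 1:]]
    seg_types = [str(x).strip() for x in head.iloc[1, 1:]]
    for mid, seg in zip(marker_ids, seg_types):
        if seg not in SEGREGATION_LABELS:
            raise SchemaError(f"marker {mid}: unknown segregation type {seg!r}")
    body = pd.read_csv(path, header=None, skiprows=2, dtype=str, keep_default_na=False)
    individuals = _check_ids(body.iloc[:, 0], "genotype CSV")
    calls = body.iloc[:, 1:].copy()
    calls.columns = marker_ids
    calls.index = individuals
    calls = calls.apply(lambda c: c.str.strip()).replace({"": np.nan, "NA": np.nan})
    marker_info = pd.DataFrame(
        {
            "seg_type": seg_types,
            "class_labels": [SEGREGATION_LABELS[s] for s in seg_types],
        },
        index=pd.Index(marker_ids, name="marker_id"),
    )
    return GenotypeMatrix(individuals, marker_info, calls)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path)
    first = df.columns[0]
    if first.lower() not in {"individual", "id"}:
        raise SchemaError("phenotype CSV: first column must be 'individual' or 'id'")
    individuals = _check_ids(df[first], "phenotype CSV")
    modules: dict[str, str] = {}
    cols: list[str] = []
    for col in df.columns[1:]:
        if ":" in col:
            name, module = col.split(":", 1)
            modules[name] = module
            cols.append(name)
        else:
            cols.append(col)
    values = df.iloc[:, 1:].astype(float)
    values.columns = cols
    values.index = individuals
    return PhenotypeTable(values, modules)


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_ids(df.index, "expression TSV")
    return ExpressionMatrix(df.astype(float))


_READERS = {
    "map": read_linkage_map,
    "genotype": read_genotypes,
    "phenotype": read_phenotypes,
    "expression": read_expression,
}


def read_dataset(path: str | Path, schema: str):
    """Dispatch to the typed reader for ``schema`` in {map, genotype, phenotype, expression}."""
    try:
        reader = _READERS[schema]
    except KeyError:
        raise SchemaError(f"unknown dataset kind {schema!r}; expected one of {sorted(_READERS)}")
    return reader(path)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------
def edges_to_frame(edges: Sequence[NetworkEdge]) -> pd.DataFrame:
    cols = ["node_a", "node_b", "r", "p", "module_pair"]
    if not edges:
        return pd.DataFrame(columns=cols)
    rows = [(e.node_a, e.node_b, e.r, e.p, e.module_pair) for e in edges]
    return pd.DataFrame(rows, columns=cols)


def _format_float(x) -> str:
    if isinstance(x, float):
        if np.isnan(x):
            return ""
        return f"{x:.6g}"
    return str(x)


def write_results(obj, path: str | Path, fmt: str = "tsv") -> Path:
    """Serialize a result table (DataFrame, edge list, or object with .to_frame()).

    Column order is preserved deterministically and floats are written with six
    significant digits, so re-writing a re-read file is bit-identical.
    """
    path = Path(path)
    if isinstance(obj, (list, tuple)) and (not obj or isinstance(obj[0], NetworkEdge)):
        df = edges_to_frame(obj)
    elif hasattr(obj, "to_frame_full"):
        df = obj.to_frame_full()
    elif isinstance(obj, pd.DataFrame):
        df = obj
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        out = df.map(_format_float) if len(df) else df
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif fmt == "json":
        records = json.loads(df.to_json(orient="records", double_precision=10))
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_linkage_map(lmap: LinkageMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = lmap.table.copy()
    out["position"] = out["position"].map(_format_float)
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> Path:
    """Two-row-header genotype CSV (marker ids, then segregation types)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write("individual," + ",".join(geno.marker_ids) + "\n")
        fh.write("," + ",".join(geno.marker_info["seg_type"]) + "\n")
        calls = geno.calls.fillna("")
        for ind in geno.individuals:
            fh.write(ind + "," + ",".join(calls.loc[ind]) + "\n")
    return path


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> Path:
    """Phenotype CSV with traits tagged ``name:module`` in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = pheno.values.copy()
    out.columns = [f"{t}:{pheno.modules[t]}" for t in out.columns]
    out = out.map(_format_float)
    out.insert(0, "individual", pheno.individuals)
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def write_expression(expr: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = expr.fpkm.map(_format_float)
    out.index.name = "gene"
    out.to_csv(path, sep="\t", lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Logging, seeds, run manifest
# ---------------------------------------------------------------------------
def get_logger(name: str = "leafqtl") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator derived from one global seed and the stage name.

    Hashing the stage name keeps stages independently reproducible: re-running
    one stage does not perturb the random stream of another.
    """
    return np.random.default_rng([int(seed) % (2**31), crc32(stage.encode())])


def write_manifest(path: str | Path, stage: str, seed: int | None,
                   params: Mapping, dims: Mapping) -> Path:
    """Record a stage's parameters, seed, and input dimensions as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"stage": stage, "seed": seed, "params": dict(params), "input_dims": dict(dims)}
    path.write_text(json.dumps(doc, indent=1, default=str) + "\n")
    get_logger().info("stage=%s seed=%s dims=%s params=%s", stage, seed, dict(dims), dict(params))
    return path
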