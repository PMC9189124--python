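"""Domain containers and file formats for multi-cohort expression analysis.

The objects here are deliberately thin wrappers around pandas structures:
an :class:`ExpressionDataset` is a gene x sample matrix of (already
log-scale, producer-normalized) expression values plus per-sample
annotations; a :class:`MetaboliteTable` holds per-sample metabolite
concentrations for the anchor cohort; a :class:`GeneModule` is an ordered
gene list (rank order = importance) with optional selection scores.

Supported file formats are plain TSV/CSV matrices, GCT 1.2, GMT gene
sets, TSV annotation tables and a small YAML manifest that ties a
collection of cohorts together.  All writers emit UTF-8, tab-separated,
'.'-decimal text.  Missing values are rejected at load time: every
downstream statistic assumes complete vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TISSUE_CLASSES",
    "FormatError",
    "ExpressionDataset",
    "DatasetCollection",
    "MetaboliteTable",
    "GeneModule",
    "validate_gene_id",
    "read_expression_table",
    "write_expression_table",
    "collapse_duplicate_genes",
    "gene_universe",
    "read_gmt",
    "write_gmt",
    "read_metabolite_table",
    "write_metabolite_table",
    "read_annotations",
    "write_annotations",
    "resolve_class_filter",
    "samples_in_class",
    "load_collection",
    "write_collection",
]

#: Recognised tissue classes, ordered roughly by disease progression.
TISSUE_CLASSES = (
    "normal",
    "stroma",
    "PIN",
    "cancer_low_grade",
    "cancer_high_grade",
    "metastasis",
    "cell_line",
    "other",
)


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def validate_gene_id(symbol: str) -> str:
    """Check a gene/probe identifier: non-empty, no tab or newline."""
    if not isinstance(symbol, str) or symbol == "":
        raise ValueError(f"gene id must be a non-empty string, got {symbol!r}")
    if "\t" in symbol or "\n" in symbol or "\r" in symbol:
        raise ValueError(f"gene id may not contain tab/newline: {symbol!r}")
    return symbol


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            raise ValueError(f"duplicate {what}: {it!r}")
        seen.add(it)


@dataclass
class ExpressionDataset:
    """A gene x sample matrix of log-scale expression with annotations.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids
    as columns; ``annotations`` (optional) is indexed by sample id and
    carries at least a ``tissue_class`` column, with optional
    ``grade_group`` and ``tumor_fraction`` (in [0, 1]).
    """

    dataset_id: str
    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        genes = [validate_gene_id(str(g)) for g in v.index]
        samples = [str(s) for s in v.columns]
        _check_unique(genes, f"gene id in dataset {self.dataset_id!r}")
        _check_unique(samples, f"sample id in dataset {self.dataset_id!r}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError(
                f"dataset {self.dataset_id!r} contains non-finite or missing values"
            )
        self.values = pd.DataFrame(arr, index=pd.Index(genes, name="gene"),
                                   columns=pd.Index(samples, name="sample"))
        if self.annotations is not None:
            ann = self.annotations.copy()
            ann.index = ann.index.astype(str)
            if "tissue_class" not in ann.columns:
                raise ValueError("annotations must carry a 'tissue_class' column")
            unknown = set(ann["tissue_class"]) - set(TISSUE_CLASSES)
            if unknown:
                raise ValueError(f"unknown tissue classes: {sorted(unknown)}")
            missing = [s for s in samples if s not in ann.index]
            if missing:
                raise ValueError(
                    f"samples without annotation in {self.dataset_id!r}: {missing[:5]}"
                )
            if "tumor_fraction" in ann.columns:
                tf = ann["tumor_fraction"].dropna()
                if ((tf < 0) | (tf > 1)).any():
                    raise ValueError("tumor_fraction must lie in [0, 1]")
            self.annotations = ann.loc[samples]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        samples = list(samples)
        ann = self.annotations.loc[samples] if self.annotations is not None else None
        return ExpressionDataset(self.dataset_id, self.values[samples], ann)


@dataclass
class DatasetCollection:
    """An ordered set of cohorts, one of which is the metabolite-paired anchor."""

    datasets: list[ExpressionDataset]
    anchor_id: str

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("a collection needs at least one dataset")
        _check_unique([d.dataset_id for d in self.datasets], "dataset id")
        if self.anchor_id not in {d.dataset_id for d in self.datasets}:
            raise ValueError(f"anchor_id {self.anchor_id!r} is not a member dataset")

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets]

    @property
    def anchor(self) -> ExpressionDataset:
        return self[self.anchor_id]

    def __getitem__(self, dataset_id: str) -> ExpressionDataset:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)


@dataclass
class MetaboliteTable:
    """Per-sample metabolite concentrations (metabolites x samples, >= 0)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        mets = [str(m) for m in v.index]
        samples = [str(s) for s in v.columns]
        _check_unique(mets, "metabolite name")
        _check_unique(samples, "metabolite-table sample id")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("metabolite table contains non-finite values")
        if (arr < 0).any():
            raise ValueError("metabolite concentrations must be non-negative")
        self.values = pd.DataFrame(arr, index=pd.Index(mets, name="metabolite"),
                                   columns=pd.Index(samples, name="sample"))

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneModule:
    """An ordered gene list; rank order encodes importance.

    ``scores`` (optional) are per-member selection scores and must be
    non-increasing along the rank order.
    """

    name: str
    members: list[str]
    scores: list[float] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.members = [validate_gene_id(str(g)) for g in self.members]
        _check_unique(self.members, f"member of module {self.name!r}")
        if self.scores is not None:
            self.scores = [float(s) for s in self.scores]
            if len(self.scores) != len(self.members):
                raise ValueError("scores and members must have equal length")
            if any(a < b - 1e-12 for a, b in zip(self.scores, self.scores[1:])):
                raise ValueError("scores must be non-increasing in rank order")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


# ---------------------------------------------------------------------------
# expression matrices


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".gct":
        return "gct"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def _check_header_unique(path: Path, sep: str, skip: int = 0) -> None:
    with open(path, "r", encoding="utf-8") as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "sample id in header")


def _read_numeric_table(path: Path, sep: str, skiprows: int = 0) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, skiprows=skiprows,
                     float_precision="round_trip")
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric cell in expression table") from exc
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: missing/ragged cells are not allowed")
    return df


def read_expression_table(path: str | Path, dialect: str | None = None,
                          duplicates: str = "error",
                          dataset_id: str | None = None,
                          annotations: pd.DataFrame | None = None) -> ExpressionDataset:
    """Read a gene x sample expression matrix (TSV, CSV or GCT 1.2).

    First column holds gene ids; the header row holds sample ids.  Duplicate
    gene ids raise unless ``duplicates='highest_mean'``, which keeps, per id,
    the row with the largest mean expression.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        _check_header_unique(path, sep)
        df = _read_numeric_table(path, sep)
    elif dialect == "gct":
        with open(path, "r", encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: GCT header must be '#1.2', got {version!r}")
            dims = fh.readline().strip().split("\t")
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed GCT dims line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        _check_header_unique(path, "\t", skip=2)
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=2,
                         float_precision="round_trip")
        desc_cols = [c for c in df.columns if str(c).lower() == "description"]
        df = df.drop(columns=desc_cols)
        try:
            df = df.apply(pd.to_numeric, errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell in GCT table") from exc
        if df.isna().to_numpy().any():
            raise FormatError(f"{path}: missing cells are not allowed")
        if df.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: GCT declares {n_genes}x{n_samples} but parsed {df.shape}"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.index.has_duplicates:
        if duplicates == "error":
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"{path}: duplicate gene id {dup!r}")
        df = collapse_duplicate_genes(df, policy=duplicates)
    return ExpressionDataset(dataset_id or path.stem, df, annotations)


def write_expression_table(dataset: ExpressionDataset, path: str | Path,
                           dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        dataset.values.to_csv(path, sep="\t", index_label="gene",
                              float_format="%.17g")
    elif dialect == "csv":
        dataset.values.to_csv(path, sep=",", index_label="gene",
                              float_format="%.17g")
    elif dialect == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{dataset.n_genes}\t{dataset.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(dataset.samples) + "\n")
            for gene, row in dataset.values.iterrows():
                cells = "\t".join(repr(float(x)) for x in row.to_numpy())
                fh.write(f"{gene}\tna\t{cells}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def collapse_duplicate_genes(frame: pd.DataFrame,
                             policy: str = "highest_mean") -> pd.DataFrame:
    """Collapse repeated gene ids in a raw parsed table.

    ``highest_mean`` keeps, for each id, the row with the largest mean
    expression across samples (ties: first occurrence); ``error`` raises if
    any id repeats.
    """
    if policy == "error":
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        return frame
    if policy != "highest_mean":
        raise ValueError(f"unknown collapse policy {policy!r}")
    if not frame.index.has_duplicates:
        return frame
    first_seen = frame.index.drop_duplicates()
    means = frame.mean(axis=1).to_numpy()
    # stable sort by descending mean, keep first row per id, restore order
    order = np.argsort(-means, kind="stable")
    best = frame.iloc[order]
    best = best[~best.index.duplicated(keep="first")]
    return best.loc[first_seen]


def gene_universe(collection: DatasetCollection, mode: str = "union") -> list[str]:
    """Genes present in any (``union``) or every (``shared``) dataset.

    Union preserves first-seen order across the collection; shared preserves
    the first dataset's order.
    """
    if mode == "union":
        seen: dict[str, None] = {}
        for ds in collection:
            for g in ds.genes:
                seen.setdefault(g, None)
        return list(seen)
    if mode == "shared":
        others = [set(ds.genes) for ds in collection.datasets[1:]]
        return [g for g in collection.datasets[0].genes
                if all(g in s for s in others)]
    raise ValueError(f"unknown universe mode {mode!r}")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> list[GeneModule]:
    """Read a GMT file: per line, name, description, then member gene ids."""
    modules: list[GeneModule] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, description, members = fields[0], fields[1], fields[2:]
            modules.append(GeneModule(name, members, description=description))
    return modules


def write_gmt(modules: Iterable[GeneModule], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mod in modules:
            desc = mod.description or "na"
            fh.write("\t".join([mod.name, desc, *mod.members]) + "\n")


# ---------------------------------------------------------------------------
# metabolite and annotation tables


def read_metabolite_table(path: str | Path) -> MetaboliteTable:
    """Read a TSV of metabolite rows x sample columns (non-negative)."""
    path = Path(path)
    _check_header_unique(path, "\t")
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric metabolite concentration") from exc
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: missing metabolite values are not allowed")
    return MetaboliteTable(df)


def write_metabolite_table(table: MetaboliteTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="metabolite",
                        float_format="%.17g")


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    return df


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# sample-class filtering

_CLASS_ALIASES: dict[str, tuple[str, ...]] = {
    "cancer": ("cancer_low_grade", "cancer_high_grade"),
    "normal": ("normal",),
    "all": TISSUE_CLASSES,
}


def resolve_class_filter(class_filter: str | Iterable[str] | None) -> tuple[str, ...] | None:
    """Expand a class filter to concrete tissue classes (None = all samples)."""
    if class_filter is None:
        return None
    if isinstance(class_filter, str):
        if class_filter in _CLASS_ALIASES:
            classes = _CLASS_ALIASES[class_filter]
            return None if class_filter == "all" else classes
        if class_filter in TISSUE_CLASSES:
            return (class_filter,)
        raise ValueError(f"unknown tissue class filter {class_filter!r}")
    classes = tuple(class_filter)
    unknown = set(classes) - set(TISSUE_CLASSES)
    if unknown:
        raise ValueError(f"unknown tissue classes: {sorted(unknown)}")
    return classes


def samples_in_class(dataset: ExpressionDataset,
                     class_filter: str | Iterable[str] | None) -> list[str]:
    """Sample ids of ``dataset`` whose tissue class matches the filter."""
    classes = resolve_class_filter(class_filter)
    if classes is None:
        return dataset.samples
    if dataset.annotations is None:
        raise ValueError(
            f"dataset {dataset.dataset_id!r} has no annotations to filter on"
        )
    mask = dataset.annotations["tissue_class"].isin(classes)
    return [s for s in dataset.samples if mask.loc[s]]


# ---------------------------------------------------------------------------
# collection manifest (YAML)


def load_collection(manifest_path: str | Path) -> tuple[DatasetCollection, MetaboliteTable | None]:
    """Load a cohort collection from a YAML manifest.

    Manifest layout::

        anchor: D01
        metabolites: metabolites.tsv      # optional
        datasets:
          - id: D01
            expression: D01_expression.tsv
            annotations: D01_annotations.tsv   # optional

    Relative paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path, "r", encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    datasets = []
    for entry in spec["datasets"]:
        ann = None
        if entry.get("annotations"):
            ann = read_annotations(base / entry["annotations"])
        ds = read_expression_table(base / entry["expression"],
                                   dataset_id=entry["id"], annotations=ann)
        datasets.append(ds)
    collection = DatasetCollection(datasets, anchor_id=spec["anchor"])
    metabolites = None
    if spec.get("metabolites"):
        metabolites = read_metabolite_table(base / spec["metabolites"])
    return collection, metabolites


def write_collection(collection: DatasetCollection, out_dir: str | Path,
                     metabolites: MetaboliteTable | None = None,
                     truth: Mapping | None = None,
                     manifest_name: str = "collection.yaml") -> Path:
    """Serialize a collection (TSV matrices + annotations + manifest) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for ds in collection:
        expr_name = f"{ds.dataset_id}_expression.tsv"
        write_expression_table(ds, out_dir / expr_name)
        entry = {"id": ds.dataset_id, "expression": expr_name}
        if ds.annotations is not None:
            ann_name = f"{ds.dataset_id}_annotations.tsv"
            write_annotations(ds.annotations, out_dir / ann_name)
            entry["annotations"] = ann_name
        entries.append(entry)
    spec: dict = {"anchor": collection.anchor_id, "datasets": entries}
    if metabolites is not None:
        write_metabolite_table(metabolites, out_dir / "metabolites.tsv")
        spec["metabolites"] = "metabolites.tsv"
    manifest = out_dir / manifest_name
    with open(manifest, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)
    if truth is not None:
        with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return manifest
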