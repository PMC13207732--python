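"""Readers, writers, and the aligned per-cohort data container.

All tabular inputs follow cBioPortal-style TSV conventions:

* expression — wide matrix, first column gene identifier, remaining columns
  sample identifiers, linear-scale non-negative abundances;
* mutations — long format with columns ``sample_id``, ``gene``,
  ``variant_class``, one row per somatic call;
* metrics / clinical — one row per sample, first column the sample id.

Gene sets are read from standard GMT files and driver lists from
one-gene-per-line text files.  Downstream modules never touch raw files:
everything is funnelled through :class:`CohortDataset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeneLookupError, ParseError, ValidationError

#: Recognised per-sample metric columns (all but mutation_count optional).
METRIC_COLUMNS = (
    "mutation_count",
    "fga",
    "hrd_score",
    "hypoxia_ragnum",
    "hypoxia_winter",
    "hypoxia_buffa",
)

#: Recognised per-sample clinical columns (all optional).
CLINICAL_COLUMNS = ("t_stage", "grade", "os_time", "os_event", "pfs_time", "pfs_event")

T_STAGE_LEVELS = ("T0", "T1", "T2", "T3", "T4")
GRADE_LEVELS = ("low", "mid", "high")


@dataclass(frozen=True)
class GeneSet:
    """A named, de-duplicated collection of gene identifiers."""

    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CohortDataset:
    """One cohort's expression, mutation, metric, and clinical layers,
    aligned on a master sample list (the expression-matrix columns).

    ``expression`` and ``mutated`` are gene × sample frames; ``metrics`` and
    ``clinical`` are sample × column frames.  ``alterations`` holds optional
    extra binary gene × sample layers (e.g. ``amplification``).
    """

    cohort_id: str
    expression: pd.DataFrame
    mutated: pd.DataFrame
    metrics: pd.DataFrame
    clinical: pd.DataFrame
    alterations: dict = field(default_factory=dict)

    @property
    def samples(self) -> list:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any broken invariant."""
        n_genes, n_samples = self.expression.shape
        if n_samples < 2 or n_genes < 1:
            raise ValidationError(
                f"{self.cohort_id}: expression must have >=2 samples and >=1 gene, "
                f"got {n_genes} x {n_samples}"
            )
        if self.expression.index.has_duplicates:
            raise ValidationError(f"{self.cohort_id}: duplicate gene identifiers")
        master = set(self.samples)
        for name, frame, axis in (
            ("mutated", self.mutated, 1),
            ("metrics", self.metrics, 0),
            ("clinical", self.clinical, 0),
        ):
            ids = frame.columns if axis == 1 else frame.index
            extra = set(ids) - master
            if extra:
                raise ValidationError(
                    f"{self.cohort_id}: {name} has samples outside the master list: "
                    f"{sorted(extra)[:5]}"
                )
        vals = self.expression.to_numpy(float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError(f"{self.cohort_id}: negative expression values")
        if not self.mutated.empty:
            mvals = self.mutated.to_numpy()
            if not np.isin(mvals, (0, 1)).all():
                raise ValidationError(f"{self.cohort_id}: mutation indicator not binary")
        if "mutation_count" in self.metrics:
            mc = self.metrics["mutation_count"].dropna()
            if (mc < 0).any():
                raise ValidationError(f"{self.cohort_id}: negative mutation_count")
        if "fga" in self.metrics:
            fga = self.metrics["fga"].dropna()
            if ((fga < 0) | (fga > 1)).any():
                raise ValidationError(f"{self.cohort_id}: fga outside [0,1]")
        for col in ("os_time", "pfs_time"):
            if col in self.clinical and (self.clinical[col].dropna() < 0).any():
                raise ValidationError(f"{self.cohort_id}: negative {col}")
        for col in ("os_event", "pfs_event"):
            if col in self.clinical:
                ev = self.clinical[col].dropna()
                if not ev.isin((0, 1)).all():
                    raise ValidationError(f"{self.cohort_id}: {col} not in {{0,1}}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_table(path) -> pd.DataFrame:
    """Read a wide gene × sample TSV; empty cells become NaN.

    Raises :class:`ParseError` naming the gene row and sample column of the
    first non-numeric cell, and :class:`ValidationError` on duplicate genes.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene identifiers in {path}: {dupes[:5]}")
    out = {}
    for col in raw.columns:
        cell = raw[col].str.strip()
        numeric = pd.to_numeric(cell.where(cell != "", other=None), errors="coerce")
        bad = numeric.isna() & (cell != "")
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ParseError(
                f"non-numeric cell in {path}: gene {gene!r}, sample {col!r}, "
                f"value {cell[bad].iloc[0]!r}"
            )
        # re-parse through numpy for correctly-rounded (round-trip) floats;
        # pd.to_numeric's fast path can be off by one ulp
        out[col] = cell.replace("", "nan").to_numpy(str).astype(np.float64)
    return pd.DataFrame(out, index=raw.index)


def read_mutation_table(
    path,
    samples: Sequence | None = None,
    gene_universe: Iterable | None = None,
    include_classes: Iterable | None = None,
) -> pd.DataFrame:
    """Read a long-format mutation TSV into a gene × sample 0/1 indicator.

    The indicator is 1 iff at least one (possibly class-filtered) call exists
    for the (gene, sample) pair.  Genes never called anywhere are retained as
    all-zero rows only when listed in ``gene_universe``; their downstream
    status is otherwise "unknown".
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(columns=["sample_id", "gene", "variant_class"])
    required = {"sample_id", "gene"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"mutation table {path} missing columns: {sorted(missing)}")
    if include_classes is not None:
        if "variant_class" not in table.columns:
            raise ValidationError(
                f"mutation table {path} has no variant_class column to filter on"
            )
        table = table[table["variant_class"].isin(set(include_classes))]
    return build_mutation_indicator(
        list(zip(table["sample_id"], table["gene"])),
        samples=samples,
        gene_universe=gene_universe,
    )


def build_mutation_indicator(
    calls: Iterable,
    samples: Sequence | None = None,
    gene_universe: Iterable | None = None,
) -> pd.DataFrame:
    """Build the indicator from (sample_id, gene) pairs; shared by readers."""
    pairs = set(map(tuple, calls))
    sample_list = (
        list(samples) if samples is not None else sorted({s for s, _ in pairs})
    )
    genes = sorted({g for _, g in pairs})
    if gene_universe is not None:
        genes = sorted(set(genes) | set(gene_universe))
    data = np.zeros((len(genes), len(sample_list)), dtype=np.int64)
    gidx = {g: i for i, g in enumerate(genes)}
    sidx = {s: j for j, s in enumerate(sample_list)}
    for s, g in pairs:
        if s in sidx:  # calls for unlisted samples are ignored
            data[gidx[g], sidx[s]] = 1
    return pd.DataFrame(data, index=genes, columns=sample_list)


def _read_sample_table(path, known_columns) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    unknown = set(table.columns) - set(known_columns)
    if unknown:
        warnings.warn(f"{path}: ignoring unrecognised columns {sorted(unknown)}")
        table = table.drop(columns=sorted(unknown))
    return table


def read_metrics_table(path) -> pd.DataFrame:
    """Per-sample metrics TSV (mutation_count, fga, hrd_score, hypoxia_*)."""
    return _read_sample_table(path, METRIC_COLUMNS)


def read_clinical_table(path) -> pd.DataFrame:
    """Per-sample clinical TSV (t_stage, grade, OS/PFS time and event)."""
    return _read_sample_table(path, CLINICAL_COLUMNS)


def read_gene_set_gmt(path, set_name: str) -> GeneSet:
    """Return the named set from a GMT file (name, description, members...)."""
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == set_name:
            members = frozenset(g for g in fields[2:] if g)
            return GeneSet(name=set_name, genes=members)
    raise GeneLookupError(f"gene set {set_name!r} not found in {path}")


def read_all_gene_sets(path) -> dict:
    """Parse every set in a GMT file; used by tests and the CLI."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        sets[fields[0]] = GeneSet(fields[0], frozenset(g for g in fields[2:] if g))
    return sets


def read_driver_list(path) -> list:
    """One gene per line; blank lines and '#' comments ignored; order kept."""
    out = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        gene = line.strip()
        if not gene or gene.startswith("#") or gene in seen:
            continue
        seen.add(gene)
        out.append(gene)
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_cohort(
    expression: pd.DataFrame,
    mutated: pd.DataFrame,
    metrics: pd.DataFrame,
    clinical: pd.DataFrame,
    cohort_id: str,
    alterations: Mapping | None = None,
) -> CohortDataset:
    """Align all components on the expression-matrix sample list.

    Samples absent from the expression matrix are dropped (with a warning);
    samples missing from the other layers get NaN rows.  Raises
    :class:`ValidationError` when fewer than two samples survive.
    """
    master = sorted(expression.columns)
    if len(master) < 2:
        raise ValidationError(f"{cohort_id}: fewer than 2 expression samples")
    expression = expression.sort_index().loc[:, master]

    def _align(frame: pd.DataFrame, name: str, axis: int) -> pd.DataFrame:
        ids = frame.columns if axis == 1 else frame.index
        dropped = sorted(set(ids) - set(master))
        if dropped:
            warnings.warn(
                f"{cohort_id}: dropping {len(dropped)} {name} sample(s) "
                f"absent from expression (e.g. {dropped[:3]})"
            )
        frame = frame.sort_index()
        return frame.reindex(columns=master) if axis == 1 else frame.reindex(master)

    mutated = _align(mutated, "mutation", axis=1).fillna(0).astype(np.int64)
    metrics = _align(metrics, "metrics", axis=0)
    clinical = _align(clinical, "clinical", axis=0)
    extra = {
        name: _align(layer, name, axis=1).fillna(0).astype(np.int64)
        for name, layer in (alterations or {}).items()
    }
    dataset = CohortDataset(
        cohort_id=cohort_id,
        expression=expression,
        mutated=mutated,
        metrics=metrics,
        clinical=clinical,
        alterations=extra,
    )
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# writers / directory layout
# ---------------------------------------------------------------------------

def write_matrix(frame: pd.DataFrame, path, index_label: str = "gene") -> None:
    """Write a wide matrix as TSV; floats use shortest-repr so a write→read
    round trip is bit-exact for decimal-representable values."""
    frame.to_csv(path, sep="\t", index_label=index_label)


def write_table(frame: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a result table with fixed float formatting (determinism)."""
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_cohort_dir(dataset: CohortDataset, directory) -> None:
    """Write one cohort's four layers (plus extra alteration layers) as TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(dataset.expression, directory / "expression.tsv")
    long = dataset.mutated.stack()
    long = long[long == 1]
    calls = pd.DataFrame(
        {
            "sample_id": long.index.get_level_values(1),
            "gene": long.index.get_level_values(0),
            "variant_class": "missense",
        }
    ).sort_values(["sample_id", "gene"], kind="stable")
    calls.to_csv(directory / "mutations.tsv", sep="\t", index=False)
    (directory / "mutation_genes.txt").write_text(
        "".join(f"{g}\n" for g in dataset.mutated.index)
    )
    dataset.metrics.to_csv(directory / "metrics.tsv", sep="\t", index_label="sample_id")
    dataset.clinical.to_csv(directory / "clinical.tsv", sep="\t", index_label="sample_id")
    for name, layer in dataset.alterations.items():
        write_matrix(layer, directory / f"{name}.tsv")


def load_cohort_dir(directory, cohort_id: str) -> CohortDataset:
    """Inverse of :func:`write_cohort_dir`."""
    directory = Path(directory)
    expression = read_expression_table(directory / "expression.tsv")
    universe_path = directory / "mutation_genes.txt"
    universe = read_driver_list(universe_path) if universe_path.exists() else None
    mutated = read_mutation_table(
        directory / "mutations.tsv",
        samples=list(expression.columns),
        gene_universe=universe,
    )
    metrics = read_metrics_table(directory / "metrics.tsv")
    clinical = read_clinical_table(directory / "clinical.tsv")
    alterations = {
        extra.stem: read_expression_table(extra).fillna(0).astype(np.int64)
        for extra in sorted(directory.glob("*.tsv"))
        if extra.stem not in {"expression", "mutations", "metrics", "clinical"}
    }
    return assemble_cohort(
        expression, mutated, metrics, clinical, cohort_id, alterations=alterations
    )
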