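"""Core data containers and file I/O for gene-level RNA-seq analysis.

The analysis works on four kinds of objects:

* :class:`CountMatrix` — raw integer read counts, genes x samples, with a
  condition/replicate design attached to every sample.
* :class:`GeneAnnotation` — per-gene covariates: principal-transcript length
  in base pairs and (optionally) GC fraction.
* :class:`ExpressionMatrix` — normalized expression on an explicit scale
  (``linear`` or ``log2``).
* :class:`FoldChangeTable` — per-gene log2 fold change and mean abundance for
  one labeled comparison.
* :class:`GeneSetCollection` — named gene-id sets (GMT format).

All file formats are plain tab-separated text; see the reader docstrings for
the exact dialects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lenbias")

__all__ = [
    "CountMatrix",
    "GeneAnnotation",
    "ExpressionMatrix",
    "FoldChangeTable",
    "GeneSetCollection",
    "read_counts",
    "read_annotation",
    "read_gmt",
    "lengths_from_gtf",
    "filter_expressed",
    "log2_fold_change",
    "write_counts",
    "write_fold_change",
    "write_annotation",
    "write_gmt",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with a sample design.

    Parameters
    ----------
    counts
        DataFrame with gene ids as index and sample ids as columns; entries
        must be nonnegative integers.
    condition_of
        Series mapping sample id -> condition label; must cover every sample.
    replicate_of
        Series mapping sample id -> positive replicate index, unique within
        each condition.
    """

    counts: pd.DataFrame
    condition_of: pd.Series
    replicate_of: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(~np.isfinite(values)):
            raise ValueError("counts contain non-finite entries")
        if np.any(values < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(values != np.floor(values)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.condition_of = pd.Series(self.condition_of)
        self.replicate_of = pd.Series(self.replicate_of).astype(int)
        for s in self.counts.columns:
            if s not in self.condition_of.index:
                raise ValueError(f"sample {s!r} missing from design")
            if s not in self.replicate_of.index:
                raise ValueError(f"sample {s!r} has no replicate index")
        self.condition_of = self.condition_of.loc[self.counts.columns]
        self.replicate_of = self.replicate_of.loc[self.counts.columns]
        if (self.replicate_of <= 0).any():
            raise ValueError("replicate indices must be positive")
        for cond, grp in self.replicate_of.groupby(self.condition_of):
            if grp.duplicated().any():
                raise ValueError(
                    f"replicate indices not unique within condition {cond!r}"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total counts N_s (column sums)."""
        return self.counts.sum(axis=0)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.condition_of:
            seen.setdefault(c, None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of[s] == condition]

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(gene_ids)], self.condition_of, self.replicate_of
        )


@dataclass
class GeneAnnotation:
    """Per-gene covariate table: transcript length (bp) and GC fraction.

    ``table`` is indexed by gene id with columns ``length_bp`` (positive
    integer) and ``gc_fraction`` (float in [0, 1], NaN when unknown).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate gene id in annotation: {dup!r}")
        if "length_bp" not in self.table.columns:
            raise ValueError("annotation requires a length_bp column")
        if "gc_fraction" not in self.table.columns:
            self.table = self.table.assign(gc_fraction=np.nan)
        lengths = self.table["length_bp"]
        if lengths.isna().any() or (lengths < 1).any():
            bad = self.table.index[lengths.isna() | (lengths < 1)][0]
            raise ValueError(f"gene {bad!r}: length_bp must be >= 1")
        self.table["length_bp"] = lengths.astype(np.int64)
        gc = self.table["gc_fraction"].astype(float)
        bad_gc = gc.notna() & ((gc < 0) | (gc > 1))
        if bad_gc.any():
            raise ValueError(
                f"gene {self.table.index[bad_gc][0]!r}: gc_fraction outside [0, 1]"
            )
        self.table["gc_fraction"] = gc

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def lengths(self, gene_ids: Sequence[str] | None = None) -> pd.Series:
        s = self.table["length_bp"]
        return s if gene_ids is None else s.loc[list(gene_ids)]

    def gc(self, gene_ids: Sequence[str] | None = None) -> pd.Series:
        s = self.table["gc_fraction"]
        return s if gene_ids is None else s.loc[list(gene_ids)]

    def has_gc(self) -> bool:
        return bool(self.table["gc_fraction"].notna().all())


@dataclass
class ExpressionMatrix:
    """Real-valued expression matrix on an explicit scale.

    ``scale`` is ``"linear"`` (nonnegative normalized abundance, e.g. RPKM)
    or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        arr = self.values.to_numpy(float)
        if np.any(~np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and np.any(arr < 0):
            raise ValueError("linear-scale expression must be nonnegative")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold change for one comparison.

    ``table`` is indexed by gene id with columns ``log2_fc`` and
    ``mean_abundance`` (mean linear abundance over both groups).
    """

    table: pd.DataFrame
    comparison_label: str

    def __post_init__(self) -> None:
        for col in ("log2_fc", "mean_abundance"):
            if col not in self.table.columns:
                raise ValueError(f"fold-change table requires column {col!r}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate gene id in fold-change table")
        if np.any(~np.isfinite(self.table["log2_fc"].to_numpy(float))):
            raise ValueError("log2_fc must be finite (check the pseudocount)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def log2_fc(self) -> pd.Series:
        return self.table["log2_fc"]


class GeneSetCollection:
    """Ordered mapping set name -> tuple of unique member gene ids."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, tuple[str, ...]] = {}
        self.descriptions: dict[str, str] = {}
        for name, members in sets.items():
            uniq = tuple(dict.fromkeys(members))
            if not uniq:
                raise ValueError(f"gene set {name!r} is empty")
            if name in self._sets:
                raise ValueError(f"duplicate set name: {name!r}")
            self._sets[name] = uniq
            if descriptions and name in descriptions:
                self.descriptions[name] = descriptions[name]

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self._sets[name]

    def items(self):
        return self._sets.items()

    def names(self) -> list[str]:
        return list(self._sets)


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a tab-separated counts file plus a design file.

    The counts file has a header row of sample ids and a first column named
    ``gene_id``. The design file has columns ``sample_id``, ``condition`` and
    optionally ``replicate``; when ``replicate`` is absent, replicates are
    numbered in file order within each condition.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", dtype={0: str})
    if "sample_id" not in design.columns or "condition" not in design.columns:
        raise ValueError("design file requires sample_id and condition columns")
    design = design.set_index("sample_id")
    if "replicate" not in design.columns:
        design["replicate"] = design.groupby("condition").cumcount() + 1
    for s in df.columns:
        if s not in design.index:
            raise ValueError(f"sample {s!r} missing from design")
    return CountMatrix(
        df,
        design["condition"].astype(str),
        design["replicate"].astype(int),
    )


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a tab-separated annotation: gene_id, length_bp[, gc_fraction]."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneAnnotation(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member ids."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"duplicate set name: {name!r}")
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_counts(cm: CountMatrix, counts_path: str | Path, design_path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    design = pd.DataFrame(
        {
            "sample_id": cm.sample_ids,
            "condition": cm.condition_of.to_numpy(),
            "replicate": cm.replicate_of.to_numpy(),
        }
    )
    design.to_csv(design_path, sep="\t", index=False)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    out = ann.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_fold_change(fc: FoldChangeTable, path: str | Path) -> None:
    out = fc.table[["log2_fc", "mean_abundance"]].copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = sets.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# GTF principal-transcript lengths


def _gtf_attributes(attr_field: str) -> dict[str, list[str]]:
    """Parse a GENCODE-style GTF attribute field into key -> list of values."""
    out: dict[str, list[str]] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out.setdefault(key, []).append(value.strip().strip('"'))
    return out


def _appris_rank(tags: Iterable[str]) -> int | None:
    """Numeric rank of an APPRIS principal tag (1 best); None when absent."""
    best: int | None = None
    for tag in tags:
        if tag.startswith("appris_principal"):
            suffix = tag[len("appris_principal"):].lstrip("_")
            rank = int(suffix) if suffix.isdigit() else 1
            if best is None or rank < best:
                best = rank
    return best


def lengths_from_gtf(gtf_path: str | Path) -> GeneAnnotation:
    """Derive per-gene principal-transcript lengths from a GENCODE GTF.

    Gene length is the exonic length (sum of ``end - start + 1`` over exons)
    of the transcript carrying an APPRIS ``appris_principal`` tag (lowest
    rank wins); when no transcript is tagged, the longest transcript is used.
    Ties break by longest exonic length, then lexicographically smallest
    transcript id. GC fraction is left missing. Genes without exon records
    are skipped with a warning.
    """
    exon_len: dict[str, int] = {}
    tx_gene: dict[str, str] = {}
    tx_rank: dict[str, int] = {}
    genes_seen: dict[str, None] = {}
    with open(gtf_path, encoding="utf-8") as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            feature, start, end, attrs = fields[2], fields[3], fields[4], fields[8]
            if feature not in ("gene", "transcript", "exon"):
                continue
            parsed = _gtf_attributes(attrs)
            gene_id = parsed.get("gene_id", [None])[0]
            if gene_id is None:
                continue
            if feature == "gene":
                genes_seen.setdefault(gene_id, None)
                continue
            tx_id = parsed.get("transcript_id", [None])[0]
            if tx_id is None:
                continue
            genes_seen.setdefault(gene_id, None)
            tx_gene[tx_id] = gene_id
            rank = _appris_rank(parsed.get("tag", []))
            if rank is not None:
                prev = tx_rank.get(tx_id)
                tx_rank[tx_id] = rank if prev is None else min(prev, rank)
            if feature == "exon":
                exon_len[tx_id] = exon_len.get(tx_id, 0) + int(end) - int(start) + 1

    per_gene: dict[str, list[tuple[str, int, int | None]]] = {}
    for tx_id, length in exon_len.items():
        per_gene.setdefault(tx_gene[tx_id], []).append(
            (tx_id, length, tx_rank.get(tx_id))
        )

    rows: dict[str, int] = {}
    for gene_id in genes_seen:
        candidates = per_gene.get(gene_id)
        if not candidates:
            logger.warning("gene %s has no exon records; skipped", gene_id)
            continue
        principal = [c for c in candidates if c[2] is not None]
        pool = principal or candidates
        if principal:
            best_rank = min(c[2] for c in principal)
            pool = [c for c in principal if c[2] == best_rank]
        # longest first, then lexicographically smallest transcript id
        pool = sorted(pool, key=lambda c: (-c[1], c[0]))
        rows[gene_id] = pool[0][1]

    table = pd.DataFrame(
        {"length_bp": pd.Series(rows, dtype=np.int64), "gc_fraction": np.nan}
    )
    return GeneAnnotation(table)


# ---------------------------------------------------------------------------
# filtering and fold change


def cpm_values(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million for every gene and sample (no filtering)."""
    libs = cm.library_sizes
    if (libs == 0).any():
        raise ValueError("zero library size")
    return cm.counts * 1e6 / libs


def filter_expressed(cm: CountMatrix, cpm_threshold: float = 1.0) -> CountMatrix:
    """Keep genes expressed at >= ``cpm_threshold`` cpm in every replicate of
    at least one condition; row order is preserved."""
    if cpm_threshold <= 0:
        raise ValueError("cpm_threshold must be positive")
    cpm = cpm_values(cm)
    keep = np.zeros(len(cm.gene_ids), dtype=bool)
    for cond in cm.conditions():
        samples = cm.samples_of(cond)
        keep |= (cpm[samples] >= cpm_threshold).all(axis=1).to_numpy()
    if not keep.any():
        raise ValueError(
            "no gene passes the expression filter; review cpm_threshold"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("expression filter removed %d genes", dropped)
    return CountMatrix(cm.counts.loc[keep], cm.condition_of, cm.replicate_of)


def log2_fold_change(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
    comparison_label: str | None = None,
) -> FoldChangeTable:
    """log2((mean_a + pseudocount) / (mean_b + pseudocount)) per gene.

    ``expr`` must be on the linear scale. Groups must be non-empty, disjoint
    and drawn from the matrix samples; single-sample groups give a
    replicate-vs-replicate comparison.
    """
    if expr.scale != "linear":
        raise ValueError("log2_fold_change requires a linear-scale matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    for s in (*group_a, *group_b):
        if s not in expr.sample_ids:
            raise ValueError(f"unknown sample id: {s!r}")
    mean_a = expr.values[group_a].mean(axis=1)
    mean_b = expr.values[group_b].mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    mean_ab = expr.values[group_a + group_b].mean(axis=1)
    label = comparison_label or f"{'+'.join(group_a)}_vs_{'+'.join(group_b)}"
    return FoldChangeTable(
        pd.DataFrame({"log2_fc": lfc, "mean_abundance": mean_ab}), label
    )


def align_to_annotation(
    cm: CountMatrix, ann: GeneAnnotation
) -> tuple[CountMatrix, int]:
    """Drop counted genes absent from the annotation (they cannot enter any
    length analysis); returns the reduced matrix and the number dropped."""
    keep = [g for g in cm.gene_ids if g in ann.table.index]
    dropped = len(cm.gene_ids) - len(keep)
    if dropped:
        logger.warning("%d genes absent from annotation were dropped", dropped)
    if not keep:
        raise ValueError("no counted gene is present in the annotation")
    return cm.subset_genes(keep), dropped
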