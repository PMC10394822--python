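"""Domain types and file I/O for the pipeline.

Every other module consumes only the typed containers defined here.  All
tabular formats are plain TSV (UTF-8, '.' decimal point); matrices are laid
out probes/genes as rows and samples as columns unless ``transposed=True``.

Genomic coordinates are 0-based half-open internally and on disk (DMR tables,
gene models, promoter windows); 1-based inputs must be converted at the
boundary by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError

logger = logging.getLogger("cimpkit")

#: Closed vocabulary for the probe-to-TSS relation.
TSS_RELATIONS = ("TSS200", "TSS1500", "Body", "other")

#: Valid CIMP group labels (low / intermediate / high methylator phenotype).
CIMP_GROUPS = ("lCIMP", "iCIMP", "hCIMP", "unknown")

#: Declared expression scales.
EXPRESSION_SCALES = ("counts", "rpkm", "log2")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Methylation β-values (methylated fraction per probe), probes × samples.

    Missing values are NaN and are preserved as missing — no imputation is
    performed at read time; downstream operations state their own
    missing-data policy.
    """

    values: pd.DataFrame  # index: probe ids, columns: sample ids, float64

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValidationError("duplicate probe ids in beta matrix")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in beta matrix")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"beta value out of [0,1] for probe {v.index[i]!r}, "
                f"sample {v.columns[j]!r}: {arr[i, j]}"
            )
        self.values = v.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class ProbeAnnotation:
    """Per-probe annotation: gene assignment and relation to the TSS."""

    table: pd.DataFrame  # index probe_id; gene_symbol, tss_relation, chrom, pos, strand

    REQUIRED = ("gene_symbol", "tss_relation", "chrom", "pos", "strand")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"probe annotation missing columns: {missing}")
        if t.index.has_duplicates:
            raise ValidationError("duplicate probe ids in annotation")
        bad = set(t["tss_relation"]) - set(TSS_RELATIONS)
        if bad:
            raise ValidationError(f"unknown tss_relation values: {sorted(bad)}")

    def probes_in_categories(self, categories: Iterable[str]) -> pd.Index:
        cats = set(categories)
        return self.table.index[self.table["tss_relation"].isin(cats)]


@dataclass
class ExpressionMatrix:
    """Gene expression, genes × samples, with a declared scale.

    ``scale`` is one of ``counts`` (non-negative raw/normalized counts),
    ``rpkm`` (non-negative length-normalized values) or ``log2`` (already
    log2(x+1)-transformed).
    """

    values: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise ValidationError(f"unknown expression scale {self.scale!r}")
        v = self.values
        if v.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        if self.scale != "log2":
            arr = v.to_numpy(dtype=float)
            if np.any((arr < 0) & ~np.isnan(arr)):
                raise ValidationError(
                    f"negative expression on scale {self.scale!r}"
                )
        self.values = v.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_log2(self) -> pd.DataFrame:
        """Return the matrix on the log2(x+1) scale (identity if already log2)."""
        if self.scale == "log2":
            return self.values
        return np.log2(self.values + 1.0)


@dataclass
class SampleMetadata:
    """Per-sample clinical covariates.

    Columns: ``cimp_group`` (lCIMP/iCIMP/hCIMP/unknown), ``purity`` (tumor
    cell fraction in [0,1]), ``mitotic_rate`` (mitoses per 50 high-power
    fields), ``survival_time`` (days), ``event`` (1 = death observed,
    0 = censored).  Any field may be missing (NaN).
    """

    table: pd.DataFrame  # index sample_id

    COLUMNS = ("cimp_group", "purity", "mitotic_rate", "survival_time", "event")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        for col in self.COLUMNS:
            if col not in t.columns:
                t[col] = np.nan
        groups = t["cimp_group"].dropna()
        bad = set(groups) - set(CIMP_GROUPS)
        if bad:
            raise ValidationError(f"unknown CIMP group labels: {sorted(bad)}")
        purity = t["purity"].dropna()
        if ((purity < 0) | (purity > 1)).any():
            raise ValidationError("purity outside [0,1]")
        ev = t["event"].dropna()
        if not set(ev.astype(float)) <= {0.0, 1.0}:
            raise ValidationError("event indicator must be 0 or 1")
        st = t["survival_time"].dropna()
        if (st <= 0).any():
            raise ValidationError("survival_time must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in_group(self, group: str) -> list[str]:
        t = self.table
        return list(t.index[t["cimp_group"] == group])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, genes)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} contains duplicates")

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[str]]) -> "GeneSetCollection":
        return cls({name: ("", tuple(dict.fromkeys(genes))) for name, genes in d.items()})

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def items(self):
        for name, (_, genes) in self.sets.items():
            yield name, genes


@dataclass
class DMRTable:
    """Differentially methylated regions: 0-based half-open intervals.

    ``delta_beta`` is the signed methylation difference (convention
    documented by the producing stage; for the demethylation experiment it
    is control − treated, so demethylation under treatment is positive).
    """

    table: pd.DataFrame  # chrom, start, end, delta_beta, p_value

    REQUIRED = ("chrom", "start", "end", "delta_beta", "p_value")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"DMR table missing columns: {missing}")
        if (t["start"] >= t["end"]).any():
            row = t[t["start"] >= t["end"]].iloc[0]
            raise ValidationError(
                f"DMR with start >= end: {row['chrom']}:{row['start']}-{row['end']}"
            )
        p = t["p_value"]
        if ((p <= 0) | (p > 1)).any():
            raise ValidationError("DMR p_value outside (0,1]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DETable:
    """Per-gene differential expression records."""

    table: pd.DataFrame  # index gene_id; log2_fold_change, p_value, fdr

    REQUIRED = ("log2_fold_change", "p_value", "fdr")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"DE table missing columns: {missing}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id in DE table: {dup!r}")
        for col in ("p_value", "fdr"):
            v = t[col]
            if ((v <= 0) | (v > 1)).any():
                raise ValidationError(f"DE {col} outside (0,1]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneModelTable:
    """One TSS and gene-body interval per gene (0-based half-open body)."""

    table: pd.DataFrame  # index gene_id; chrom, tss, strand, body_start, body_end

    REQUIRED = ("chrom", "tss", "strand", "body_start", "body_end")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"gene model table missing columns: {missing}")
        if t.index.has_duplicates:
            raise ValidationError("duplicate gene ids in gene model table")
        if not set(t["strand"]) <= {"+", "-"}:
            raise ValidationError("strand must be '+' or '-'")
        if (t["body_start"] >= t["body_end"]).any():
            raise ValidationError("gene body with body_start >= body_end")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", encoding="utf-8", **kwargs)
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    return df


def read_beta_matrix(
    path: str | Path,
    missing_token: str = "NA",
    transposed: bool = False,
) -> BetaMatrix:
    """Read a β-value matrix TSV (probe rows, sample columns).

    ``missing_token`` cells become NaN and stay missing.  With
    ``transposed=True`` the file has samples as rows.
    """
    df = _read_tsv(path, index_col=0, na_values=[missing_token], keep_default_na=False)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric beta value ({exc})") from exc
    if transposed:
        df = df.T
    df.index = df.index.astype(str)
    n_in = df.shape[0]
    bm = BetaMatrix(df)
    logger.info("read_beta_matrix: %s -> %d probes x %d samples (%d missing cells)",
                path, n_in, df.shape[1], bm.n_missing)
    return bm


def read_expression_matrix(
    path: str | Path,
    scale: str = "counts",
    missing_token: str = "NA",
    transposed: bool = False,
) -> ExpressionMatrix:
    df = _read_tsv(path, index_col=0, na_values=[missing_token], keep_default_na=False)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    if transposed:
        df = df.T
    df.index = df.index.astype(str)
    em = ExpressionMatrix(df, scale=scale)
    logger.info("read_expression_matrix: %s -> %d genes x %d samples (scale=%s)",
                path, *df.shape, scale)
    return em


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = _read_tsv(path)
    if "probe_id" not in df.columns:
        raise ParseError(f"{path}: missing 'probe_id' column")
    df = df.set_index("probe_id")
    df.index = df.index.astype(str)
    return ProbeAnnotation(df)


def read_metadata(path: str | Path, missing_token: str = "NA") -> SampleMetadata:
    df = _read_tsv(path, na_values=[missing_token], keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    for col in ("purity", "mitotic_rate", "survival_time", "event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleMetadata(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (name, description, tab-separated genes).

    Duplicate genes within one line are deduplicated (first occurrence kept);
    duplicate set names are an error.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def read_dmr_table(path: str | Path) -> DMRTable:
    """Read a DMR TSV: chrom, start, end, delta_beta, p_value (0-based half-open)."""
    df = _read_tsv(path)
    missing = [c for c in DMRTable.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return DMRTable(df)


def read_de_table(path: str | Path) -> DETable:
    df = _read_tsv(path)
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing 'gene_id' column")
    missing = [c for c in DETable.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df.set_index("gene_id")
    df.index = df.index.astype(str)
    return DETable(df)


def read_gene_models(path: str | Path) -> GeneModelTable:
    """Read a BED-like gene model TSV: chrom, body_start, body_end, gene_id, strand, tss."""
    df = _read_tsv(path)
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing 'gene_id' column")
    df = df.set_index("gene_id")
    df.index = df.index.astype(str)
    missing = [c for c in GeneModelTable.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("tss", "body_start", "body_end"):
        df[col] = df[col].astype(int)
    return GeneModelTable(df)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

#: Number of decimals kept when writing float matrices; round-trips are exact
#: at this precision.
FLOAT_PRECISION = 10
_FLOAT_FMT = f"%.{FLOAT_PRECISION}g"


def write_beta_matrix(bm: BetaMatrix, path: str | Path, missing_token: str = "NA") -> None:
    bm.values.to_csv(path, sep="\t", index_label="probe_id",
                     na_rep=missing_token, float_format=_FLOAT_FMT)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path,
                            missing_token: str = "NA") -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id",
                     na_rep=missing_token, float_format=_FLOAT_FMT)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="probe_id")


def write_metadata(md: SampleMetadata, path: str | Path, missing_token: str = "NA") -> None:
    md.table.to_csv(path, sep="\t", index_label="sample_id",
                    na_rep=missing_token, float_format=_FLOAT_FMT)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in gsc.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_dmr_table(dmrs: DMRTable, path: str | Path) -> None:
    dmrs.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_de_table(de: DETable, path: str | Path) -> None:
    de.table.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def write_gene_models(gm: GeneModelTable, path: str | Path) -> None:
    cols = ["chrom", "body_start", "body_end", "strand", "tss"]
    gm.table[cols].to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON configuration file into a plain dict of stage blocks."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: top-level config must be a mapping")
    return cfg
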