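"""Domain types and file I/O for expression matrices, gene signatures and
clinical tables.

Expression matrices are gene-by-sample tables (TSV/CSV, first column
``gene``), optionally paired with a per-sample annotation CSV keyed by
``sample_id``.  Signatures are read from GMT files, with up/down-regulated
arm pairs encoded as two lines named ``<name>_UP`` and ``<name>_DN``.
Gene identifiers are matched case-insensitively after whitespace stripping;
no alias or ortholog mapping is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "Signature",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "read_muscle_fat",
    "match_signature",
    "compute_llff",
]

RAW_COUNTS = "raw_counts"
LOG_NORMALIZED = "log_normalized"

#: annotation columns understood by the pipeline; only ``group`` is mandatory
ANNOTATION_COLUMNS = ("cohort", "tissue", "tirm", "group", "subject_id")

CLINICAL_RANGES = {
    "ricci": (0.0, 10.0),
    "lamperti": (0.0, 15.0),
    "mrc_sum": (0.0, 60.0),
    "llff": (0.0, 100.0),
}


@dataclass
class ExpressionMatrix:
    """A gene-by-sample expression matrix with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame of shape (genes, samples); index holds unique gene
        symbols, columns unique sample identifiers.
    scale
        ``"raw_counts"`` (non-negative) or ``"log_normalized"``.
    samples
        Optional per-sample annotation frame indexed by sample id.
        Recognised columns: cohort, tissue, tirm (neg/pos/na),
        group (fshd/control), subject_id.
    """

    values: pd.DataFrame
    scale: str = LOG_NORMALIZED
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in (RAW_COUNTS, LOG_NORMALIZED):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if self.scale == RAW_COUNTS and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")
        if self.samples is not None:
            missing = [s for s in self.values.columns if s not in self.samples.index]
            if missing:
                raise ValueError(f"samples missing annotation: {missing}")
            self.samples = self.samples.loc[self.values.columns]
            if "group" not in self.samples.columns or self.samples["group"].isna().any():
                raise ValueError("every annotated sample needs a group label")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ann = self.samples.loc[list(sample_ids)] if self.samples is not None else None
        return ExpressionMatrix(self.values[list(sample_ids)], self.scale, ann)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, scale or self.scale, self.samples)


@dataclass(frozen=True)
class Signature:
    """A named gene signature with up- and (optionally) down-regulated arms.

    ``down_genes`` may be empty, in which case the signature is scored by
    the mean expression of ``up_genes``; two-armed signatures are scored as
    a single-sample t-statistic contrasting the arms.
    """

    name: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        up, dn = set(self.up_genes), set(self.down_genes)
        if len(up) != len(self.up_genes) or len(dn) != len(self.down_genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes within an arm")
        shared = up & dn
        if shared:
            raise ValueError(
                f"signature {self.name!r}: genes in both arms: {sorted(shared)}"
            )
        if not up and not dn:
            raise ValueError(f"signature {self.name!r} is empty")

    @property
    def two_armed(self) -> bool:
        return len(self.down_genes) > 0

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def _sep_for(path: str) -> str:
    p = str(path)
    if p.endswith(".gz"):
        p = p[:-3]
    return "," if p.endswith(".csv") else "\t"


def read_expression(path, scale: str = LOG_NORMALIZED, annotations=None) -> ExpressionMatrix:
    """Read a gene-by-sample expression table, optionally with annotations.

    The first column holds gene symbols; the header row holds sample ids.
    Duplicate gene rows are collapsed by their arithmetic mean (on the
    stored scale) with a warning.  A non-numeric cell raises with its
    coordinates; a sample without an annotation row raises naming it.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str).str.strip()

    bad = df.apply(pd.to_numeric, errors="coerce")
    nonnum = bad.isna() & df.notna()
    if nonnum.to_numpy().any():
        g = df.index[nonnum.any(axis=1)][0]
        s = df.columns[nonnum.loc[g]][0]
        raise ValueError(
            f"non-numeric expression value at gene {g!r}, sample {s!r}: {df.loc[g, s]!r}"
        )
    df = bad.astype(float)

    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        warnings.warn(f"collapsing duplicate gene rows by mean: {dups}")
        df = df.groupby(level=0, sort=False).mean()

    ann = None
    if annotations is not None:
        ann = pd.read_csv(annotations).set_index("sample_id")
        orphans = [s for s in df.columns if s not in ann.index]
        if orphans:
            raise ValueError(f"annotation file lacks rows for samples: {orphans}")
    return ExpressionMatrix(df, scale=scale, samples=ann)


def write_expression(em: ExpressionMatrix, path, annotations_path=None) -> None:
    """Write the matrix (and annotations, if any) back to disk; round-trips
    with :func:`read_expression` to full float precision."""
    out = em.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=_sep_for(path), float_format="%.17g")
    if annotations_path is not None:
        if em.samples is None:
            raise ValueError("matrix carries no annotations to write")
        ann = em.samples.copy()
        ann.index.name = "sample_id"
        ann.to_csv(annotations_path)


def read_gmt(path) -> list[Signature]:
    """Parse a GMT file into signatures, pairing ``_UP``/``_DN`` lines.

    Lines named ``<sig>_UP`` and ``<sig>_DN`` are merged into one two-armed
    signature; an unpaired line becomes a single-arm (mean-type) signature.
    """
    raw: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {line[:60]!r}")
            name = fields[0].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if name in raw:
                raise ValueError(f"duplicate GMT set name {name!r}")
            raw[name] = genes
            order.append(name)

    sigs: list[Signature] = []
    consumed: set[str] = set()
    for name in order:
        if name in consumed:
            continue
        if name.endswith("_UP") and name[:-3] + "_DN" in raw:
            base = name[:-3]
            sigs.append(Signature(base, tuple(raw[name]), tuple(raw[base + "_DN"])))
            consumed.update({name, base + "_DN"})
        elif name.endswith("_DN") and name[:-3] + "_UP" in raw:
            base = name[:-3]
            sigs.append(Signature(base, tuple(raw[base + "_UP"]), tuple(raw[name])))
            consumed.update({name, base + "_UP"})
        else:
            sigs.append(Signature(name, tuple(raw[name])))
            consumed.add(name)
    return sigs


def write_gmt(sigs: list[Signature], path, description: str = "fshdmbb") -> None:
    """Write signatures as GMT; two-armed ones become ``_UP``/``_DN`` line pairs."""
    with open(path, "w") as fh:
        for sig in sigs:
            if sig.two_armed:
                fh.write("\t".join([f"{sig.name}_UP", description, *sig.up_genes]) + "\n")
                fh.write("\t".join([f"{sig.name}_DN", description, *sig.down_genes]) + "\n")
            else:
                fh.write("\t".join([sig.name, description, *sig.up_genes]) + "\n")


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a subject-level clinical table.

    Expected columns (any subset): subject_id, age_years, sex (M/F),
    ricci (0-10), lamperti (0-15), mrc_sum (0-60), mvc_ta, llff (%),
    d4z4_units (FSHD1 only), duration_years, fshd_type
    (fshd1/fshd2/control).  Missing values stay explicit (NaN) and are
    deleted case-wise by each downstream analysis.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("clinical table needs a subject_id column")
    validate_clinical(df)
    return df


def validate_clinical(df: pd.DataFrame) -> None:
    for col, (lo, hi) in CLINICAL_RANGES.items():
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.dropna()[(vals.dropna() < lo) | (vals.dropna() > hi)]
            if len(bad):
                raise ValueError(f"{col} outside [{lo}, {hi}]: {bad.tolist()}")
    if "d4z4_units" in df.columns and "fshd_type" in df.columns:
        off = df["d4z4_units"].notna() & (df["fshd_type"] != "fshd1")
        if off.any():
            raise ValueError(
                "d4z4_units present for non-FSHD1 subjects: "
                f"{df.loc[off, 'subject_id'].tolist()}"
            )


def read_muscle_fat(path) -> pd.DataFrame:
    """Read a per-subject per-muscle fat-fraction table
    (subject_id, muscle, fat_fraction, area)."""
    df = pd.read_csv(path)
    need = {"subject_id", "fat_fraction", "area"}
    if not need <= set(df.columns):
        raise ValueError(f"muscle fat table needs columns {sorted(need)}")
    if ((df["fat_fraction"] < 0) | (df["fat_fraction"] > 100)).any():
        raise ValueError("fat_fraction outside [0, 100]")
    if (df["area"] <= 0).any():
        raise ValueError("muscle areas must be positive")
    return df


def compute_llff(fat: pd.DataFrame) -> pd.Series:
    """Area-weighted lower-limb fat fraction per subject.

    LLFF_s = sum_m(area_m * ff_m) / sum_m(area_m), in percent.  Invariant
    under rescaling all areas by a positive constant.
    """
    if ((fat["fat_fraction"] < 0) | (fat["fat_fraction"] > 100)).any():
        raise ValueError("fat_fraction outside [0, 100]")
    if (fat["area"] <= 0).any():
        raise ValueError("muscle areas must be positive")

    def _wmean(g: pd.DataFrame) -> float:
        total = g["area"].sum()
        if total <= 0:
            raise ValueError("zero total muscle area")
        return float((g["area"] * g["fat_fraction"]).sum() / total)

    out = fat.groupby("subject_id", sort=False).apply(_wmean, include_groups=False)
    out.name = "llff"
    return out


def match_signature(sig: Signature, em: ExpressionMatrix) -> tuple[Signature, dict]:
    """Restrict a signature to genes measured in the matrix.

    Matching is case-insensitive after whitespace stripping.  Returns the
    restricted signature (gene ids as spelled in the matrix) and a coverage
    report with the fraction of each arm found; warns below 0.8 coverage.
    For two-armed signatures, an arm restricted below 2 genes raises, since
    the t-statistic needs a variance per arm.
    """
    lookup: dict[str, str] = {}
    for g in em.values.index:
        lookup.setdefault(str(g).strip().lower(), g)

    def _restrict(genes: tuple[str, ...]) -> tuple[list[str], float]:
        found = [lookup[k] for g in genes if (k := str(g).strip().lower()) in lookup]
        cov = len(found) / len(genes) if genes else 1.0
        return found, cov

    up, cov_up = _restrict(sig.up_genes)
    dn, cov_dn = _restrict(sig.down_genes)

    for arm, cov in (("up", cov_up), ("down", cov_dn)):
        if cov < 0.8:
            warnings.warn(
                f"signature {sig.name!r}: only {cov:.0%} of the {arm} arm is measured"
            )
    if sig.two_armed and (len(up) < 2 or len(dn) < 2):
        raise ValueError(
            f"signature {sig.name!r}: restricted arm too small for t-statistic "
            f"scoring (up={len(up)}, down={len(dn)}; need >= 2 per arm)"
        )
    if not sig.two_armed and len(up) == 0:
        raise ValueError(f"signature {sig.name!r}: no genes measured")

    matched = Signature(sig.name, tuple(up), tuple(dn))
    report = {
        "coverage_up": cov_up,
        "coverage_dn": cov_dn if sig.two_armed else float("nan"),
        "n_up": len(up),
        "n_dn": len(dn),
        "missing_up": tuple(g for g in sig.up_genes if str(g).strip().lower() not in lookup),
        "missing_dn": tuple(g for g in sig.down_genes if str(g).strip().lower() not in lookup),
    }
    return matched, report
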