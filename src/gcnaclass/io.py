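"""Readers and writers for the external tables the pipeline consumes.

All tables are plain tab-delimited text.  Readers validate invariants up
front and raise :class:`FormatError` with the offending field named, so
that malformed inputs fail loudly rather than propagating NaNs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GisticMatrix",
    "read_gistic_matrix",
    "write_gistic_matrix",
    "read_segments",
    "write_segments",
    "read_mutations",
    "write_mutations",
    "read_clinical",
    "write_clinical",
    "write_results",
]

HISTOLOGY_CODES = {"A", "O", "OA", "AA", "AO", "AOA", "GBM", "unknown"}
GRADE_CODES = {"II", "III", "IV", "unknown"}
VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}

# free-text histology spellings → enum codes
_HISTOLOGY_SYNONYMS = {
    "astrocytoma": "A",
    "diffuse astrocytoma": "A",
    "oligodendroglioma": "O",
    "oligoastrocytoma": "OA",
    "anaplastic astrocytoma": "AA",
    "anaplastic oligodendroglioma": "AO",
    "anaplastic oligoastrocytoma": "AOA",
    "glioblastoma": "GBM",
    "glioblastoma multiforme": "GBM",
    "gbm": "GBM",
}


class FormatError(ValueError):
    """Raised when an input table violates its format contract."""


@dataclass
class GisticMatrix:
    """Gene × sample continuous copy-number scores (GISTIC2.0-style)."""

    genes: list[str]
    samples: list[str]
    scores: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.genes), len(self.samples)):
            raise FormatError("score matrix shape does not match gene/sample lists")
        dup_g = _duplicates(self.genes)
        if dup_g:
            raise FormatError(f"duplicate gene symbol(s): {dup_g}")
        dup_s = _duplicates(self.samples)
        if dup_s:
            raise FormatError(f"duplicate sample ID(s): {dup_s}")
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            i, j = np.argwhere(~np.isfinite(self.scores))[0]
            raise FormatError(
                f"non-finite score at gene {self.genes[i]!r}, sample {self.samples[j]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.genes, columns=self.samples)

    def sample_scores(self, sample_id: str) -> pd.Series:
        j = self.samples.index(sample_id)
        return pd.Series(self.scores[:, j], index=self.genes)


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


def normalize_chrom(c: str) -> str:
    c = str(c).strip()
    c = c.removeprefix("chr").removeprefix("Chr").removeprefix("CHR")
    if c == "23":
        c = "X"
    if c == "24":
        c = "Y"
    if c not in VALID_CHROMS:
        raise FormatError(f"invalid chromosome {c!r}")
    return c


def read_gistic_matrix(path: str | Path) -> GisticMatrix:
    """Read a tab-delimited gene×sample score matrix.

    First column holds gene symbols, header row holds sample IDs.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup_cols = _duplicates(header[1:])
    if dup_cols:
        raise FormatError(f"duplicate sample ID(s): {dup_cols}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise FormatError("no genes: data section is empty")
    samples = [str(s) for s in df.columns]
    genes = [str(g) for g in df.index]
    try:
        scores = df.to_numpy(dtype=float)
    except ValueError as exc:
        # locate the first offending cell for the error message
        for gi, g in enumerate(genes):
            for sj, s in enumerate(samples):
                try:
                    float(df.iat[gi, sj])
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric score at gene {g!r}, sample {s!r}: {df.iat[gi, sj]!r}"
                    ) from exc
        raise FormatError(str(exc)) from exc
    return GisticMatrix(genes=genes, samples=samples, scores=scores)


def write_gistic_matrix(matrix: GisticMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


_SEG_SYNONYMS = {
    "sample": "sample_id", "sample_id": "sample_id", "id": "sample_id",
    "chrom": "chrom", "chromosome": "chrom", "chr": "chrom",
    "start": "start", "loc.start": "start", "loc_start": "start",
    "end": "end", "loc.end": "end", "loc_end": "end",
    "log2": "log2", "seg.mean": "log2", "seg_mean": "log2", "segment_mean": "log2",
}


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG-style table: sample_id, chrom, start, end, log2.

    Coordinates are 1-based inclusive (GRCh37).  "chrN" and "N" spellings
    both normalize to "N".
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {c: _SEG_SYNONYMS[c.lower()] for c in df.columns if c.lower() in _SEG_SYNONYMS}
    df = df.rename(columns=rename)
    missing = [c for c in ("sample_id", "chrom", "start", "end", "log2") if c not in df.columns]
    if missing:
        raise FormatError(
            f"segment file missing column(s) {missing}; expected sample, chrom, start, end, log2"
        )
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "chrom": [normalize_chrom(c) for c in df["chrom"]],
            "start": pd.to_numeric(df["start"]).astype(int),
            "end": pd.to_numeric(df["end"]).astype(int),
            "log2": pd.to_numeric(df["log2"]).astype(float),
        }
    )
    bad = out.index[out["start"] > out["end"]]
    if len(bad):
        # +2 converts 0-based frame index to 1-based file line past the header
        raise FormatError(f"segment start > end at line {bad[0] + 2}")
    if not np.all(np.isfinite(out["log2"])):
        raise FormatError("non-finite log2 value in segment table")
    return out


def write_segments(seg: pd.DataFrame, path: str | Path) -> None:
    seg.to_csv(path, sep="\t", index=False)


_MUT_SYNONYMS = {
    "sample_id": "sample_id", "sample": "sample_id",
    "tumor_sample_barcode": "sample_id",
    "gene": "gene", "gene_symbol": "gene", "hugo_symbol": "gene",
    "variant_class": "variant_class", "variant_classification": "variant_class",
}


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like mutation table: sample_id, gene, variant_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {c: _MUT_SYNONYMS[c.lower()] for c in df.columns if c.lower() in _MUT_SYNONYMS}
    df = df.rename(columns=rename)
    missing = [c for c in ("sample_id", "gene") if c not in df.columns]
    if missing:
        raise FormatError(
            f"mutation file missing column(s) {missing}; "
            "expected sample_id (or Tumor_Sample_Barcode) and gene (or Hugo_Symbol)"
        )
    if "variant_class" not in df.columns:
        df["variant_class"] = ""
    out = df[["sample_id", "gene", "variant_class"]].copy()
    out["variant_class"] = out["variant_class"].fillna("")
    if (out["gene"].fillna("") == "").any():
        raise FormatError("empty gene symbol in mutation table")
    return out.astype(str)


def write_mutations(mut: pd.DataFrame, path: str | Path) -> None:
    mut.to_csv(path, sep="\t", index=False)


CLINICAL_COLUMNS = ["sample_id", "age_years", "histology_2007", "who_grade", "kps", "os_months", "event"]


def _map_histology(value: str) -> str:
    v = str(value).strip()
    if v == "" or v.lower() in ("nan", "na", "none"):
        return "unknown"
    if v in HISTOLOGY_CODES:
        return v
    return _HISTOLOGY_SYNONYMS.get(v.lower(), "unknown")


def _map_grade(value: str) -> str:
    v = str(value).strip().upper().removeprefix("WHO ").removeprefix("GRADE ").strip()
    if v in ("2", "II"):
        return "II"
    if v in ("3", "III"):
        return "III"
    if v in ("4", "IV"):
        return "IV"
    return "unknown"


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical table.

    Unknown histologies and grades map to "unknown" (never dropped).
    Missing KPS / OS are typed missing (NaN); os_months < 0 is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"clinical file missing column(s) {missing}; expected header {CLINICAL_COLUMNS}"
        )
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "age_years": pd.to_numeric(df["age_years"], errors="coerce"),
            "histology_2007": [_map_histology(v) for v in df["histology_2007"]],
            "who_grade": [_map_grade(v) for v in df["who_grade"]],
            "kps": pd.to_numeric(df["kps"], errors="coerce"),
            "os_months": pd.to_numeric(df["os_months"], errors="coerce"),
            "event": pd.to_numeric(df["event"], errors="coerce"),
        }
    )
    if (out["os_months"].dropna() < 0).any():
        bad = out.loc[out["os_months"] < 0, "sample_id"].iloc[0]
        raise FormatError(f"negative os_months for sample {bad!r}")
    if (out["age_years"].dropna() < 0).any():
        bad = out.loc[out["age_years"] < 0, "sample_id"].iloc[0]
        raise FormatError(f"negative age_years for sample {bad!r}")
    ev = out["event"].dropna()
    if not ev.isin([0, 1]).all():
        raise FormatError("event flag must be 0 or 1")
    kps = out["kps"].dropna()
    if ((kps < 0) | (kps > 100)).any():
        raise FormatError("kps must be within 0-100")
    return out


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    clin.to_csv(path, sep="\t", index=False, na_rep="")


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write pipeline output tables as deterministic TSVs plus a manifest.

    Per-sample tables (any table carrying a sample_id column) are sorted
    by sample_id so reruns are byte-identical.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        t = table
        if "sample_id" in t.columns:
            t = t.sort_values("sample_id", kind="mergesort").reset_index(drop=True)
        t.to_csv(path, sep="\t", index=False, na_rep="")
        written[name] = path
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "tables": sorted(tables),
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    written["manifest"] = mpath
    return written
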