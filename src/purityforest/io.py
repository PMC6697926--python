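"""Tabular readers/writers and the model archive.

Formats
-------
* Beta matrix: TSV, probes as rows, header ``probe_id\\t<sample...>``, missing
  values as the literal token ``NA`` (minfi / GEO series-matrix convention).
* Purity table: TSV with columns ``sample_id``, ``purity`` and optionally
  ``group`` and ``source``.
* Probe annotation: CSV modeled on the Illumina 450K manifest columns
  (probe id, ';'-separated gene symbols, ';'-separated gene-region relations,
  single relation-to-CpG-island category).
* Tumor-suppressor gene list: plain text, one symbol per line.
* Model archive: single joblib file with an embedded format version and the
  full training provenance, so that a loaded model predicts bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "PurityTable",
    "ProbeAnnotation",
    "ValidationError",
    "ModelArchiveError",
    "PURITY_SOURCES",
    "ISLAND_CATEGORIES",
    "GENE_REGIONS",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_purity_table",
    "write_purity_table",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_gene_list",
    "read_probe_list",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "purityforest-model-1"
NA_TOKEN = "NA"

PURITY_SOURCES = ("ABSOLUTE", "ESTIMATE", "LUMP", "RF_PREDICTED", "SYNTHETIC_TRUTH")
ISLAND_CATEGORIES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
GENE_REGIONS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")


class ValidationError(ValueError):
    """An input violates a documented invariant (range, duplicates, category)."""


class ModelArchiveError(RuntimeError):
    """A model archive is corrupted or has an incompatible format version."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class BetaMatrix:
    """Methylation beta values, probes x samples, each value in [0, 1] or NA."""

    values: pd.DataFrame  # index: probe ids, columns: sample ids

    def __post_init__(self):
        self.values.index = self.values.index.astype(str)
        self.values.index.name = "probe_id"
        self.values.columns = self.values.columns.astype(str)
        self.values.columns.name = None
        self.validate()

    def validate(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"beta value out of [0, 1]: probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}, value {arr[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def restrict_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(sample_ids)].copy())

    def restrict_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids), :].copy())


@dataclass
class PurityTable:
    """Per-sample purity in [0, 1] with a label-source tag and optional group."""

    purity: pd.Series  # index: sample ids
    source: str
    group: pd.Series | None = None

    def __post_init__(self):
        self.purity = self.purity.astype(float)
        self.purity.index = self.purity.index.astype(str)
        _check_unique(self.purity.index, "sample ids")
        if self.source not in PURITY_SOURCES:
            raise ValidationError(
                f"unknown purity source {self.source!r}; expected one of {PURITY_SOURCES}"
            )
        vals = self.purity.to_numpy()
        if np.any(np.isnan(vals)):
            raise ValidationError("purity values must not be missing")
        if np.any((vals < 0) | (vals > 1)):
            sid = self.purity.index[np.argwhere((vals < 0) | (vals > 1))[0][0]]
            raise ValidationError(f"purity out of [0, 1] for sample {sid!r}")
        if self.group is not None:
            self.group = self.group.astype(str)
            self.group.index = self.group.index.astype(str)
            if not self.group.index.equals(self.purity.index):
                self.group = self.group.reindex(self.purity.index)
                if self.group.isna().any():
                    raise ValidationError("group labels do not cover all samples")

    @property
    def sample_ids(self) -> pd.Index:
        return self.purity.index

    def __len__(self) -> int:
        return len(self.purity)

    def restrict(self, sample_ids) -> "PurityTable":
        ids = list(sample_ids)
        return PurityTable(
            purity=self.purity.loc[ids].copy(),
            source=self.source,
            group=None if self.group is None else self.group.loc[ids].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"sample_id": self.purity.index, "purity": self.purity.to_numpy()})
        if self.group is not None:
            frame["group"] = self.group.to_numpy()
        frame["source"] = self.source
        return frame


@dataclass
class ProbeAnnotation:
    """Probe -> gene symbols, gene-region relations, CpG-island relation.

    ``table`` is indexed by probe id with columns ``gene_symbols`` (frozenset),
    ``gene_region`` (frozenset of manifest categories) and ``island_relation``
    (exactly one manifest category).
    """

    table: pd.DataFrame

    def __post_init__(self):
        self.table.index = self.table.index.astype(str)
        _check_unique(self.table.index, "annotation probe ids")
        bad = set(self.table["island_relation"]) - set(ISLAND_CATEGORIES)
        if bad:
            raise ValidationError(
                f"unknown island_relation categories {sorted(bad)}; "
                f"expected one of {ISLAND_CATEGORIES}"
            )
        for regions in self.table["gene_region"]:
            unknown = set(regions) - set(GENE_REGIONS)
            if unknown:
                raise ValidationError(f"unknown gene_region categories {sorted(unknown)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# beta matrix


def read_beta_matrix(path, strict: bool = True) -> BetaMatrix:
    """Read a probes-x-samples beta matrix from TSV.

    With ``strict`` on, any value outside [0, 1] aborts; with ``strict`` off,
    values within 1e-9 of the boundaries are clamped (floating-point dust from
    upstream normalization) and anything worse still aborts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"beta matrix not found: {path}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    _check_unique(raw.index, f"probe ids in {path.name}")
    _check_unique(raw.columns, f"sample ids in {path.name}")
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str), dtype=float)
    for col in raw.columns:
        cells = raw[col]
        numeric = pd.to_numeric(cells.where(cells != NA_TOKEN), errors="coerce")
        bad = numeric.isna() & (cells != NA_TOKEN)
        if bad.any():
            probe = cells.index[bad][0]
            raise ValidationError(
                f"non-numeric cell (probe {probe!r}, sample {col!r}): {cells[bad].iloc[0]!r}"
            )
        values[col] = numeric
    arr = values.to_numpy()
    with np.errstate(invalid="ignore"):
        out_low = arr < 0
        out_high = arr > 1
    if strict:
        if np.any(out_low | out_high):
            i, j = np.argwhere(out_low | out_high)[0]
            raise ValidationError(
                f"beta value out of [0, 1]: probe {values.index[i]!r}, "
                f"sample {values.columns[j]!r}, value {arr[i, j]}"
            )
    else:
        tol = 1e-9
        dust = ((arr < 0) & (arr >= -tol)) | ((arr > 1) & (arr <= 1 + tol))
        hopeless = (out_low | out_high) & ~dust
        if np.any(hopeless):
            i, j = np.argwhere(hopeless)[0]
            raise ValidationError(
                f"beta value out of [0, 1] beyond clamping tolerance: probe "
                f"{values.index[i]!r}, sample {values.columns[j]!r}, value {arr[i, j]}"
            )
        arr = np.clip(arr, 0.0, 1.0)
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return BetaMatrix(values)


def write_beta_matrix(m: BetaMatrix, path) -> Path:
    """Write a beta matrix as TSV; round-trips bit-identically through the reader."""
    if m.values.shape[0] == 0 or m.values.shape[1] == 0:
        raise ValidationError("refusing to write a degenerate beta matrix (no probes or samples)")
    path = Path(path)
    frame = m.values.copy()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", na_rep=NA_TOKEN)
    return path


# ---------------------------------------------------------------------------
# purity table


def read_purity_table(path, source: str | None = None) -> PurityTable:
    """Read a per-sample purity table (TSV: sample_id, purity[, group][, source]).

    The label source is taken from the ``source`` argument or, failing that,
    from a constant ``source`` column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"purity table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "purity"):
        if col not in frame.columns:
            raise ValidationError(f"purity table {path.name} lacks required column {col!r}")
    if source is None:
        if "source" not in frame.columns:
            raise ValidationError(
                "label source must be given by the caller or a 'source' column"
            )
        sources = frame["source"].unique()
        if len(sources) != 1:
            raise ValidationError(f"mixed sources in one table: {sources.tolist()}")
        source = str(sources[0])
    purity = pd.Series(frame["purity"].to_numpy(), index=frame["sample_id"], name="purity")
    group = None
    if "group" in frame.columns:
        group = pd.Series(frame["group"].astype(str).to_numpy(), index=frame["sample_id"], name="group")
    return PurityTable(purity=purity, source=source, group=group)


def write_purity_table(t: PurityTable, path) -> Path:
    path = Path(path)
    t.to_frame().to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# probe annotation


def _split_field(cell: str) -> frozenset:
    if cell is None or cell == "" or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    return frozenset(part.strip() for part in str(cell).split(";") if part.strip())


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read a manifest-style annotation CSV.

    Expected columns: ``probe_id``, ``gene_symbols`` (';'-separated, may be
    empty), ``gene_region`` (';'-separated), ``island_relation`` (single
    category).  Unknown categories abort.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation table not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("probe_id", "gene_symbols", "gene_region", "island_relation"):
        if col not in frame.columns:
            raise ValidationError(f"annotation {path.name} lacks required column {col!r}")
    table = pd.DataFrame(
        {
            "gene_symbols": [_split_field(c) for c in frame["gene_symbols"]],
            "gene_region": [_split_field(c) for c in frame["gene_region"]],
            "island_relation": frame["island_relation"].str.strip().to_numpy(),
        },
        index=frame["probe_id"].str.strip(),
    )
    return ProbeAnnotation(table)


def write_probe_annotation(ann: ProbeAnnotation, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "probe_id": ann.table.index,
            "gene_symbols": [";".join(sorted(s)) for s in ann.table["gene_symbols"]],
            "gene_region": [";".join(sorted(s)) for s in ann.table["gene_region"]],
            "island_relation": ann.table["island_relation"].to_numpy(),
        }
    )
    frame.to_csv(path, index=False)
    return path


def read_gene_list(path) -> tuple:
    """Plain-text gene list (e.g. TSGene 2.0 export), one symbol per line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    symbols = [line.strip() for line in path.read_text().splitlines()]
    return tuple(s for s in symbols if s)


read_probe_list = read_gene_list  # same dialect: one identifier per line


# ---------------------------------------------------------------------------
# model archive


def save_model(model, path) -> Path:
    """Serialize a trained PurityModel to a single-file archive."""
    path = Path(path)
    payload = {"format_version": MODEL_FORMAT_VERSION, "model": model}
    joblib.dump(payload, path)
    return path


def load_model(path):
    """Load a PurityModel archive, checking the embedded format version."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model archive not found: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:  # noqa: BLE001 - joblib raises a zoo of errors
        raise ModelArchiveError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelArchiveError(f"{path} is not a purityforest model archive")
    version = payload["format_version"]
    if version != MODEL_FORMAT_VERSION:
        raise ModelArchiveError(
            f"model archive version mismatch: found {version!r}, "
            f"expected {MODEL_FORMAT_VERSION!r}"
        )
    return payload["model"]
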