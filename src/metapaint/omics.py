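"""Multi-omics experiment files: parse, validate, write, preprocess.

An experiment bundles one to four single-omics datasets, each a typed table
(gene/protein/reaction/compound rows x time-point columns) targeted at one
of the four visual channels.  Two on-disk forms are supported:

Single file::

    !NUM-DATASETS 2
    !DATASET tx<TAB>Transcriptomics<TAB>gene<TAB>edge_color<TAB>ALL<TAB>1
    !COLUMNS tx<TAB>1 h<TAB>3 h
    !DATASET met<TAB>Metabolomics<TAB>compound<TAB>node_color<TAB>1<TAB>1
    >DATASET tx
    glnA<TAB>0.4<TAB>-2.1
    >DATASET met
    quinate<TAB>5.0

Multi-file: the header becomes a master file whose ``!DATASET`` lines carry a
seventh field, the per-dataset table file (path relative to the master file);
sections live one per file as bare tables.

Missing values are the empty field, ``NA`` or ``NaN`` (case-insensitive), and
stay missing (``None``) in memory — never coerced to zero.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

from .network import DATA_TYPES

log = logging.getLogger(__name__)

EDGE_CHANNELS = ("edge_color", "edge_thickness")
NODE_CHANNELS = ("node_color", "node_thickness")
CHANNELS = EDGE_CHANNELS + NODE_CHANNELS

MISSING_TOKENS = {"", "na", "nan"}


class OmicsValidationError(ValueError):
    """Invalid experiment structure; carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass
class DatasetSpec:
    """Per-dataset parameters from the file header."""

    dataset_id: str
    label: str
    data_type: str
    target_channel: str
    column_selection: list[int] = field(default_factory=list)  # 1-based; [] = all
    signed: bool = False

    def __post_init__(self):
        if self.data_type not in DATA_TYPES:
            raise OmicsValidationError(
                f"dataset {self.dataset_id!r}: unknown data type {self.data_type!r}"
            )
        if self.target_channel not in CHANNELS:
            raise OmicsValidationError(
                f"dataset {self.dataset_id!r}: unknown channel {self.target_channel!r}"
            )
        if self.data_type == "compound" and self.target_channel not in NODE_CHANNELS:
            raise OmicsValidationError(
                f"dataset {self.dataset_id!r}: compound data must target a node channel"
            )
        if self.data_type != "compound" and self.target_channel not in EDGE_CHANNELS:
            raise OmicsValidationError(
                f"dataset {self.dataset_id!r}: {self.data_type} data must target an "
                "edge channel"
            )
        if any(i < 1 for i in self.column_selection):
            raise OmicsValidationError(
                f"dataset {self.dataset_id!r}: column indices are 1-based"
            )


@dataclass
class OmicsTable:
    """Rows of (entity token, numeric values); ``None`` marks a missing cell."""

    rows: list[tuple[str, list[float | None]]]
    n_columns: int
    column_labels: list[str] | None = None

    def __post_init__(self):
        for token, values in self.rows:
            if not token:
                raise OmicsValidationError("entity token must be nonempty")
            if len(values) != self.n_columns:
                raise OmicsValidationError(
                    f"row {token!r} has {len(values)} values, expected {self.n_columns}"
                )
        if self.column_labels is not None and len(self.column_labels) != self.n_columns:
            raise OmicsValidationError("column label count != column count")

    def labels(self) -> list[str]:
        return self.column_labels or [f"C{i}" for i in range(1, self.n_columns + 1)]


@dataclass
class SingleOmicsDataset:
    spec: DatasetSpec
    table: OmicsTable

    def __post_init__(self):
        for i in self.spec.column_selection:
            if i > self.table.n_columns:
                raise OmicsValidationError(
                    f"dataset {self.spec.dataset_id!r}: selected column {i} beyond "
                    f"table width {self.table.n_columns}"
                )

    def selected_columns(self) -> list[int]:
        """0-based column indices after applying the spec's selection."""
        if self.spec.column_selection:
            return [i - 1 for i in self.spec.column_selection]
        return list(range(self.table.n_columns))

    @property
    def n_selected(self) -> int:
        return len(self.selected_columns())

    def selected_values(self, token_row: list[float | None]) -> list[float | None]:
        return [token_row[i] for i in self.selected_columns()]

    def selected_labels(self) -> list[str]:
        labels = self.table.labels()
        return [labels[i] for i in self.selected_columns()]


@dataclass
class MultiOmicsExperiment:
    datasets: list[SingleOmicsDataset]

    def __post_init__(self):
        if not 1 <= len(self.datasets) <= 4:
            raise OmicsValidationError(
                f"an experiment holds 1-4 datasets, got {len(self.datasets)}"
            )
        seen_ch: dict[str, str] = {}
        seen_id: set[str] = set()
        for ds in self.datasets:
            ch, did = ds.spec.target_channel, ds.spec.dataset_id
            if ch in seen_ch:
                raise OmicsValidationError(
                    f"channel {ch!r} claimed by both {seen_ch[ch]!r} and {did!r}"
                )
            if did in seen_id:
                raise OmicsValidationError(f"duplicate dataset id {did!r}")
            seen_ch[ch] = did
            seen_id.add(did)

    @property
    def n_frames(self) -> int:
        """Animation frame count: the widest dataset after column selection.

        Narrower datasets hold their last column through later frames, so a
        one-column metabolomics set stays static while a four-column
        transcriptomics set animates.
        """
        return max(ds.n_selected for ds in self.datasets)

    def frame_labels(self) -> list[str]:
        widest = max(self.datasets, key=lambda d: d.n_selected)
        return widest.selected_labels()

    def dataset(self, dataset_id: str) -> SingleOmicsDataset:
        for ds in self.datasets:
            if ds.spec.dataset_id == dataset_id:
                return ds
        raise KeyError(dataset_id)


# -- cell parsing ----------------------------------------------------------


def parse_cell(text: str, line: int | None = None) -> float | None:
    if text.strip().casefold() in MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise OmicsValidationError(f"non-numeric cell {text!r}", line) from None


def format_cell(v: float | None) -> str:
    if v is None:
        return ""
    return repr(v) if not float(v).is_integer() else str(float(v))


def _parse_columns_field(text: str, line: int) -> list[int]:
    text = text.strip()
    if not text or text.upper() == "ALL":
        return []
    try:
        return [int(t) for t in text.split(",")]
    except ValueError:
        raise OmicsValidationError(f"bad column selection {text!r}", line) from None


# -- single-file format ----------------------------------------------------


def parse_single_file(path) -> MultiOmicsExperiment:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    return _parse_single_lines(lines, str(path))


def _parse_single_lines(lines: list[str], origin: str) -> MultiOmicsExperiment:
    declared: int | None = None
    specs: list[DatasetSpec] = []
    columns: dict[str, list[str]] = {}
    sections: dict[str, list[tuple[str, list[float | None]]]] = {}
    order: list[str] = []
    current: str | None = None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("!NUM-DATASETS"):
            try:
                declared = int(line.split(None, 1)[1])
            except (IndexError, ValueError):
                raise OmicsValidationError("malformed !NUM-DATASETS", lineno) from None
        elif line.startswith("!DATASET"):
            cells = line.split("\t")
            if len(cells) < 6:
                raise OmicsValidationError(
                    "!DATASET needs id, label, data_type, channel, columns, signed",
                    lineno,
                )
            _, did, label, dtype, channel, cols, signed = (cells + [""])[:7]
            try:
                specs.append(
                    DatasetSpec(
                        dataset_id=did,
                        label=label,
                        data_type=dtype,
                        target_channel=channel,
                        column_selection=_parse_columns_field(cols, lineno),
                        signed=signed.strip() == "1",
                    )
                )
            except OmicsValidationError as exc:
                if exc.line is None:
                    raise OmicsValidationError(str(exc), lineno) from None
                raise
        elif line.startswith("!COLUMNS"):
            cells = line.split("\t")
            if len(cells) < 2:
                raise OmicsValidationError("!COLUMNS needs a dataset id", lineno)
            columns[cells[1]] = cells[2:]
        elif line.startswith(">DATASET"):
            parts = line.split("\t")
            did = parts[1].strip() if len(parts) > 1 else line.split(None, 1)[1].strip()
            if did in sections:
                raise OmicsValidationError(f"duplicate section for {did!r}", lineno)
            sections[did] = []
            order.append(did)
            current = did
        elif line.startswith("!"):
            raise OmicsValidationError(f"unknown directive {line.split()[0]!r}", lineno)
        else:
            if current is None:
                raise OmicsValidationError("data row before any >DATASET section", lineno)
            cells = line.split("\t")
            token = cells[0].strip()
            values = [parse_cell(c, lineno) for c in cells[1:]]
            sections[current].append((token, values))

    if declared is None:
        raise OmicsValidationError(f"{origin}: missing !NUM-DATASETS header")
    if declared != len(sections):
        raise OmicsValidationError(
            f"{origin}: header declares {declared} datasets but file contains "
            f"{len(sections)} sections"
        )
    if len(specs) != len(sections):
        raise OmicsValidationError(
            f"{origin}: {len(specs)} !DATASET headers for {len(sections)} sections"
        )

    datasets = []
    spec_by_id = {s.dataset_id: s for s in specs}
    if len(spec_by_id) != len(specs):
        raise OmicsValidationError(f"{origin}: duplicate dataset id in header")
    for did in order:
        if did not in spec_by_id:
            raise OmicsValidationError(f"{origin}: section {did!r} has no !DATASET header")
        datasets.append(
            SingleOmicsDataset(
                spec=spec_by_id[did],
                table=_make_table(sections[did], columns.get(did)),
            )
        )
    return MultiOmicsExperiment(datasets=datasets)


def _make_table(
    rows: list[tuple[str, list[float | None]]], labels: list[str] | None
) -> OmicsTable:
    if not rows:
        raise OmicsValidationError("dataset section has no rows")
    n = max(len(v) for _, v in rows)
    padded = [(t, v + [None] * (n - len(v))) for t, v in rows]
    return OmicsTable(rows=padded, n_columns=n, column_labels=labels)


def write_single_file(experiment: MultiOmicsExperiment, path) -> None:
    lines = [f"!NUM-DATASETS {len(experiment.datasets)}"]
    for ds in experiment.datasets:
        lines.append(_dataset_header_line(ds.spec))
        if ds.table.column_labels is not None:
            lines.append(
                "\t".join(["!COLUMNS", ds.spec.dataset_id, *ds.table.column_labels])
            )
    for ds in experiment.datasets:
        lines.append(f">DATASET\t{ds.spec.dataset_id}")
        for token, values in ds.table.rows:
            lines.append("\t".join([token, *[format_cell(v) for v in values]]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _dataset_header_line(spec: DatasetSpec, filename: str | None = None) -> str:
    cols = ",".join(str(i) for i in spec.column_selection) or "ALL"
    cells = [
        "!DATASET",
        spec.dataset_id,
        spec.label,
        spec.data_type,
        spec.target_channel,
        cols,
        "1" if spec.signed else "0",
    ]
    if filename is not None:
        cells.append(filename)
    return "\t".join(cells)


# -- multi-file format -----------------------------------------------------


def parse_master_file(path) -> MultiOmicsExperiment:
    base = os.path.dirname(os.path.abspath(str(path)))
    declared: int | None = None
    entries: list[tuple[DatasetSpec, str]] = []
    columns: dict[str, list[str]] = {}

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if line.startswith("!NUM-DATASETS"):
                try:
                    declared = int(line.split(None, 1)[1])
                except (IndexError, ValueError):
                    raise OmicsValidationError("malformed !NUM-DATASETS", lineno) from None
            elif line.startswith("!DATASET"):
                cells = line.split("\t")
                if len(cells) < 7:
                    raise OmicsValidationError(
                        "master !DATASET needs id, label, data_type, channel, "
                        "columns, signed, file",
                        lineno,
                    )
                _, did, label, dtype, channel, cols, signed, fname = (cells + [""])[:8]
                spec = DatasetSpec(
                    dataset_id=did,
                    label=label,
                    data_type=dtype,
                    target_channel=channel,
                    column_selection=_parse_columns_field(cols, lineno),
                    signed=signed.strip() == "1",
                )
                entries.append((spec, fname.strip()))
            elif line.startswith("!COLUMNS"):
                cells = line.split("\t")
                columns[cells[1]] = cells[2:]
            else:
                raise OmicsValidationError(f"unexpected line in master file", lineno)

    if declared is None:
        raise OmicsValidationError(f"{path}: missing !NUM-DATASETS header")
    if not entries:
        raise OmicsValidationError(f"{path}: at least one dataset entry required")
    if declared != len(entries):
        raise OmicsValidationError(
            f"{path}: header declares {declared} datasets, {len(entries)} listed"
        )

    datasets = []
    for spec, fname in entries:
        table_path = os.path.join(base, fname)
        if not os.path.exists(table_path):
            raise OmicsValidationError(
                f"master file references missing dataset file {fname!r}"
            )
        rows = _read_table_file(table_path)
        datasets.append(
            SingleOmicsDataset(
                spec=spec, table=_make_table(rows, columns.get(spec.dataset_id))
            )
        )
    return MultiOmicsExperiment(datasets=datasets)


def _read_table_file(path) -> list[tuple[str, list[float | None]]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            rows.append((cells[0].strip(), [parse_cell(c, lineno) for c in cells[1:]]))
    return rows


def write_master_file(experiment: MultiOmicsExperiment, master_path) -> None:
    """Write the multi-file form: a master file plus one table file per dataset."""
    base = os.path.dirname(os.path.abspath(str(master_path)))
    lines = [f"!NUM-DATASETS {len(experiment.datasets)}"]
    for ds in experiment.datasets:
        fname = f"{ds.spec.dataset_id}.tsv"
        lines.append(_dataset_header_line(ds.spec, fname))
        if ds.table.column_labels is not None:
            lines.append(
                "\t".join(["!COLUMNS", ds.spec.dataset_id, *ds.table.column_labels])
            )
        with open(os.path.join(base, fname), "w", encoding="utf-8") as fh:
            for token, values in ds.table.rows:
                fh.write("\t".join([token, *[format_cell(v) for v in values]]) + "\n")
    with open(master_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# -- preprocessing transforms ---------------------------------------------


def fold_change_transform(
    table: OmicsTable, reference_column: int, log2: bool = True
) -> OmicsTable:
    """Express each column as a (log2) ratio to a reference column.

    The reference column is dropped, so a five-time-point table becomes a
    four-column fold-change table.  Rows with a missing or zero reference —
    or, under log2, a nonpositive ratio — produce missing cells.
    """
    if table.n_columns < 2:
        raise OmicsValidationError("fold change needs at least 2 columns")
    if not 1 <= reference_column <= table.n_columns:
        raise OmicsValidationError(
            f"reference column {reference_column} outside 1..{table.n_columns}"
        )
    ref_i = reference_column - 1
    keep = [i for i in range(table.n_columns) if i != ref_i]
    out_rows: list[tuple[str, list[float | None]]] = []
    for token, values in table.rows:
        ref = values[ref_i]
        if ref is None or ref == 0:
            log.warning("fold change: row %r has missing/zero reference", token)
            out_rows.append((token, [None] * len(keep)))
            continue
        out: list[float | None] = []
        for i in keep:
            v = values[i]
            if v is None:
                out.append(None)
            else:
                ratio = v / ref
                if log2:
                    out.append(math.log2(ratio) if ratio > 0 else None)
                else:
                    out.append(ratio)
        out_rows.append((token, out))
    labels = None
    if table.column_labels is not None:
        labels = [table.column_labels[i] for i in keep]
    return OmicsTable(rows=out_rows, n_columns=len(keep), column_labels=labels)


def essentiality_transform(table: OmicsTable) -> OmicsTable:
    """Convert normalized growth yields to essentiality: v -> 1 - v.

    A knockout that barely grows (yield near 0) maps to essentiality near 1.
    Values outside [0, 1] are transformed anyway, with a warning.
    """
    out_rows: list[tuple[str, list[float | None]]] = []
    for token, values in table.rows:
        out: list[float | None] = []
        for v in values:
            if v is None:
                out.append(None)
            else:
                if not 0.0 <= v <= 1.0:
                    log.warning("essentiality: yield %r for %r outside [0, 1]", v, token)
                out.append(1.0 - v)
        out_rows.append((token, out))
    return OmicsTable(
        rows=out_rows, n_columns=table.n_columns, column_labels=table.column_labels
    )
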