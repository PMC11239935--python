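"""Data model and file I/O for multivariate time series collections.

A :class:`MultivariateSeries` is an ``n x m`` array (``n`` time points,
``m`` channels); a :class:`LabeledCollection` bundles several of them
with binary class labels.  Readers cover the UEA ``.ts`` dialect
(sktime/aeon flavour), generic wide/long delimited text, and the
whitespace-delimited sensor tables used by PhysioNet gait recordings.
Preprocessing helpers implement last-value padding to a common length
and non-overlapping block averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class MultivariateSeries:
    """One multivariate instance: ``n`` time points by ``m`` channels.

    Parameters
    ----------
    values
        Real matrix of shape ``(n, m)``; rows are time points.
    channel_names
        One identifier per channel; defaults to ``ch0 .. ch{m-1}``.
    instance_id
        Free-form identifier used in logs and round-trips.
    """

    values: np.ndarray
    channel_names: tuple[str, ...] = ()
    instance_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        object.__setattr__(self, "values", values)
        if not self.channel_names:
            names = tuple(f"ch{j}" for j in range(values.shape[1]))
            object.__setattr__(self, "channel_names", names)
        elif len(self.channel_names) != values.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{values.shape[1]} channels"
            )

    @property
    def n(self) -> int:
        """Number of time points."""
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Number of channels."""
        return self.values.shape[1]


@dataclass(frozen=True)
class LabeledCollection:
    """A set of instances with binary class labels.

    ``positive_label`` marks the class of interest (e.g. diseased) used
    by recall and by probabilistic scores downstream.
    """

    instances: tuple[MultivariateSeries, ...]
    labels: tuple[str, ...]
    positive_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "instances", tuple(self.instances))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if len(self.instances) != len(self.labels):
            raise ValueError(
                f"{len(self.instances)} instances but {len(self.labels)} labels"
            )
        observed = set(self.labels)
        if self.labels and str(self.positive_label) not in observed:
            raise ValueError(
                f"positive_label {self.positive_label!r} not among labels {sorted(observed)}"
            )
        object.__setattr__(self, "positive_label", str(self.positive_label))

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))


# ---------------------------------------------------------------------------
# UEA .ts reader (sktime/aeon dialect)
# ---------------------------------------------------------------------------

_KNOWN_TAGS = {
    "problemname",
    "timestamps",
    "missing",
    "univariate",
    "dimensions",
    "equallength",
    "serieslength",
    "classlabel",
    "targetlabel",
    "data",
}


def read_ts(path, positive_label: str | None = None) -> LabeledCollection:
    """Read a UEA/sktime ``.ts`` file into a :class:`LabeledCollection`.

    The dialect: ``@``-prefixed header tags, then ``@data`` followed by
    one record per line; channels separated by ``:``, values within a
    channel comma-separated, the trailing ``:``-field being the class
    label.  Unknown header tags are ignored with a warning.

    Parameters
    ----------
    path
        Path to the ``.ts`` file.
    positive_label
        Which class is treated as positive; defaults to the
        lexicographically last label (so e.g. ``"1"`` beats ``"0"``).
    """
    declared_dims: int | None = None
    has_class_labels: bool | None = None
    in_data = False
    records: list[list[list[float]]] = []
    labels: list[str] = []

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not in_data and line.startswith("@"):
                head, _, rest = line.partition(" ")
                tag = head[1:].lower()
                if tag == "data":
                    if has_class_labels is not True:
                        raise FormatError(
                            f"{path}: line {lineno}: @classLabel true required "
                            "(labeled records needed for classification)"
                        )
                    in_data = True
                    continue
                if tag == "dimensions":
                    try:
                        declared_dims = int(rest.strip())
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}: line {lineno}: bad @dimensions value {rest!r}"
                        ) from exc
                elif tag == "univariate":
                    if rest.strip().lower() == "true":
                        declared_dims = 1
                elif tag == "classlabel":
                    has_class_labels = rest.strip().lower().startswith("true")
                elif tag not in _KNOWN_TAGS:
                    logger.warning("%s: line %d: ignoring unknown tag @%s", path, lineno, tag)
                continue
            if not in_data:
                raise FormatError(
                    f"{path}: line {lineno}: data before @data marker: {line[:40]!r}"
                )
            fields = line.split(":")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: record has no ':'-separated label field"
                )
            label = fields[-1].strip()
            chans = []
            for block in fields[:-1]:
                try:
                    chans.append([float(v) for v in block.split(",") if v.strip() != ""])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric value in channel block"
                    ) from exc
            if declared_dims is not None and len(chans) != declared_dims:
                raise FormatError(
                    f"{path}: line {lineno}: {len(chans)} channel blocks but "
                    f"{declared_dims} dimensions declared"
                )
            lengths = {len(c) for c in chans}
            if len(lengths) != 1:
                raise FormatError(
                    f"{path}: line {lineno}: unequal channel lengths {sorted(lengths)} "
                    "within one record"
                )
            records.append(chans)
            labels.append(label)

    if not records:
        raise FormatError(f"{path}: no data records found")
    instances = tuple(
        MultivariateSeries(np.asarray(chans, dtype=float).T, instance_id=f"rec{i}")
        for i, chans in enumerate(records)
    )
    if positive_label is None:
        positive_label = sorted(set(labels))[-1]
    return LabeledCollection(instances, tuple(labels), positive_label)


def write_ts(collection: LabeledCollection, path, problem_name: str = "dataset") -> None:
    """Write a collection in the UEA ``.ts`` dialect (round-trip partner of
    :func:`read_ts`)."""
    m = collection.instances[0].m
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@problemName {problem_name}\n")
        fh.write("@timestamps false\n@missing false\n")
        fh.write(f"@univariate {'true' if m == 1 else 'false'}\n")
        fh.write(f"@dimensions {m}\n")
        fh.write("@equalLength false\n")
        fh.write(f"@classLabel true {' '.join(collection.class_labels)}\n")
        fh.write("@data\n")
        for inst, label in zip(collection.instances, collection.labels):
            blocks = [
                ",".join(format(float(v), ".17g") for v in inst.values[:, j])
                for j in range(inst.m)
            ]
            fh.write(":".join(blocks) + f":{label}\n")


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def read_delimited(
    path,
    layout: str = "wide",
    time_column: str | int | None = None,
    delimiter: str | None = None,
    instance_id: str = "",
) -> MultivariateSeries:
    """Read one multivariate series from a delimited text table.

    In ``wide`` layout rows are time points and columns are channels
    (the PhysioNet gait files are whitespace-delimited wide tables whose
    first column is time).  In ``long`` layout the table has columns
    ``time``/``channel``/``value`` and is pivoted to wide.

    Parameters
    ----------
    time_column
        Column name (or positional index in headerless files) excluded
        from the channels; required for long layout (as the row index).
    delimiter
        ``None`` means "any whitespace"; pass ``","`` etc. otherwise.
    """
    if layout not in {"wide", "long"}:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    sep = delimiter if delimiter is not None else r"\s+"
    # Sniff a header line: if the first row has any non-numeric token, use it.
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().split() if delimiter is None else fh.readline().split(delimiter)
    has_header = any(not _is_number(tok) for tok in first)
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None, engine="python")

    if layout == "long":
        cols = list(df.columns)
        if len(cols) < 3:
            raise FormatError(f"{path}: long layout needs >=3 columns, got {cols}")
        tcol = time_column if time_column is not None else cols[0]
        other = [c for c in cols if c != tcol]
        df = df.pivot(index=tcol, columns=other[0], values=other[1]).sort_index()
        df.columns = [str(c) for c in df.columns]
    elif time_column is not None:
        if time_column not in df.columns:
            raise FormatError(f"{path}: time column {time_column!r} not found")
        df = df.drop(columns=[time_column])

    bad = df.map(lambda v: not _is_number(v))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at row {r}, column {df.columns[c]!r}"
        )
    values = df.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError(
            f"{path}: {values.shape[1]} channel(s); signature extraction needs >=2"
        )
    return MultivariateSeries(
        values,
        tuple(str(c) for c in df.columns),
        instance_id=instance_id or str(path),
    )


def _is_number(tok) -> bool:
    try:
        float(tok)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def pad_to_length(
    collection: LabeledCollection, target: int | None = None
) -> LabeledCollection:
    """Equalize instance lengths by repeating each channel's final value.

    Shorter series are extended to ``target`` (default: the longest
    length in the collection) by appending rows that repeat the last
    observed value per channel.  Already-equal collections pass through
    unchanged; padding is idempotent.
    """
    lengths = [inst.n for inst in collection.instances]
    maxlen = max(lengths)
    if target is None:
        target = maxlen
    if target < maxlen:
        raise ValueError(f"target {target} < max instance length {maxlen}")
    if all(l == target for l in lengths):
        return collection
    padded = []
    for inst in collection.instances:
        if inst.n == target:
            padded.append(inst)
            continue
        tail = np.repeat(inst.values[-1:, :], target - inst.n, axis=0)
        padded.append(replace(inst, values=np.vstack([inst.values, tail])))
    return LabeledCollection(tuple(padded), collection.labels, collection.positive_label)


def block_average(series: MultivariateSeries, window: int) -> MultivariateSeries:
    """Replace non-overlapping blocks of ``window`` points by their mean.

    A trailing remainder shorter than ``window`` is dropped, so the
    output has ``floor(n / window)`` time points.  ``window=1`` is the
    identity.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if window == 1:
        return series
    nblocks = series.n // window
    if nblocks == 0:
        raise ValueError(f"series of length {series.n} shorter than window {window}")
    trimmed = series.values[: nblocks * window]
    means = trimmed.reshape(nblocks, window, series.m).mean(axis=1)
    return replace(series, values=means)


# ---------------------------------------------------------------------------
# Signature matrix CSV
# ---------------------------------------------------------------------------

def write_signatures(matrix, path) -> None:
    """Write a signature matrix as CSV: one ``tau{t}_k{k}`` column per
    feature, instances as rows, the class label as the last column."""
    if matrix.features.size == 0:
        raise ValueError("empty signature matrix")
    df = pd.DataFrame(matrix.features, columns=list(matrix.column_names))
    df["label"] = list(matrix.labels)
    df.to_csv(path, index=False, float_format="%.17g")


def read_signatures(path, positive_label: str | None = None):
    """Read back a signature CSV written by :func:`write_signatures`."""
    from .signatures import SignatureMatrix

    df = pd.read_csv(path, dtype={"label": str})
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    labels = tuple(df.pop("label").astype(str))
    if positive_label is None:
        positive_label = sorted(set(labels))[-1]
    return SignatureMatrix(
        features=df.to_numpy(dtype=float),
        column_names=tuple(df.columns),
        labels=labels,
        positive_label=positive_label,
    )
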