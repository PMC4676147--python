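"""Reading/writing log2-ratio matrices and exporting probe-level calls.

The on-disk matrix format is plain TSV/CSV: an optional header row of probe
labels, an optional leading column of sample labels, and a rectangular
numeric body of log2 test/reference intensity ratios.  Rows are samples by
default (n samples x p probes).  Missing values are rejected, not imputed:
the estimator assumes a complete matrix.

Probe coordinates are 1-based inclusive throughout the package; only the BED
export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "LogRatioMatrix",
    "Segment",
    "FormatError",
    "ParseError",
    "DimensionError",
    "read_matrix",
    "write_matrix",
    "segments_from_calls",
    "write_calls",
]


class FormatError(ValueError):
    """The file is not a rectangular delimited matrix."""


class ParseError(ValueError):
    """A body cell could not be parsed as a finite number."""


class DimensionError(ValueError):
    """The matrix violates the n >= 1, p >= 2 requirement."""


@dataclass
class LogRatioMatrix:
    """An n x p matrix of log2 intensity ratios with sample/probe labels.

    Optional per-probe annotation (`chromosome`, `position` in bp) enables
    genomic coordinates in the BED export; without it, exports fall back to
    probe-index coordinates.
    """

    values: np.ndarray
    sample_ids: List[str]
    probe_ids: List[str]
    chromosome: Optional[List[str]] = None
    position: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 1:
            raise DimensionError("need at least one sample")
        if p < 2:
            raise DimensionError(
                f"need at least two probes (p={p}); the TV penalty is undefined otherwise"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite value at sample {self.sample_ids[i]!r}, probe {self.probe_ids[j]!r}; "
                "missing values must be removed or imputed upstream"
            )
        if len(self.sample_ids) != n or len(self.probe_ids) != p:
            raise DimensionError("label lengths do not match matrix shape")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=np.int64)
            if self.position.shape != (p,):
                raise DimensionError("position annotation length must equal p")
        if self.chromosome is not None and len(self.chromosome) != p:
            raise DimensionError("chromosome annotation length must equal p")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Segment:
    """A maximal run of same-sign calls in one sample (1-based inclusive probes)."""

    sample_id: str
    start_probe: int
    end_probe: int
    mean_estimate: float
    call: str  # "gain" | "loss"

    def __post_init__(self):
        if not 1 <= self.start_probe <= self.end_probe:
            raise ValueError("need 1 <= start_probe <= end_probe")
        if self.call not in ("gain", "loss"):
            raise ValueError(f"call must be 'gain' or 'loss', got {self.call!r}")
        if self.call == "gain" and self.mean_estimate <= 0:
            raise ValueError("gain segments require a positive mean estimate")
        if self.call == "loss" and self.mean_estimate >= 0:
            raise ValueError("loss segments require a negative mean estimate")


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def read_matrix(
    path,
    delimiter: str = "\t",
    rows_are_samples: bool = True,
) -> LogRatioMatrix:
    """Read a delimited log2-ratio matrix.

    A header row and/or a leading label column are detected by their first
    data cell being non-numeric; detected labels are preserved, otherwise
    synthetic ``S1..Sn`` / ``P1..Pp`` labels are generated.  Raises
    :class:`FormatError` for ragged files, :class:`ParseError` (naming the
    cell) for non-numeric body entries, and :class:`DimensionError` when
    fewer than two probes remain.
    """
    path = Path(path)
    rows: List[List[str]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if line.strip() == "":
                continue
            rows.append(line.split(delimiter))
    if not rows:
        raise FormatError(f"{path}: empty file")
    width = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(
                f"{path}: ragged row {k + 1} (expected {width} fields, got {len(r)})"
            )

    has_header = not _looks_numeric(rows[0][-1])
    data_rows = rows[1:] if has_header else rows
    # a label column must be non-numeric in every data row; a stray
    # non-numeric cell (e.g. "NA") is a body parse error, not a label
    has_rowlabels = bool(data_rows) and all(not _looks_numeric(r[0]) for r in data_rows)
    body = [r[1:] if has_rowlabels else r for r in (rows[1:] if has_header else rows)]
    if not body or not body[0]:
        raise DimensionError(f"{path}: no numeric body")

    col_labels = (rows[0][1:] if has_rowlabels else rows[0]) if has_header else None
    row_labels = [r[0] for r in (rows[1:] if has_header else rows)] if has_rowlabels else None

    values = np.empty((len(body), len(body[0])))
    for i, r in enumerate(body):
        for j, tok in enumerate(r):
            try:
                v = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: cannot parse {tok!r} at data row {i + 1}, column {j + 1}"
                ) from None
            values[i, j] = v
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(f"{path}: non-finite value at data row {i + 1}, column {j + 1}")

    if not rows_are_samples:
        values = values.T
        row_labels, col_labels = col_labels, row_labels
    n, p = values.shape
    sample_ids = list(row_labels) if row_labels else [f"S{i + 1}" for i in range(n)]
    probe_ids = list(col_labels) if col_labels else [f"P{j + 1}" for j in range(p)]
    return LogRatioMatrix(values=values, sample_ids=sample_ids, probe_ids=probe_ids)


def write_matrix(matrix: LogRatioMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix with header row and label column, round-trip safe.

    Values are written with repr-precision (%.17g) so that
    ``read_matrix(write_matrix(M))`` reproduces finite doubles bit-exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample" + delimiter + delimiter.join(matrix.probe_ids) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.values):
            fh.write(sid + delimiter + delimiter.join(f"{v:.17g}" for v in row) + "\n")


def segments_from_calls(
    calls: np.ndarray, X_hat: np.ndarray, sample_ids: Sequence[str]
) -> List[Segment]:
    """Partition each sample's nonzero calls into maximal constant-sign runs."""
    segments: List[Segment] = []
    n, p = calls.shape
    for i in range(n):
        j = 0
        while j < p:
            s = calls[i, j]
            if s == 0:
                j += 1
                continue
            k = j
            while k + 1 < p and calls[i, k + 1] == s:
                k += 1
            segments.append(
                Segment(
                    sample_id=sample_ids[i],
                    start_probe=j + 1,
                    end_probe=k + 1,
                    mean_estimate=float(X_hat[i, j : k + 1].mean()),
                    call="gain" if s > 0 else "loss",
                )
            )
            j = k + 1
    return segments


def write_calls(
    fit,
    matrix: LogRatioMatrix,
    threshold: float = 0.225,
    out_dir=None,
    calls_path=None,
    segments_path=None,
    frequency_path=None,
) -> Tuple[np.ndarray, List[Segment], pd.DataFrame]:
    """Threshold a fit into CNV calls and export them.

    A probe is called where ``|x_hat| > threshold`` (strict).  Writes, under
    `out_dir` (or at the explicit paths):

    * ``calls.tsv`` — the n x p call matrix with values in {-1, 0, +1};
    * ``segments.bed`` — maximal same-sign runs per sample as BED
      (0-based half-open; genomic coordinates when probe positions are
      annotated, probe-index coordinates otherwise);
    * ``frequency.tsv`` — per-probe gain/loss frequency across samples.

    Returns ``(calls, segments, frequency_frame)``.
    """
    X_hat = np.asarray(fit.X_hat if hasattr(fit, "X_hat") else fit, dtype=np.float64)
    if X_hat.shape != matrix.values.shape:
        raise DimensionError(
            f"fit shape {X_hat.shape} does not match matrix shape {matrix.values.shape}"
        )
    calls = np.sign(X_hat) * (np.abs(X_hat) > threshold)
    calls = calls.astype(int)
    segments = segments_from_calls(calls, X_hat, matrix.sample_ids)
    freq = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "gain_frequency": (calls == 1).mean(axis=0),
            "loss_frequency": (calls == -1).mean(axis=0),
        }
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        calls_path = calls_path or out_dir / "calls.tsv"
        segments_path = segments_path or out_dir / "segments.bed"
        frequency_path = frequency_path or out_dir / "frequency.tsv"

    if calls_path is not None:
        pd.DataFrame(calls, index=matrix.sample_ids, columns=matrix.probe_ids).to_csv(
            calls_path, sep="\t", index_label="sample"
        )
    if segments_path is not None:
        with Path(segments_path).open("w") as fh:
            for seg in segments:
                if matrix.position is not None:
                    chrom = (
                        matrix.chromosome[seg.start_probe - 1]
                        if matrix.chromosome is not None
                        else "chrNA"
                    )
                    start = int(matrix.position[seg.start_probe - 1]) - 1
                    end = int(matrix.position[seg.end_probe - 1])
                else:
                    chrom = "probe_index"
                    start = seg.start_probe - 1  # 1-based inclusive -> 0-based half-open
                    end = seg.end_probe
                name = f"{seg.sample_id}:{seg.call}"
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{seg.mean_estimate:.6g}\n")
    if frequency_path is not None:
        freq.to_csv(frequency_path, sep="\t", index=False)
    return calls, segments, freq
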