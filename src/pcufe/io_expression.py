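"""Reading, writing and aligning expression matrices and sample annotations.

File conventions
----------------
*Expression TSV*: UTF-8, tab-delimited.  Row 1 is a header
``feature_id<TAB>sample1<TAB>...``; each following row is one feature.
Values are written in scientific notation with 12 significant digits so
that write/read round trips are stable.

*Annotation table*: two columns (``sample_id``, ``class_label``),
comma- or tab-delimited, optional header.  Exactly two distinct labels
must be present.  Class index 1 is assigned to the lexicographically
smaller label, class index 2 to the larger one.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import AlignmentError, MatrixFormatError

logger = logging.getLogger(__name__)

#: format used for all serialized floating point numbers (12 significant digits)
FLOAT_FMT = "{:.11e}"


@dataclass
class ExpressionMatrix:
    """Feature-by-sample real-valued matrix with identifiers.

    Parameters
    ----------
    feature_ids :
        Ordered unique feature identifiers (length ``N``).
    sample_ids :
        Ordered unique sample identifiers (length ``M``).
    values :
        ``N x M`` array; ``values[i, j]`` is the expression of feature
        ``i`` in sample ``j``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.feature_ids) != n:
            raise MatrixFormatError(
                f"{len(self.feature_ids)} feature ids for {n} rows"
            )
        if len(self.sample_ids) != m:
            raise MatrixFormatError(
                f"{len(self.sample_ids)} sample ids for {m} columns"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise MatrixFormatError("matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """Return a copy restricted to the given feature row positions."""
        idx = list(indices)
        return ExpressionMatrix(
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :].copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """Return a copy restricted to the given sample column positions."""
        idx = list(indices)
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[j] for j in idx],
            values=self.values[:, idx].copy(),
        )


@dataclass
class SampleAnnotation:
    """Sample-to-class map for a two-class design.

    ``class_of[sample_id]`` gives the label; ``classes`` lists the two
    labels in lexicographic order, so ``classes[0]`` is class index 1 and
    ``classes[1]`` is class index 2.
    """

    sample_ids: list[str]
    class_labels: list[str]
    require_two_per_class: bool = True

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_labels = [str(c).strip() for c in self.class_labels]
        if len(self.sample_ids) != len(self.class_labels):
            raise MatrixFormatError("sample_ids and class_labels length mismatch")
        _check_unique(self.sample_ids, "sample")
        distinct = sorted(set(self.class_labels))
        if len(distinct) != 2:
            raise MatrixFormatError(
                f"exactly two class labels required, found {len(distinct)}: "
                + ", ".join(distinct)
            )
        if self.require_two_per_class:
            for lab in distinct:
                count = self.class_labels.count(lab)
                if count < 2:
                    raise MatrixFormatError(
                        f"class {lab!r} has {count} sample(s); association "
                        "testing needs at least 2 per class"
                    )
        self.classes: tuple[str, str] = (distinct[0], distinct[1])
        self.class_of: dict[str, str] = dict(zip(self.sample_ids, self.class_labels))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_indicator(self) -> np.ndarray:
        """0/1 array: 1 where the sample belongs to class index 2."""
        return np.array(
            [1 if c == self.classes[1] else 0 for c in self.class_labels], dtype=int
        )

    def subset(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        wanted = list(sample_ids)
        missing = [s for s in wanted if s not in self.class_of]
        if missing:
            raise AlignmentError(f"samples not annotated: {missing}")
        return SampleAnnotation(
            sample_ids=wanted,
            class_labels=[self.class_of[s] for s in wanted],
            require_two_per_class=self.require_two_per_class,
        )


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MatrixFormatError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


def read_expression_matrix(
    path: str | os.PathLike,
    missing_token: str = "NA",
) -> ExpressionMatrix:
    """Read a feature-by-sample TSV into an :class:`ExpressionMatrix`.

    Features containing the missing token are dropped (their count is
    logged); the remaining values must all parse as finite numbers.
    """
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    n_dropped = 0
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise MatrixFormatError(f"{path}: empty file")
        sample_ids = header.rstrip("\n").split("\t")[1:]
        if len(sample_ids) < 2:
            raise MatrixFormatError(
                f"{path}: at least 2 sample columns required, found {len(sample_ids)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(sample_ids) + 1:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                    f"found {len(cells)}"
                )
            fid, raw = cells[0], cells[1:]
            if missing_token in raw:
                n_dropped += 1
                continue
            try:
                row = [float(v) for v in raw]
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: {exc}") from exc
            if not all(math.isfinite(v) for v in row):
                raise MatrixFormatError(f"{path}:{lineno}: non-finite value")
            feature_ids.append(fid)
            rows.append(row)
    if n_dropped:
        logger.info("dropped %d feature(s) with missing values", n_dropped)
    if not rows:
        raise MatrixFormatError(f"{path}: no usable feature rows")
    return ExpressionMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write an expression matrix in the package TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            fh.write(fid + "\t" + "\t".join(FLOAT_FMT.format(v) for v in row) + "\n")


def read_sample_annotation(
    path: str | os.PathLike,
    header: bool = True,
) -> SampleAnnotation:
    """Read a two-column (sample_id, class_label) table.

    The delimiter is sniffed: tab if the first data line contains one,
    else comma.  Labels are whitespace-trimmed.
    """
    sample_ids: list[str] = []
    labels: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty annotation file")
    if header:
        lines = lines[1:]
    if not lines:
        raise MatrixFormatError(f"{path}: no annotation rows")
    delim = "\t" if "\t" in lines[0] else ","
    for lineno, line in enumerate(lines, start=2 if header else 1):
        cells = line.split(delim)
        if len(cells) < 2:
            raise MatrixFormatError(
                f"{path}:{lineno}: expected 2 columns separated by {delim!r}"
            )
        sample_ids.append(cells[0].strip())
        labels.append(cells[1].strip())
    return SampleAnnotation(sample_ids=sample_ids, class_labels=labels)


def write_sample_annotation(
    annot: SampleAnnotation, path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id,class_label\n")
        for sid, lab in zip(annot.sample_ids, annot.class_labels):
            fh.write(f"{sid},{lab}\n")


def align(
    matrix: ExpressionMatrix, annot: SampleAnnotation
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Restrict both objects to their shared samples, in matrix column order.

    Samples present in only one of the two inputs are dropped (and
    logged).  Raises :class:`AlignmentError` if the intersection is
    empty.
    """
    annotated = set(annot.sample_ids)
    keep = [j for j, sid in enumerate(matrix.sample_ids) if sid in annotated]
    if not keep:
        raise AlignmentError("matrix and annotation share no samples")
    dropped_mat = [s for s in matrix.sample_ids if s not in annotated]
    dropped_ann = [s for s in annot.sample_ids if s not in set(matrix.sample_ids)]
    if dropped_mat:
        logger.info("align: dropped %d matrix sample(s): %s", len(dropped_mat), dropped_mat)
    if dropped_ann:
        logger.info("align: dropped %d annotation sample(s): %s", len(dropped_ann), dropped_ann)
    new_matrix = matrix.subset_samples(keep)
    new_annot = annot.subset(new_matrix.sample_ids)
    return new_matrix, new_annot


def write_result_tables(
    ufe_result,
    disc_result,
    out_dir: str | os.PathLike,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, str]:
    """Serialize pipeline outputs.

    Writes ``features.tsv`` (per-feature statistic, raw/adjusted p,
    selected flag), ``components.tsv`` (per-component eigenvalue,
    association p raw/adjusted, membership in the selected set),
    ``roc.tsv`` when a discrimination result is available, and
    ``summary.json``.  Returns a name-to-path map of written files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    fpath = os.path.join(out_dir, "features.tsv")
    with open(fpath, "w", encoding="utf-8") as fh:
        fh.write("feature_id\tstatistic\tp_raw\tp_adjusted\tselected\n")
        selected_set = set(ufe_result.selected_features)
        for i, fid in enumerate(ufe_result.feature_ids):
            fh.write(
                "\t".join(
                    [
                        fid,
                        FLOAT_FMT.format(ufe_result.feature_statistic[i]),
                        FLOAT_FMT.format(ufe_result.feature_p_raw[i]),
                        FLOAT_FMT.format(ufe_result.feature_p_adjusted[i]),
                        "1" if fid in selected_set else "0",
                    ]
                )
                + "\n"
            )
    paths["features"] = fpath

    cpath = os.path.join(out_dir, "components.tsv")
    with open(cpath, "w", encoding="utf-8") as fh:
        fh.write("component\teigenvalue\tp_raw\tp_adjusted\tin_omega\n")
        omega = set(ufe_result.omega1)
        for assoc in ufe_result.stage1_associations:
            l = assoc.component
            fh.write(
                "\t".join(
                    [
                        str(l),
                        FLOAT_FMT.format(ufe_result.stage1.eigenvalues[l - 1]),
                        FLOAT_FMT.format(assoc.p_raw),
                        FLOAT_FMT.format(assoc.p_adjusted),
                        "1" if l in omega else "0",
                    ]
                )
                + "\n"
            )
    paths["components"] = cpath

    summary: dict = {
        "n_features": len(ufe_result.feature_ids),
        "omega1": list(ufe_result.omega1),
        "omega2": list(ufe_result.omega2) if ufe_result.omega2 else [],
        "n_selected_features": len(ufe_result.selected_features),
        "selected_features": list(ufe_result.selected_features),
        "fallback": ufe_result.fallback,
        "config": config or {},
        "seed": seed,
    }
    if disc_result is not None:
        rpath = os.path.join(out_dir, "roc.tsv")
        with open(rpath, "w", encoding="utf-8") as fh:
            fh.write("threshold\tfpr\ttpr\n")
            for thr, fpr, tpr in disc_result.roc:
                fh.write(
                    FLOAT_FMT.format(thr)
                    + "\t"
                    + FLOAT_FMT.format(fpr)
                    + "\t"
                    + FLOAT_FMT.format(tpr)
                    + "\n"
                )
        paths["roc"] = rpath
        summary["auc"] = disc_result.auc
        summary["evaluation_mode"] = disc_result.mode
        summary["confusion_matrix"] = {
            "classes": list(disc_result.classes),
            "layout": "predicted_x_true",
            "counts": [[int(c) for c in row] for row in disc_result.confusion],
        }
    spath = os.path.join(out_dir, "summary.json")
    with open(spath, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = spath
    return paths
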