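"""Reading count matrices and sample labels; writing result tables.

Plain delimited text is the interchange format: a count matrix has gene
IDs in the first column and sample IDs in the header row; labels are a
two-column (sample_id, group) table.  Output tables carry header comments
recording the package version, a config hash and the seed, and use a fixed
float format so identical runs are byte-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["read_count_matrix", "read_labels", "write_table"]

_FLOAT_FORMAT = "%.10g"


class CountMatrixError(ValueError):
    """Raised for malformed count-matrix or label files."""


def _sep_for(path, dialect=None):
    if dialect in ("csv", ","):
        return ","
    if dialect in ("tsv", "\t"):
        return "\t"
    return "," if str(path).endswith(".csv") else "\t"


def read_count_matrix(path, dialect=None):
    """Read a genes x samples count matrix from delimited text.

    The first column holds gene IDs, the header row sample IDs.  Values
    must be nonnegative and finite; duplicate gene IDs, ragged rows and
    negative values raise :class:`CountMatrixError` naming the offender.
    """
    sep = _sep_for(path, dialect)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise CountMatrixError(f"{path}: malformed table ({exc})") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise CountMatrixError(f"{path}: duplicate gene ID {dup!r}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise CountMatrixError(f"{path}: non-numeric value ({exc})") from exc
    if not np.all(np.isfinite(values)):
        bad = frame.index[~np.isfinite(values).all(axis=1)][0]
        raise CountMatrixError(f"{path}: non-finite value in gene {bad!r}")
    if np.any(values < 0):
        bad = frame.index[(values < 0).any(axis=1)][0]
        raise CountMatrixError(f"{path}: negative value in gene {bad!r}")
    frame = pd.DataFrame(values, index=frame.index.astype(str),
                         columns=frame.columns.astype(str))
    return frame


def read_labels(path, dialect=None):
    """Read a two-column (sample_id, group) table into a Series.

    Exactly two distinct groups are required.
    """
    sep = _sep_for(path, dialect)
    frame = pd.read_csv(path, sep=sep, header=0, comment="#")
    if frame.shape[1] != 2:
        raise CountMatrixError(f"{path}: expected 2 columns, got {frame.shape[1]}")
    labels = pd.Series(frame.iloc[:, 1].astype(str).to_numpy(),
                       index=frame.iloc[:, 0].astype(str))
    if labels.index.has_duplicates:
        dup = labels.index[labels.index.duplicated()][0]
        raise CountMatrixError(f"{path}: duplicate sample ID {dup!r}")
    groups = labels.unique()
    if len(groups) != 2:
        raise CountMatrixError(
            f"{path}: expected exactly 2 groups, got {list(groups)}")
    return labels


def write_table(frame, path, seed=None, config_hash=None, index=False):
    """Write a result table as TSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# robustde {__version__}\n")
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format=_FLOAT_FORMAT)


def read_table(path):
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
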