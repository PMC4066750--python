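"""Readers and writers for count tables, designs and simulated datasets.

TSV is the canonical dialect (tab-separated, UTF-8, '.' decimal, no
quoting); CSV is accepted on input.  MatrixMarket input takes a triplet
file plus row/column id sidecar files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .core import CountMatrix, DesignMatrix
from .simulator import SimulatedDataset

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "read_groups",
    "write_simulated_dataset",
]


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt == "csv" or (fmt is None and path.suffix.lower() == ".csv"):
        return ","
    return "\t"


def read_counts(path, fmt: str | None = None, feature_ids_path=None, sample_ids_path=None) -> CountMatrix:
    """Read a features-by-samples count table (TSV/CSV, or MTX with id sidecars).

    The first column holds feature ids and the header row sample ids.
    Duplicate ids, negative or non-integer entries are rejected with the
    offending cell named in the error.
    """
    path = Path(path)
    if fmt == "mtx" or (fmt is None and path.suffix.lower() == ".mtx"):
        if feature_ids_path is None or sample_ids_path is None:
            raise ValueError("MTX input needs feature and sample id sidecar files")
        m = scipy.io.mmread(str(path))
        values = m.toarray() if hasattr(m, "toarray") else np.asarray(m)
        feature_ids = Path(feature_ids_path).read_text().split()
        sample_ids = Path(sample_ids_path).read_text().split()
        return CountMatrix(values, feature_ids, sample_ids)
    frame = pd.read_csv(path, sep=_sep_for(path, fmt), index_col=0, comment="#")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate feature id: {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = frame.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
        g, i = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"malformed numeric cell at feature {frame.index[g]!r}, sample {frame.columns[i]!r}")
    try:
        return CountMatrix(values, list(frame.index.astype(str)), list(frame.columns.astype(str)))
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_counts(counts: CountMatrix, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        counts.to_frame().to_csv(fh, sep="\t", index_label="feature_id")


def read_groups(path) -> list[str]:
    """One group label per line (optionally 'sample<TAB>group')."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    return [ln.split("\t")[-1] for ln in lines]


def read_design(path) -> DesignMatrix:
    """Numeric design matrix TSV: header of coefficient names, one row per sample.

    Columns whose name ends in '*' are marked as coefficients of interest;
    if none are marked, every non-intercept-like column (not constant 1) is.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    names = [c.rstrip("*") for c in frame.columns]
    starred = [j for j, c in enumerate(frame.columns) if c.endswith("*")]
    values = frame.to_numpy(dtype=float)
    if not starred:
        starred = [j for j in range(values.shape[1]) if not np.allclose(values[:, j], 1.0)]
    return DesignMatrix(values, names, starred)


def write_simulated_dataset(ds: SimulatedDataset, out_prefix, header_comment: str | None = None) -> dict[str, Path]:
    """Serialize a simulated dataset: clean/outlier counts, truth and mask TSVs."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "clean": Path(f"{out_prefix}_counts_clean.tsv"),
        "outlier": Path(f"{out_prefix}_counts_outlier.tsv"),
        "truth": Path(f"{out_prefix}_truth.tsv"),
        "mask": Path(f"{out_prefix}_outlier_mask.tsv"),
    }
    write_counts(ds.clean_counts, paths["clean"], header_comment)
    write_counts(ds.counts, paths["outlier"], header_comment)
    truth = pd.DataFrame(
        {
            "feature_id": ds.clean_counts.feature_ids,
            "de_status": ds.truth_de,
            "fold_change": ds.fold_change,
            "true_dispersion": ds.true_phi,
        }
    )
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        truth.to_csv(fh, sep="\t", index=False)
    mask = ds.outlier_mask
    if mask is None:
        mask = np.zeros(ds.clean_counts.values.shape, dtype=bool)
    mask_frame = pd.DataFrame(mask.astype(int), index=ds.clean_counts.feature_ids, columns=ds.clean_counts.sample_ids)
    with open(paths["mask"], "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        mask_frame.to_csv(fh, sep="\t", index_label="feature_id")
    return paths
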