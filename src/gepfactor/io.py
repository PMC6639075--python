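"""Reading/writing count matrices and pipeline artifacts.

Counts move as MatrixMarket coordinate files with ``genes.tsv`` /
``barcodes.tsv`` sidecars, or as dense TSV (cells x genes).  All emitted
tables are TSV with 6 significant digits and a header naming the unit
system, because confusing l1-normalized, TPM-unit and z-score-beta tables
is the main user hazard of this method.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = ["RunConfig", "read_counts", "write_counts", "write_table",
           "read_table"]

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Serializable record of one pipeline run; stored beside the outputs so
    any run is reproducible from its config + seed."""

    input_path: str = ""
    input_format: str = "auto"      # mtx | tsv | auto
    output_dir: str = "."
    k: int | None = None
    k_list: list[int] = field(default_factory=list)
    R: int = 200
    rho: float = 0.3
    tau: float | str = "auto"
    n_overdispersed: int = 2000
    selection: str = "vscore"       # vscore | fano
    from_tpm: bool = False          # full-transcript path
    seed: int = 0
    threads: int = 1

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _read_sidecar(path: Path) -> list[str]:
    # 10x-style sidecars may have 1 or 2+ columns; the identifier comes first
    df = pd.read_csv(path, sep="\t", header=None)
    return df.iloc[:, 0].astype(str).tolist()


def read_counts(path: str | Path, fmt: str = "auto",
                orientation: str = "auto") -> pd.DataFrame:
    """Load a cells x genes integer count matrix.

    ``path`` is either a dense TSV (cells in rows, first column = cell
    names) or an ``.mtx`` file with ``genes.tsv`` and ``barcodes.tsv``
    sidecars in the same directory.  MTX orientation is auto-detected from
    the sidecar lengths; pass ``orientation='genes-by-cells'`` or
    ``'cells-by-genes'`` to override.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name, df.columns.name = "cell", "gene"
    elif fmt == "mtx":
        mat = scipy.io.mmread(path)
        mat = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        genes = _read_sidecar(path.parent / "genes.tsv")
        cells = _read_sidecar(path.parent / "barcodes.tsv")
        if orientation == "auto":
            if mat.shape == (len(cells), len(genes)):
                pass
            elif mat.shape == (len(genes), len(cells)):
                mat = mat.T
            else:
                raise ValueError(
                    f"matrix shape {mat.shape} matches neither "
                    f"(cells={len(cells)}, genes={len(genes)}) nor its transpose"
                )
        elif orientation == "genes-by-cells":
            mat = mat.T
        elif orientation != "cells-by-genes":
            raise ValueError(f"unknown orientation {orientation!r}")
        if mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"(cells={len(cells)}, genes={len(genes)})"
            )
        df = pd.DataFrame(mat, index=pd.Index(cells, name="cell"),
                          columns=pd.Index(genes, name="gene"))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    dup = df.columns[df.columns.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene names: {dup[:10]}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path,
                 fmt: str = "mtx") -> None:
    """Write counts as MTX + sidecars (sparse, integer) or dense TSV."""
    path = Path(path)
    if fmt == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(counts.to_numpy())
        scipy.io.mmwrite(str(path), sparse, field="integer")
        pd.Series(counts.columns).to_csv(path.parent / "genes.tsv",
                                         sep="\t", index=False, header=False)
        pd.Series(counts.index).to_csv(path.parent / "barcodes.tsv",
                                       sep="\t", index=False, header=False)
    elif fmt == "tsv":
        counts.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_table(df: pd.DataFrame, path: str | Path, units: str) -> None:
    """TSV with a leading comment line naming the unit system."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")
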