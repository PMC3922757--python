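"""Matrix, basis and image I/O.

Matrices are read/written as CSV (comma separated, row = observation,
optional header) or raw ``.npy`` binary arrays, chosen by file suffix.
A coupled basis is serialized as a directory with two matrix files and
one parameter table (columns: index, rho, nu).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import CoupledBasis, SourcePairParams

__all__ = ["load_matrix", "save_matrix", "save_basis", "load_basis",
           "load_image", "save_image"]


def load_matrix(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    # CSV / whitespace text, tolerate a single header line
    try:
        return np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None,
                          ndmin=2)
    except ValueError:
        return np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None,
                          skiprows=1, ndmin=2)


def save_matrix(path, M: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(M))
    else:
        np.savetxt(path, np.atleast_2d(M), delimiter=",")


def save_basis(directory, basis: CoupledBasis) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_matrix(d / "W_x.csv", basis.W_x)
    save_matrix(d / "W_y.csv", basis.W_y)
    pd.DataFrame({
        "index": np.arange(basis.n_pairs),
        "rho": basis.rhos,
        "nu": basis.nus,
    }).to_csv(d / "pairs.csv", index=False)


def load_basis(directory) -> CoupledBasis:
    d = Path(directory)
    W_x = load_matrix(d / "W_x.csv")
    W_y = load_matrix(d / "W_y.csv")
    tab = pd.read_csv(d / "pairs.csv")
    pairs = [
        SourcePairParams(rho=r.rho, nu=None if np.isinf(r.nu) else r.nu)
        for r in tab.itertuples()
    ]
    return CoupledBasis(W_x=W_x, W_y=W_y, pairs=pairs)


def load_image(path) -> np.ndarray:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.dtype.kind in "ui":
        img = img / np.iinfo(img.dtype).max
    return img


def save_image(path, img: np.ndarray, bits: int = 8) -> None:
    import imageio.v3 as iio

    scale = (1 << bits) - 1
    arr = np.clip(np.asarray(img), 0.0, 1.0) * scale
    iio.imwrite(path, arr.astype(np.uint16 if bits > 8 else np.uint8))
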