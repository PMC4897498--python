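"""Reading and writing the tabular formats the package consumes and emits.

Response matrices travel as CSV/TSV with persons in rows and items in
columns (a ``transpose`` flag handles the other convention explicitly).
An optional header row and a leading ID column are auto-detected — any
first row/column that does not parse to {0, 1} is treated as labels — or
can be forced.  Chain samples are stored in a small on-disk layout (one
``.npz`` of draws plus a JSON manifest echoing sizes, seed and config) so
summarization is decoupled from fitting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ResponseMatrix
from .sampler import ChainSamples

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "save_samples",
    "load_samples",
]

_BINARY = {"0", "1", "0.0", "1.0"}


def _is_binary_token(tok: str) -> bool:
    return tok.strip() in _BINARY


def _guess_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if path.suffix.lower() in (".tsv", ".tab"):
        return "\t"
    return ","


def read_response_matrix(
    path,
    delimiter: str | None = None,
    header: bool | str = "auto",
    id_column: bool | str = "auto",
    transpose: bool = False,
) -> ResponseMatrix:
    """Read a binary response matrix from a delimited text file.

    ``header`` / ``id_column`` may be True, False, or "auto" (detect by
    whether the first row/column parses to {0,1}).  Errors name the
    offending cell in 1-based file coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _guess_delimiter(path, delimiter)
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if line.strip() == "":
                continue
            rows.append(line.split(sep))
    if not rows:
        raise ValueError(f"{path}: file is empty")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")

    if header == "auto":
        header = not all(_is_binary_token(tok) for tok in rows[0][1:] or rows[0])
        # a pure-binary first row is data; anything else is a header
        header = header and not all(_is_binary_token(tok) for tok in rows[0])
    item_ids = None
    if header:
        if len(rows) < 2:
            raise ValueError(f"{path}: only a header row present")
        item_ids = [tok.strip() for tok in rows[0]]
        rows = rows[1:]

    if id_column == "auto":
        id_column = not all(_is_binary_token(r[0]) for r in rows)
    person_ids = None
    if id_column:
        person_ids = [r[0].strip() for r in rows]
        rows = [r[1:] for r in rows]
        if item_ids is not None and len(item_ids) == len(rows[0]) + 1:
            item_ids = item_ids[1:]

    values = np.empty((len(rows), len(rows[0])), dtype=np.int8)
    row_offset = 2 if header else 1
    col_offset = 2 if id_column else 1
    for i, r in enumerate(rows):
        for j, tok in enumerate(r):
            if not _is_binary_token(tok):
                raise ValueError(
                    f"{path}: non-binary cell {tok!r} at row {i + row_offset}, "
                    f"column {j + col_offset}"
                )
            values[i, j] = int(float(tok))

    if transpose:
        values = values.T
        person_ids, item_ids = item_ids, person_ids
    return ResponseMatrix(values, person_ids=person_ids, item_ids=item_ids)


def write_response_matrix(path, y: ResponseMatrix, delimiter: str = ",") -> Path:
    """Write a response matrix as delimited text (values only, no labels)."""
    path = Path(path)
    np.savetxt(path, y.values, fmt="%d", delimiter=delimiter)
    return path


def save_samples(directory, samples: ChainSamples) -> Path:
    """Persist chain samples: draws in ``samples.npz``, metadata in ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(
        directory / "samples.npz",
        theta=samples.theta_draws,
        alpha=samples.alpha_draws,
        beta=samples.beta_draws,
    )
    manifest = {
        "kept": samples.kept,
        "n": samples.n,
        "k": samples.k,
        "usable": samples.usable,
        "config": samples.config,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return directory


def load_samples(directory) -> ChainSamples:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    with np.load(directory / "samples.npz") as npz:
        samples = ChainSamples(
            theta_draws=npz["theta"],
            alpha_draws=npz["alpha"],
            beta_draws=npz["beta"],
            config=manifest.get("config", {}),
            usable=bool(manifest.get("usable", True)),
        )
    return samples
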