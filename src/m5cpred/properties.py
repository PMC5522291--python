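"""Physical-chemical dinucleotide property table.

The pseudo dinucleotide composition encoding correlates lagged values of
physical-chemical properties along a sequence's dinucleotides.  This module
holds the 10-property x 16-dinucleotide table those properties come from, its
TSV IO, and the per-property standardization (zero mean, unit population
standard deviation over the 16 dinucleotides) that the encoding assumes.

A default table of ten RNA dinucleotide structural and thermodynamic
parameters (helical step geometry: shift, slide, rise, tilt, roll, twist;
nearest-neighbour thermodynamics: stacking energy, enthalpy, entropy, free
energy) ships with the package; any table with the same shape can be
substituted, and downstream model artifacts record the table's checksum so a
model is never applied across a silent table swap.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

ALPHABET = "ACGU"
#: the 16 dinucleotides in alphabetical order (AA, AC, ..., UU)
DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in ALPHABET for b in ALPHABET)
DINUC_INDEX: dict[str, int] = {d: i for i, d in enumerate(DINUCLEOTIDES)}

_STANDARD_TOL = 1e-9


@dataclass(frozen=True)
class PropertyTable:
    """Numeric values of physical-chemical properties per dinucleotide.

    Parameters
    ----------
    property_names : tuple of str
        One label per property (row).
    values : ndarray of shape (n_properties, 16)
        Property values, columns ordered as :data:`DINUCLEOTIDES`.
    standardized : bool
        Whether each row has zero mean and unit population SD over the
        16 dinucleotides.
    """

    property_names: tuple[str, ...]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(DINUCLEOTIDES):
            raise InputError(
                f"property table must have 16 dinucleotide columns, got shape {values.shape}"
            )
        if values.shape[0] != len(self.property_names):
            raise InputError("number of property names does not match number of rows")
        if len(set(self.property_names)) != len(self.property_names):
            raise InputError("duplicate property names in table")
        if not np.all(np.isfinite(values)):
            raise InputError("property table contains non-finite values")
        object.__setattr__(self, "values", values)
        # the standardized flag is asserted by standardize(); custom tables may
        # set it to use raw values directly (e.g. hand-computed checks)

    @property
    def n_properties(self) -> int:
        return self.values.shape[0]

    def value(self, property_index: int, dinucleotide: str) -> float:
        """Value of one property for one dinucleotide (0-based property index)."""
        return float(self.values[property_index, DINUC_INDEX[dinucleotide]])

    def checksum(self) -> str:
        """SHA-256 over names and values; identifies the table in model files."""
        h = hashlib.sha256()
        h.update("\t".join(self.property_names).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.property_names), columns=list(DINUCLEOTIDES))


def load_property_table(path: str | Path | None = None) -> PropertyTable:
    """Read a property table from TSV (first column ``property``, 16 columns AA..UU).

    With ``path=None`` the packaged default table is loaded.  The returned
    table is unstandardized; call :func:`standardize` before encoding.
    """
    if path is None:
        ref = resources.files("m5cpred").joinpath("data/rna_dinucleotide_properties.tsv")
        with resources.as_file(ref) as p:
            return load_property_table(p)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read property table {path}: {exc}") from exc
    missing = [d for d in DINUCLEOTIDES if d not in df.columns]
    if missing:
        raise InputError(f"property table {path} lacks dinucleotide columns: {missing}")
    extra = [c for c in df.columns if c not in DINUC_INDEX]
    if extra:
        raise InputError(f"property table {path} has unexpected columns: {extra}")
    if df.index.has_duplicates:
        raise InputError(f"property table {path} has duplicate property names")
    df = df[list(DINUCLEOTIDES)]
    try:
        values = df.to_numpy(dtype=float, na_value=np.nan)
    except (ValueError, TypeError) as exc:
        raise InputError(f"property table {path} has non-numeric cells: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise InputError(f"property table {path} has non-numeric or missing cells")
    return PropertyTable(tuple(str(n) for n in df.index), values, standardized=False)


def save_property_table(table: PropertyTable, path: str | Path) -> None:
    table.to_frame().rename_axis("property").to_csv(path, sep="\t")


def standardize(table: PropertyTable) -> PropertyTable:
    """Return a copy with each property row at mean 0 / population SD 1.

    Standardizing an already-standardized table is a no-op (up to rounding).
    A property that is constant across the 16 dinucleotides carries no
    contrast and raises ``InputError``.
    """
    mean = table.values.mean(axis=1, keepdims=True)
    sd = table.values.std(axis=1, keepdims=True)
    zero = np.isclose(sd[:, 0], 0.0)
    if np.any(zero):
        names = [table.property_names[i] for i in np.flatnonzero(zero)]
        raise InputError(f"zero-variance property rows cannot be standardized: {names}")
    return PropertyTable(table.property_names, (table.values - mean) / sd, standardized=True)
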