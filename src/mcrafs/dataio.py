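"""Reading and writing of spectral matrices, profiles and AFS regions.

The on-disk layout for a spectral dataset is a small delimited-text matrix:

* optional comment lines ``# key: value`` (currently ``closure_c0``),
* a header row: one corner label cell followed by the ``n`` wavelengths (nm),
* ``k`` data rows: the condition value (added acid, mol/l) followed by the
  ``n`` absorbance values of that spectrum.

Rows are spectra (conditions), columns are wavelength channels; a file whose
axes come out transposed is rejected by the axis-monotonicity checks rather
than silently transposed.  All numerics are written with 17 significant
digits (``repr`` round-trip precision for IEEE doubles) so that files
round-trip bit-identically.

AFS regions are stored as a documented JSON schema, see :func:`write_region`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralDataset",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "read_profile",
    "write_profile",
    "read_region",
    "write_region",
]

#: printf format giving exact (repr) round-trips for IEEE-754 doubles
FLOAT_FMT = "%.17g"


class DatasetFormatError(ValueError):
    """A file could not be parsed into a valid dataset."""


@dataclass
class SpectralDataset:
    """An absorbance matrix with its wavelength and titration axes.

    Parameters
    ----------
    absorbance
        ``(k, n)`` matrix of absorbance values; rows are measured spectra
        (one per condition), columns are wavelength channels.  Entries may
        be slightly negative (preprocessed data); no lower bound is imposed.
    wavelengths
        Length-``n`` strictly increasing wavelength axis in nm.
    conditions
        Length-``k`` nondecreasing axis of added titrant (mol/l).
    closure_c0
        Optional total-mass constant of the closure (mass-balance)
        constraint, in mol/l.
    """

    absorbance: np.ndarray
    wavelengths: np.ndarray
    conditions: np.ndarray
    closure_c0: float | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=float)
        if self.absorbance.ndim != 2:
            raise DatasetFormatError("absorbance must be a 2-D matrix")
        k, n = self.absorbance.shape
        if k < 2 or n < 2:
            raise DatasetFormatError(f"need at least a 2x2 matrix, got {k}x{n}")
        if self.wavelengths.shape != (n,):
            raise DatasetFormatError(
                f"wavelength axis has length {self.wavelengths.size}, expected {n}"
            )
        if self.conditions.shape != (k,):
            raise DatasetFormatError(
                f"condition axis has length {self.conditions.size}, expected {k}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise DatasetFormatError("absorbance contains non-finite entries")
        if not (
            np.all(np.isfinite(self.wavelengths))
            and np.all(np.isfinite(self.conditions))
        ):
            raise DatasetFormatError("axes contain non-finite entries")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DatasetFormatError("wavelengths must be strictly increasing")
        if np.any(np.diff(self.conditions) < 0):
            raise DatasetFormatError("conditions must be nondecreasing")
        if self.closure_c0 is not None:
            self.closure_c0 = float(self.closure_c0)

    @property
    def k(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n(self) -> int:
        return self.absorbance.shape[1]

    def transposed(self) -> "SpectralDataset":
        """The dataset with the roles of the two axes exchanged.

        Used to compute concentrational quantities with the machinery
        written for the spectral side.  Axis monotonicity is preserved
        because both axes are monotone.
        """
        return SpectralDataset(
            absorbance=self.absorbance.T.copy(),
            wavelengths=self.conditions.copy()
            if np.all(np.diff(self.conditions) > 0)
            else np.arange(self.k, dtype=float),
            conditions=self.wavelengths.copy(),
            closure_c0=self.closure_c0,
        )


def _parse_float(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise DatasetFormatError(
            f"{path}, line {lineno}: cannot parse {token!r} as a number"
        ) from None


def _split(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        # auto: comma if present, else any whitespace/tab
        delimiter = "," if "," in line else None
    if delimiter is None:
        return line.split()
    return [t.strip() for t in line.split(delimiter)]


def read_dataset(path: str | Path, dialect: str | None = None) -> SpectralDataset:
    """Read a :class:`SpectralDataset` from a delimited-text file.

    ``dialect`` is the column delimiter (default: comma if the line contains
    one, else whitespace/tab).  Parse failures report the offending line.
    """
    path = Path(path)
    closure_c0: float | None = None
    header: list[str] | None = None
    rows: list[list[float]] = []
    conditions: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("closure_c0"):
                    closure_c0 = _parse_float(
                        body.split(":", 1)[1].strip(), path, lineno
                    )
                continue
            tokens = _split(line, dialect)
            if header is None:
                header = tokens
                continue
            if len(tokens) != len(header):
                raise DatasetFormatError(
                    f"{path}, line {lineno}: expected {len(header)} columns, "
                    f"got {len(tokens)}"
                )
            values = [_parse_float(t, path, lineno) for t in tokens]
            conditions.append(values[0])
            rows.append(values[1:])
    if header is None or not rows:
        raise DatasetFormatError(f"{path}: no data rows found")
    wavelengths = [
        _parse_float(t, path, 1) for t in header[1:]
    ]  # header cell 0 is the corner label
    return SpectralDataset(
        absorbance=np.array(rows, dtype=float),
        wavelengths=np.array(wavelengths, dtype=float),
        conditions=np.array(conditions, dtype=float),
        closure_c0=closure_c0,
    )


def write_dataset(
    dataset: SpectralDataset, path: str | Path, delimiter: str = ","
) -> None:
    """Write a dataset in the layout documented in the module docstring."""
    path = Path(path)
    with open(path, "w") as fh:
        if dataset.closure_c0 is not None:
            fh.write(f"# closure_c0: {FLOAT_FMT % dataset.closure_c0}\n")
        fh.write(
            "condition\\wavelength"
            + delimiter
            + delimiter.join(FLOAT_FMT % w for w in dataset.wavelengths)
            + "\n"
        )
        for cond, row in zip(dataset.conditions, dataset.absorbance):
            fh.write(
                FLOAT_FMT % cond
                + delimiter
                + delimiter.join(FLOAT_FMT % v for v in row)
                + "\n"
            )


def read_profile(path: str | Path, dialect: str | None = None) -> np.ndarray:
    """Read a single profile (one value per line, or axis,value pairs).

    Returns the value column as a 1-D array.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _split(line, dialect)
            values.append(_parse_float(tokens[-1], path, lineno))
    if not values:
        raise DatasetFormatError(f"{path}: empty profile file")
    return np.array(values, dtype=float)


def write_profile(
    profile: np.ndarray,
    path: str | Path,
    axis: np.ndarray | None = None,
    delimiter: str = ",",
) -> None:
    path = Path(path)
    profile = np.asarray(profile, dtype=float)
    with open(path, "w") as fh:
        if axis is None:
            for v in profile:
                fh.write(FLOAT_FMT % v + "\n")
        else:
            for a, v in zip(np.asarray(axis, dtype=float), profile):
                fh.write(FLOAT_FMT % a + delimiter + FLOAT_FMT % v + "\n")


# --- AFS region files -------------------------------------------------------
#
# JSON schema:
# {
#   "factor_side": "spectral" | "concentrational",
#   "params": {"epsilon": float, "delta": float, "eps_b": float},
#   "polygons": [
#       {"label": str | null, "vertices": [[x1, x2, ...], ...]},
#       ...
#   ]
# }
# Vertex lists are closed implicitly (last vertex joins the first).


def write_region(region, path: str | Path) -> None:
    """Write an AFS region (see :mod:`mcrafs.afs`) as structured text (JSON)."""
    path = Path(path)
    labels = region.component_labels or [None] * len(region.polygons)
    doc = {
        "factor_side": region.factor_side,
        "params": {
            "epsilon": region.params.epsilon,
            "delta": region.params.delta,
            "eps_b": region.params.eps_b,
        },
        "polygons": [
            {"label": lab, "vertices": [[float(c) for c in v] for v in poly]}
            for lab, poly in zip(labels, region.polygons)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_region(path: str | Path):
    """Read an AFS region written by :func:`write_region`."""
    from .afs import AFSRegion
    from .factor_core import FeasibilityParams

    with open(Path(path)) as fh:
        doc = json.load(fh)
    params = FeasibilityParams(**doc["params"])
    polygons = [np.array(p["vertices"], dtype=float) for p in doc["polygons"]]
    labels = [p["label"] for p in doc["polygons"]]
    if all(lab is None for lab in labels):
        labels = None
    return AFSRegion(
        factor_side=doc["factor_side"],
        polygons=polygons,
        component_labels=labels,
        params=params,
        validate=False,
    )
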