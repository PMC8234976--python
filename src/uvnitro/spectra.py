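"""Data model and I/O for UV absorbance spectra and composition tables.

The in-memory containers mirror what a dual-beam spectrophotometer produces:
a shared wavelength grid (nm), one absorbance vector per sample at a stated
cuvette pathlength, and an optional composition table giving the response
triple (nitrate in uM, nitrite in uM, salinity in psu) for each sample.

Two delimited-text dialects are supported:

* wide  -- first column ``wavelength_nm``, one column per sample id; an
  optional leading ``# pathlength_cm=<x>`` comment records the cuvette.
* long  -- columns ``sample_id, wavelength_nm, absorbance``.

Composition tables use columns ``sample_id, no3_uM, no2_uM, salinity_psu``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "GridRangeError",
    "WavelengthGrid",
    "AbsorbanceSpectrum",
    "Composition",
    "SpectraSet",
    "read_spectra",
    "write_spectra",
    "read_compositions",
    "write_compositions",
    "resample",
    "window",
]

#: wavelengths outside this span are physically implausible for this instrument class
_GRID_BOUNDS = (190.0, 400.0)
_DEFAULT_PATHLENGTH_CM = 3.0


class ParseError(ValueError):
    """A spectra or composition file could not be parsed."""


class GridRangeError(ValueError):
    """A requested wavelength lies outside the available grid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, uniformly spaced wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid must be a 1-d vector of >= 2 points")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavelength grid contains non-finite values")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-8, atol=1e-9):
            raise ValueError("wavelength grid must be uniformly spaced")
        if v[0] < _GRID_BOUNDS[0] or v[-1] > _GRID_BOUNDS[1]:
            raise ValueError(
                f"wavelength grid must lie within {_GRID_BOUNDS} nm, got "
                f"[{v[0]}, {v[-1]}]"
            )
        object.__setattr__(self, "values", v)

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def index_of(self, wavelength: float) -> int:
        """Index of an on-grid wavelength; raises GridRangeError if off-grid."""
        idx = int(np.argmin(np.abs(self.values - wavelength)))
        if abs(self.values[idx] - wavelength) > 1e-6:
            raise GridRangeError(
                f"{wavelength} nm is not on the grid "
                f"[{self.lo}, {self.hi}] @ {self.spacing} nm"
            )
        return idx

    def window_slice(self, lo: float, hi: float) -> slice:
        """Slice selecting [lo, hi] inclusive; both bounds must be on-grid."""
        if lo >= hi:
            raise ValueError(f"window bounds must satisfy lo < hi, got {lo} >= {hi}")
        return slice(self.index_of(lo), self.index_of(hi) + 1)

    def restrict(self, lo: float, hi: float) -> "WavelengthGrid":
        return WavelengthGrid(self.values[self.window_slice(lo, hi)])


@dataclass
class AbsorbanceSpectrum:
    """One sample's absorbance (dimensionless AU) on a wavelength grid."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    pathlength: float = _DEFAULT_PATHLENGTH_CM  # cm
    sample_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (len(self.grid),):
            raise ValueError(
                f"absorbance length {a.size} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite absorbance values")
        if not self.pathlength > 0:
            raise ValueError(f"pathlength must be > 0 cm, got {self.pathlength}")
        self.absorbance = a

    def window(self, lo: float, hi: float) -> "AbsorbanceSpectrum":
        sl = self.grid.window_slice(lo, hi)
        return AbsorbanceSpectrum(
            grid=self.grid.restrict(lo, hi),
            absorbance=self.absorbance[sl],
            pathlength=self.pathlength,
            sample_id=self.sample_id,
        )


@dataclass(frozen=True)
class Composition:
    """Response triple for one sample: nitrate (uM), nitrite (uM), salinity (psu).

    Values may be negative when the triple is a model *prediction*; generator
    inputs are validated non-negative at simulation time.
    """

    no3: float
    no2: float
    salinity: float

    def as_array(self) -> np.ndarray:
        return np.array([self.no3, self.no2, self.salinity], dtype=float)

    @staticmethod
    def names() -> tuple[str, str, str]:
        return ("no3", "no2", "salinity")


class SpectraSet:
    """Ordered collection of spectra sharing one grid, optionally with compositions."""

    def __init__(
        self,
        spectra: Sequence[AbsorbanceSpectrum],
        compositions: Sequence[Composition] | None = None,
    ):
        spectra = list(spectra)
        if not spectra:
            raise ValueError("SpectraSet requires at least one spectrum")
        g0 = spectra[0].grid
        for s in spectra[1:]:
            if not np.array_equal(s.grid.values, g0.values):
                raise ValueError(
                    f"sample {s.sample_id!r} is on a different wavelength grid"
                )
        if compositions is not None:
            compositions = list(compositions)
            if len(compositions) != len(spectra):
                raise ValueError(
                    f"{len(compositions)} compositions for {len(spectra)} spectra"
                )
        self.spectra: list[AbsorbanceSpectrum] = spectra
        self.compositions: list[Composition] | None = compositions
        self._grid = g0

    @property
    def grid(self) -> WavelengthGrid:
        return self._grid

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def pathlength(self) -> float:
        """Common pathlength (cm); raises if the set mixes pathlengths."""
        pl = {s.pathlength for s in self.spectra}
        if len(pl) != 1:
            raise ValueError(
                "set mixes pathlengths %s; rescale to a common pathlength first"
                % sorted(pl)
            )
        return pl.pop()

    @property
    def X(self) -> np.ndarray:
        """n x m absorbance matrix (requires a common pathlength)."""
        _ = self.pathlength
        return np.vstack([s.absorbance for s in self.spectra])

    @property
    def Y(self) -> np.ndarray:
        """n x 3 composition matrix (no3, no2, salinity)."""
        if self.compositions is None:
            raise ValueError("this SpectraSet carries no compositions")
        return np.vstack([c.as_array() for c in self.compositions])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[AbsorbanceSpectrum]:
        return iter(self.spectra)

    def window(self, lo: float, hi: float) -> "SpectraSet":
        return SpectraSet(
            [s.window(lo, hi) for s in self.spectra], compositions=self.compositions
        )

    def with_spectra(self, spectra: Sequence[AbsorbanceSpectrum]) -> "SpectraSet":
        """Same compositions/order, replaced spectra (e.g. after correction)."""
        return SpectraSet(list(spectra), compositions=self.compositions)


# ---------------------------------------------------------------------------
# I/O


def _read_pathlength_comment(path: str) -> float:
    pl = _DEFAULT_PATHLENGTH_CM
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("pathlength_cm"):
                try:
                    pl = float(body.split("=", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"malformed pathlength comment: {line!r}") from exc
    return pl


def _numeric_column(df: pd.DataFrame, col: str, path: str) -> np.ndarray:
    try:
        return df[col].astype(float).to_numpy()
    except (TypeError, ValueError):
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0]
        raise ParseError(
            f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r} (row {row})"
        ) from None


def _orient_ascending(wl: np.ndarray, path: str) -> tuple[np.ndarray, bool]:
    d = np.diff(wl)
    if np.all(d > 0):
        return wl, False
    if np.all(d < 0):
        logger.info("%s: descending wavelength column, re-sorting ascending", path)
        return wl[::-1], True
    raise ParseError(f"{path}: wavelength column is not monotone")


def read_spectra(path: str, dialect: str = "wide") -> SpectraSet:
    """Read a spectra file in the ``wide`` or ``long`` dialect.

    Descending wavelength columns are accepted and re-sorted (logged); any
    other non-monotone ordering, ragged rows, missing or non-numeric cells,
    and duplicate sample ids are parse errors naming the offender.
    """
    if dialect == "wide":
        return _read_wide(path)
    if dialect == "long":
        return _read_long(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def _read_wide(path: str) -> SpectraSet:
    pathlength = _read_pathlength_comment(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "wavelength_nm":
        raise ParseError(
            f"{path}: first column must be 'wavelength_nm', got {df.columns[0]!r}"
        )
    ids = list(df.columns[1:])
    if not ids:
        raise ParseError(f"{path}: no sample columns")
    # pandas mangles duplicate headers to 'x.1'; detect them in the raw header
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                raw = next(csv_iter_line(line))
                break
    raw_ids = raw[1:]
    dupes = {s for s in raw_ids if raw_ids.count(s) > 1}
    if dupes:
        raise ParseError(f"{path}: duplicate sample_id(s) {sorted(dupes)}")
    wl = _numeric_column(df, "wavelength_nm", path)
    wl, flipped = _orient_ascending(wl, path)
    try:
        grid = WavelengthGrid(wl)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    spectra = []
    for sid in ids:
        col = _numeric_column(df, sid, path)
        if flipped:
            col = col[::-1]
        if np.any(~np.isfinite(col)):
            at = wl[np.flatnonzero(~np.isfinite(col))[0]]
            raise ParseError(
                f"{path}: missing absorbance for sample {sid!r} at {at:g} nm"
            )
        spectra.append(
            AbsorbanceSpectrum(grid, col, pathlength=pathlength, sample_id=str(sid))
        )
    return SpectraSet(spectra)


def csv_iter_line(line: str) -> Iterable[list[str]]:
    import csv

    return csv.reader(io.StringIO(line))


def _read_long(path: str) -> SpectraSet:
    pathlength = _read_pathlength_comment(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    need = {"sample_id", "wavelength_nm", "absorbance"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: long dialect needs columns {sorted(need)}")
    df = df.copy()
    df["wavelength_nm"] = _numeric_column(df, "wavelength_nm", path)
    df["absorbance"] = _numeric_column(df, "absorbance", path)
    if df.duplicated(["sample_id", "wavelength_nm"]).any():
        r = df[df.duplicated(["sample_id", "wavelength_nm"])].iloc[0]
        raise ParseError(
            f"{path}: duplicate entry for sample {r['sample_id']!r} "
            f"at {r['wavelength_nm']:g} nm"
        )
    order = list(dict.fromkeys(df["sample_id"]))
    wide = df.pivot(index="wavelength_nm", columns="sample_id", values="absorbance")
    wl = wide.index.to_numpy(float)  # pivot sorts ascending
    try:
        grid = WavelengthGrid(wl)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    spectra = []
    for sid in order:
        col = wide[sid].to_numpy(float)
        if np.any(~np.isfinite(col)):
            at = wl[np.flatnonzero(~np.isfinite(col))[0]]
            raise ParseError(
                f"{path}: missing absorbance for sample {sid!r} at {at:g} nm"
            )
        spectra.append(
            AbsorbanceSpectrum(grid, col, pathlength=pathlength, sample_id=str(sid))
        )
    return SpectraSet(spectra)


def write_spectra(sset: SpectraSet, path: str, dialect: str = "wide") -> None:
    """Write a SpectraSet; ``read_spectra`` round-trips it bit-exactly."""
    pl = sset.pathlength
    if dialect == "wide":
        df = pd.DataFrame({"wavelength_nm": sset.grid.values})
        for s in sset.spectra:
            df[s.sample_id] = s.absorbance
        with open(path, "w") as fh:
            fh.write(f"# pathlength_cm={pl!r}\n")
            df.to_csv(fh, index=False)
    elif dialect == "long":
        frames = [
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "wavelength_nm": s.grid.values,
                    "absorbance": s.absorbance,
                }
            )
            for s in sset.spectra
        ]
        with open(path, "w") as fh:
            fh.write(f"# pathlength_cm={pl!r}\n")
            pd.concat(frames, ignore_index=True).to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_compositions(path: str) -> dict[str, Composition]:
    """Read a composition table keyed by sample_id (order preserved)."""
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    need = {"sample_id", "no3_uM", "no2_uM", "salinity_psu"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: composition table needs columns {sorted(need)}")
    if df["sample_id"].duplicated().any():
        dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ParseError(f"{path}: duplicate sample_id(s) {dupes}")
    out: dict[str, Composition] = {}
    for _, row in df.iterrows():
        try:
            out[str(row["sample_id"])] = Composition(
                float(row["no3_uM"]), float(row["no2_uM"]), float(row["salinity_psu"])
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: non-numeric composition for sample {row['sample_id']!r}"
            ) from exc
    return out


def write_compositions(
    sample_ids: Sequence[str], compositions: Sequence[Composition], path: str
) -> None:
    pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "no3_uM": [c.no3 for c in compositions],
            "no2_uM": [c.no2 for c in compositions],
            "salinity_psu": [c.salinity for c in compositions],
        }
    ).to_csv(path, index=False)


def attach_compositions(sset: SpectraSet, table: dict[str, Composition]) -> SpectraSet:
    """Align a composition table to a SpectraSet by sample_id."""
    missing = [sid for sid in sset.sample_ids if sid not in table]
    if missing:
        raise ValueError(f"no composition for sample(s) {missing}")
    return SpectraSet(sset.spectra, [table[sid] for sid in sset.sample_ids])


# ---------------------------------------------------------------------------
# grid operations


def resample(s: AbsorbanceSpectrum, g: WavelengthGrid) -> AbsorbanceSpectrum:
    """Linear interpolation of a spectrum onto grid ``g`` (no extrapolation)."""
    if g.lo < s.grid.lo - 1e-9 or g.hi > s.grid.hi + 1e-9:
        raise GridRangeError(
            f"target grid [{g.lo}, {g.hi}] extends beyond spectrum span "
            f"[{s.grid.lo}, {s.grid.hi}]"
        )
    vals = np.interp(g.values, s.grid.values, s.absorbance)
    return AbsorbanceSpectrum(g, vals, pathlength=s.pathlength, sample_id=s.sample_id)


def window(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Restrict a SpectraSet to [lo, hi] nm inclusive (bounds must be on-grid)."""
    return s.window(lo, hi)
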