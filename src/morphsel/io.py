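"""Readers and writers for landmark digitizing formats and trait tables.

Supports the TPS landmark dialect emitted by the tpsDig family of
digitizing tools (``LM=`` records with optional ``IMAGE=``, ``ID=`` and
``SCALE=`` keys), slider definition files for semilandmarks, and the
delimited per-specimen trait/fitness table used by the selection
analysis.

Conventions
-----------
* Landmark indices are 1-based in files and converted to 0-based at the
  parse boundary; everything in memory is 0-based.
* ``SCALE`` factors are stored but never pre-applied to coordinates:
  Procrustes superimposition is scale-invariant, and centroid size can be
  reported in either digitizer or physical units on request.
* The TPS y-axis increases upward (digitizer convention); no axis flip is
  performed on input or output.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import IO

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "SliderTable",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "read_sliders",
    "write_sliders",
    "read_trait_table",
    "write_trait_table",
]

EPISODES = ("mating", "fertilization")


class TPSParseError(ValueError):
    """Raised when a TPS or slider stream violates the format."""


@dataclass
class LandmarkSet:
    """A collection of digitized specimen outlines.

    Parameters
    ----------
    coords : ndarray, shape (n, k, 2)
        Landmark coordinates in digitizer units, one row of ``k``
        (x, y) pairs per specimen, in digitizing order.
    specimen_ids : list of str
        One label per specimen.
    scale : ndarray or None
        Optional per-specimen unit-conversion factor (digitizer units ->
        physical units); stored, not applied.
    fixed_mask : ndarray of bool, shape (k,)
        True where a landmark is fixed (anatomical), False where it is a
        semilandmark free to slide. Defaults to all fixed.
    images : list of str or None
        Optional per-specimen image file names from ``IMAGE=`` lines.
    """

    coords: np.ndarray
    specimen_ids: list[str]
    scale: np.ndarray | None = None
    fixed_mask: np.ndarray | None = None
    images: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n_specimens, k, 2)")
        n, k, _ = self.coords.shape
        if n > 0 and k < 3:
            raise ValueError(f"need at least 3 landmarks per specimen, got k={k}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")
        if len(self.specimen_ids) != n:
            raise ValueError("specimen_ids length does not match coords")
        if self.scale is not None:
            self.scale = np.asarray(self.scale, dtype=float)
            if self.scale.shape != (n,):
                raise ValueError("scale must have one entry per specimen")
            if np.any(self.scale <= 0):
                raise ValueError("scale factors must be positive")
        if self.fixed_mask is None:
            self.fixed_mask = np.ones(k, dtype=bool)
        else:
            self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
            if self.fixed_mask.shape != (k,):
                raise ValueError("fixed_mask must have one flag per landmark")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        """Landmarks per specimen."""
        return self.coords.shape[1]

    def with_sliders(self, sliders: "SliderTable") -> "LandmarkSet":
        """Return a copy whose fixed_mask complements the slider set."""
        sliders.validate(self.k)
        mask = np.ones(self.k, dtype=bool)
        mask[sliders.slider_indices] = False
        return LandmarkSet(
            coords=self.coords.copy(),
            specimen_ids=list(self.specimen_ids),
            scale=None if self.scale is None else self.scale.copy(),
            fixed_mask=mask,
            images=None if self.images is None else list(self.images),
        )


@dataclass
class SliderTable:
    """Semilandmark slider definitions: (before, slider, after) triples.

    Indices are 0-based in memory (1-based in files). Each semilandmark
    slides along the chord between its ``before`` and ``after``
    neighbours during Procrustes sliding.
    """

    triples: np.ndarray  # (s, 3) int

    def __post_init__(self) -> None:
        self.triples = np.asarray(self.triples, dtype=int)
        if self.triples.size == 0:
            self.triples = self.triples.reshape(0, 3)
        if self.triples.ndim != 2 or self.triples.shape[1] != 3:
            raise ValueError("triples must have shape (n_sliders, 3)")
        sliders = self.triples[:, 1]
        if len(np.unique(sliders)) != len(sliders):
            raise TPSParseError("duplicate slider landmark in slider table")
        for before, slider, after in self.triples:
            if slider == before or slider == after:
                raise TPSParseError(
                    f"slider {slider + 1} coincides with one of its neighbours"
                )

    @property
    def n_sliders(self) -> int:
        return self.triples.shape[0]

    @property
    def slider_indices(self) -> np.ndarray:
        return self.triples[:, 1]

    def validate(self, k: int) -> None:
        """Check all indices lie in [0, k)."""
        if self.triples.size and (self.triples.min() < 0 or self.triples.max() >= k):
            bad = self.triples.max() + 1
            raise TPSParseError(
                f"slider table references landmark {bad} but configuration has k={k}"
            )


def _as_text_stream(source) -> IO[str]:
    if isinstance(source, str):
        return open(source, "r", encoding="utf-8")
    if isinstance(source, bytes):
        return _io.StringIO(source.decode())
    return source


def read_tps(source) -> LandmarkSet:
    """Parse a TPS landmark stream (path, text, or file object).

    Each record starts with ``LM=k`` followed by ``k`` whitespace
    separated coordinate lines, then optional ``KEY=value`` lines
    (``ID``, ``IMAGE``, ``SCALE`` recognised; unknown keys ignored).
    Record order is preserved. ``k`` must agree across records.
    """
    close = isinstance(source, str)
    stream = _as_text_stream(source)
    try:
        lines = stream.read().splitlines()
    finally:
        if close:
            stream.close()

    records: list[dict] = []
    current: dict | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            try:
                k = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise TPSParseError(f"line {lineno}: malformed LM= header") from exc
            if current is not None and len(current["coords"]) < current["k"]:
                raise TPSParseError(
                    f"record {len(records) + 1} "
                    f"({current.get('id', '?')}): expected {current['k']} "
                    f"coordinate lines, found {len(current['coords'])}"
                )
            if current is not None:
                records.append(current)
            current = {"k": k, "coords": [], "id": None, "image": None, "scale": None}
        elif "=" in line and not _looks_numeric(line):
            if current is None:
                raise TPSParseError(f"line {lineno}: key line before any LM= record")
            key, _, value = line.partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "ID":
                current["id"] = value
            elif key == "IMAGE":
                current["image"] = value
            elif key == "SCALE":
                try:
                    current["scale"] = float(value)
                except ValueError as exc:
                    raise TPSParseError(
                        f"line {lineno}: non-numeric SCALE value {value!r}"
                    ) from exc
            # unknown keys: preserved-and-ignored (dialect drift)
        else:
            if current is None:
                raise TPSParseError(f"line {lineno}: coordinates before any LM= record")
            parts = line.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"line {lineno}: expected two coordinates, got {line!r}"
                )
            try:
                xy = (float(parts[0]), float(parts[1]))
            except ValueError as exc:
                raise TPSParseError(
                    f"line {lineno}: non-numeric coordinate in {line!r}"
                ) from exc
            if len(current["coords"]) >= current["k"]:
                raise TPSParseError(
                    f"line {lineno}: more than LM={current['k']} coordinate lines "
                    f"in record {len(records) + 1}"
                )
            current["coords"].append(xy)

    if current is not None:
        if len(current["coords"]) < current["k"]:
            raise TPSParseError(
                f"record {len(records) + 1} ({current.get('id', '?')}): "
                f"expected {current['k']} coordinate lines, "
                f"found {len(current['coords'])}"
            )
        records.append(current)

    if not records:
        return LandmarkSet(coords=np.empty((0, 3, 2)), specimen_ids=[])

    ks = {r["k"] for r in records}
    if len(ks) > 1:
        raise TPSParseError(f"inconsistent landmark counts across records: {sorted(ks)}")

    coords = np.array([r["coords"] for r in records], dtype=float)
    ids = [r["id"] if r["id"] is not None else str(i + 1) for i, r in enumerate(records)]
    scales = [r["scale"] for r in records]
    scale = None
    if any(s is not None for s in scales):
        scale = np.array([s if s is not None else 1.0 for s in scales], dtype=float)
    images = None
    if any(r["image"] is not None for r in records):
        images = [r["image"] or "" for r in records]
    return LandmarkSet(coords=coords, specimen_ids=ids, scale=scale, images=images)


def _looks_numeric(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0])
        float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(landmarks: LandmarkSet, stream) -> None:
    """Write a LandmarkSet as TPS records; read_tps round-trips it."""
    close = isinstance(stream, str)
    out = open(stream, "w", encoding="utf-8") if close else stream
    try:
        for i in range(landmarks.n_specimens):
            out.write(f"LM={landmarks.k}\n")
            for x, y in landmarks.coords[i]:
                out.write(f"{x:.12g} {y:.12g}\n")
            if landmarks.images is not None and landmarks.images[i]:
                out.write(f"IMAGE={landmarks.images[i]}\n")
            out.write(f"ID={landmarks.specimen_ids[i]}\n")
            if landmarks.scale is not None:
                out.write(f"SCALE={landmarks.scale[i]:.12g}\n")
    finally:
        if close:
            out.close()


def read_sliders(source, k: int | None = None) -> SliderTable:
    """Parse a slider file: a count header then one before/slider/after
    triple per row (1-based indices, NTS-style layout).

    If ``k`` is given the indices are validated against it.
    """
    close = isinstance(source, str)
    stream = _as_text_stream(source)
    try:
        tokens_rows = [ln.split() for ln in stream.read().splitlines() if ln.strip()]
    finally:
        if close:
            stream.close()

    if not tokens_rows:
        return SliderTable(triples=np.empty((0, 3), dtype=int))

    rows = tokens_rows
    # optional single-integer count header
    expected = None
    if len(rows[0]) == 1:
        try:
            expected = int(rows[0][0])
        except ValueError as exc:
            raise TPSParseError(f"malformed slider count header {rows[0][0]!r}") from exc
        rows = rows[1:]

    triples = []
    for i, row in enumerate(rows, start=1):
        if len(row) != 3:
            raise TPSParseError(f"slider row {i}: expected 3 indices, got {row!r}")
        try:
            before, slider, after = (int(v) for v in row)
        except ValueError as exc:
            raise TPSParseError(f"slider row {i}: non-integer index in {row!r}") from exc
        if min(before, slider, after) < 1:
            raise TPSParseError(f"slider row {i}: indices are 1-based, got {row!r}")
        triples.append((before - 1, slider - 1, after - 1))

    if expected is not None and expected != len(triples):
        raise TPSParseError(
            f"slider header announces {expected} rows but {len(triples)} found"
        )
    table = SliderTable(triples=np.array(triples, dtype=int).reshape(-1, 3))
    if k is not None:
        table.validate(k)
    return table


def write_sliders(sliders: SliderTable, stream) -> None:
    """Write a SliderTable in the count-header triple layout (1-based)."""
    close = isinstance(stream, str)
    out = open(stream, "w", encoding="utf-8") if close else stream
    try:
        out.write(f"{sliders.n_sliders}\n")
        for before, slider, after in sliders.triples:
            out.write(f"{before + 1} {slider + 1} {after + 1}\n")
    finally:
        if close:
            out.close()


REQUIRED_TRAIT_COLUMNS = ("specimen_id", "episode", "pw", "fitness")


def read_trait_table(source) -> pd.DataFrame:
    """Read the delimited per-specimen trait/fitness table.

    Requires columns ``specimen_id``, ``episode`` (mating or
    fertilization), ``pw`` (pronotum width, the body-size index) and
    ``fitness`` (binary mating success or offspring count). Extra
    columns pass through untouched.
    """
    df = pd.read_csv(source)
    missing = [c for c in REQUIRED_TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing required column(s): {missing}")
    if df["specimen_id"].duplicated().any():
        dups = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen id(s): {dups[:5]}")
    bad_ep = set(df["episode"].unique()) - set(EPISODES)
    if bad_ep:
        raise ValueError(f"unknown episode label(s) {sorted(bad_ep)}; expected {EPISODES}")
    df["pw"] = pd.to_numeric(df["pw"])
    df["fitness"] = pd.to_numeric(df["fitness"])
    if (df["fitness"] < 0).any():
        raise ValueError("fitness values must be non-negative")
    df["specimen_id"] = df["specimen_id"].astype(str)
    return df


def write_trait_table(df: pd.DataFrame, stream) -> None:
    df.to_csv(stream, index=False)
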